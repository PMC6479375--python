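"""Zero-phase band-pass decomposition into the canonical EEG rhythms.

The default bank follows the conventional affective-EEG intervals:
Delta 1-3, Theta 4-7, Alpha 8-13, Beta 14-30, Gamma 31-50 Hz. The printed
edges leave small gaps (3-4 Hz, 7-8 Hz, ...); the gaps are kept as-is
rather than inventing contiguous boundaries.

Filtering uses a Butterworth band-pass in second-order sections applied
forward then backward (``sosfiltfilt``), so the net response is zero-phase
and the passband magnitude is the squared Butterworth response. Edge
transients are mitigated by odd-reflection padding of up to three
characteristic periods of the band's low edge (capped at signal length - 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .data import BandSpec, Trial, TrialSet

DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 1.0, 3.0),
    BandSpec("theta", 4.0, 7.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 14.0, 30.0),
    BandSpec("gamma", 31.0, 50.0),
)

DEFAULT_FILTER_ORDER = 5


@dataclass
class BandBank:
    """Ordered, uniquely named collection of band specs."""

    bands: tuple[BandSpec, ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        self.bands = tuple(self.bands)
        if not self.bands:
            raise ValueError("band bank must contain at least one band")
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate band names: {names}")

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bands]

    def __iter__(self):
        return iter(self.bands)

    def __len__(self) -> int:
        return len(self.bands)


def default_band_bank() -> BandBank:
    return BandBank(DEFAULT_BANDS)


def design_bandpass(
    band: BandSpec, sampling_rate_hz: float, order: int = DEFAULT_FILTER_ORDER
) -> np.ndarray:
    """Second-order sections of the Butterworth band-pass for one band."""
    nyq = sampling_rate_hz / 2.0
    if band.hi_hz >= nyq:
        raise ValueError(
            f"band {band.name!r} upper edge {band.hi_hz} Hz reaches the Nyquist "
            f"frequency {nyq} Hz at sampling rate {sampling_rate_hz} Hz"
        )
    return signal.butter(
        order, [band.lo_hz, band.hi_hz], btype="bandpass", fs=sampling_rate_hz, output="sos"
    )


def settling_samples(band: BandSpec, sampling_rate_hz: float) -> int:
    """Padding span used around filtering: three periods of the low edge."""
    return int(np.ceil(3.0 * sampling_rate_hz / band.lo_hz))


def _filtfilt(sos: np.ndarray, x: np.ndarray, pad: int) -> np.ndarray:
    n = x.shape[-1]
    min_pad = 3 * (2 * sos.shape[0] + 1)  # sosfiltfilt's own minimum
    if n <= min_pad:
        raise ValueError(
            f"signal of {n} samples is too short for stable zero-phase filtering "
            f"(needs > {min_pad} samples)"
        )
    return signal.sosfiltfilt(sos, x, axis=-1, padlen=min(pad, n - 1))


def bandpass(trial: Trial, band: BandSpec, order: int = DEFAULT_FILTER_ORDER) -> Trial:
    """Zero-phase band-pass one trial; shape, rate and label are preserved."""
    sos = design_bandpass(band, trial.sampling_rate_hz, order)
    pad = settling_samples(band, trial.sampling_rate_hz)
    return trial.copy_with(_filtfilt(sos, trial.data, pad))


def decompose(trials: TrialSet, bank: BandBank | None = None) -> dict[str, TrialSet]:
    """One band-filtered TrialSet per band, same trial order and labels."""
    if bank is None:
        bank = default_band_bank()
    if len(trials) == 0:
        raise ValueError("cannot decompose an empty TrialSet")
    fs = trials.sampling_rate_hz
    out: dict[str, TrialSet] = {}
    for band in bank:
        sos = design_bandpass(band, fs)
        pad = settling_samples(band, fs)
        filtered = [t.copy_with(_filtfilt(sos, t.data, pad)) for t in trials]
        out[band.name] = TrialSet(trials=filtered, class_names=trials.class_names)
    return out


def magnitude_response(
    band: BandSpec,
    sampling_rate_hz: float,
    freq_hz: float | np.ndarray,
    order: int = DEFAULT_FILTER_ORDER,
) -> np.ndarray:
    """Effective zero-phase magnitude |H(f)|^2 of the designed filter.

    Forward-backward application squares the single-pass Butterworth
    magnitude, so this is the gain a sinusoid at ``freq_hz`` experiences.
    """
    sos = design_bandpass(band, sampling_rate_hz, order)
    w = 2 * np.pi * np.atleast_1d(np.asarray(freq_hz, dtype=float)) / sampling_rate_hz
    _, h = signal.sosfreqz(sos, worN=w)
    return np.abs(h) ** 2
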