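"""Differential-entropy features of band-limited EEG.

Band-pass filtered EEG is well approximated by a zero-mean Gaussian, whose
differential entropy has the closed form

    h(X) = 1/2 * ln(2 * pi * e * sigma^2)      (in nats)

so the per-channel, per-band feature reduces to a log-variance estimate.
Each trial is cut into fixed-length windows (default 1 s, non-overlapping),
the maximum-likelihood variance (mean-removed, divide by N) is taken per
window, mapped through the closed form, and aggregated across windows
(default: mean). A tiny variance floor keeps degenerate windows finite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .data import FeatureColumn, FeatureTable, Trial, TrialSet

logger = logging.getLogger("delda")

_LN_2PIE = math.log(2.0 * math.pi * math.e)


@dataclass
class DEConfig:
    """Windowing / estimation policy for differential-entropy features.

    window_seconds : window length (default 1.0 s).
    window_overlap : fractional overlap in [0, 1) between windows (default 0).
    variance_floor : lower clamp for window variances; keeps DE finite on
        flat windows (default 1e-12).
    aggregate : 'mean' or 'median' across windows (default 'mean').

    The logarithm is natural throughout (DE in nats), which makes the
    2*pi*e constant exact.
    """

    window_seconds: float = 1.0
    window_overlap: float = 0.0
    variance_floor: float = 1e-12
    aggregate: str = "mean"

    def __post_init__(self) -> None:
        if self.window_seconds <= 0:
            raise ValueError("window_seconds must be positive")
        if not 0 <= self.window_overlap < 1:
            raise ValueError("window_overlap must lie in [0, 1)")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be positive")
        if self.aggregate not in ("mean", "median"):
            raise ValueError(f"unknown aggregate {self.aggregate!r}")

    def window_samples(self, sampling_rate_hz: float) -> int:
        w = int(round(self.window_seconds * sampling_rate_hz))
        if w < 2:
            raise ValueError(
                f"window of {self.window_seconds} s at {sampling_rate_hz} Hz "
                f"has {w} samples; need at least 2"
            )
        return w


def gaussian_de(variance: float | np.ndarray, variance_floor: float = 1e-12) -> float | np.ndarray:
    """Differential entropy (nats) of a Gaussian with the given variance.

    Monotone increasing in the variance; variances below the floor are
    clamped so the result stays finite.
    """
    v = np.asarray(variance, dtype=np.float64)
    if np.any(v < 0):
        raise ValueError("variance must be non-negative")
    out = 0.5 * (_LN_2PIE + np.log(np.maximum(v, variance_floor)))
    if np.isscalar(variance) or v.ndim == 0:
        return float(out)
    return out


def _window_starts(n_samples: int, w: int, overlap: float) -> np.ndarray:
    step = max(1, int(round(w * (1.0 - overlap))))
    last = n_samples - w
    if last < 0:
        raise ValueError(
            f"trial of {n_samples} samples is shorter than one window of {w} samples"
        )
    return np.arange(0, last + 1, step)


def trial_de(trial: Trial, cfg: DEConfig | None = None) -> np.ndarray:
    """Per-channel DE feature vector for one (already band-filtered) trial."""
    if cfg is None:
        cfg = DEConfig()
    w = cfg.window_samples(trial.sampling_rate_hz)
    starts = _window_starts(trial.n_samples, w, cfg.window_overlap)
    # (channels, windows, w) view by gather; trials are small enough to copy
    idx = starts[:, None] + np.arange(w)[None, :]
    wins = trial.data[:, idx]  # channels x windows x w
    mu = wins.mean(axis=2, keepdims=True)
    var = np.mean((wins - mu) ** 2, axis=2)  # ML estimator
    n_floored = int(np.count_nonzero(var < cfg.variance_floor))
    if n_floored:
        logger.warning(
            "trial %s: %d window variance(s) below floor %.3g; clamped",
            trial.trial_id, n_floored, cfg.variance_floor,
        )
    de = gaussian_de(var, cfg.variance_floor)
    if cfg.aggregate == "mean":
        return de.mean(axis=1)
    return np.median(de, axis=1)


def de_table(band_trials: TrialSet, band_name: str, cfg: DEConfig | None = None) -> FeatureTable:
    """DE feature table (trials x channels) for one band-filtered TrialSet."""
    rows = np.vstack([trial_de(t, cfg) for t in band_trials])
    meta = [
        FeatureColumn(channel_name=ch, band_name=band_name, feature_kind="de")
        for ch in band_trials.channel_names
    ]
    return FeatureTable(
        values=rows,
        labels=band_trials.labels,
        feature_meta=meta,
        provenance=f"de[{band_name}]",
    )


def build_de_table(
    band_sets: dict[str, TrialSet], cfg: DEConfig | None = None
) -> tuple[dict[str, FeatureTable], FeatureTable]:
    """DE tables per band plus their column-wise 'combined band' concatenation.

    Band sets must be aligned: identical trial ids, order and labels in every
    band. The combined table has channels x bands columns in bank order
    (62 x 5 = 310 for the SEED geometry).
    """
    if not band_sets:
        raise ValueError("no band sets given")
    names = list(band_sets)
    ref = band_sets[names[0]]
    ref_ids, ref_labels = ref.trial_ids, ref.labels
    for name in names[1:]:
        ts = band_sets[name]
        if ts.trial_ids != ref_ids or not np.array_equal(ts.labels, ref_labels):
            raise ValueError(
                f"band {name!r} is misaligned with band {names[0]!r}: "
                "trial order/labels differ"
            )
    tables = {name: de_table(band_sets[name], name, cfg) for name in names}
    combined = FeatureTable(
        values=np.hstack([tables[n].values for n in names]),
        labels=ref_labels,
        feature_meta=[m for n in names for m in tables[n].feature_meta],
        provenance="de[combined:" + "+".join(names) + "]",
    )
    return tables, combined
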