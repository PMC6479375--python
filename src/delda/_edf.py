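"""Minimal EDF (European Data Format) writer and an mne-backed reader.

EDF stores each signal as 16-bit integers with a per-signal physical range
declared in the header, so a write->read round-trip is exact only up to the
quantization step (physical range / 65535). Physical units are microvolts.

Writing is implemented here directly against the EDF header layout (256-byte
fixed header + 256 bytes per signal, then int16 little-endian data records);
reading delegates to :func:`mne.io.read_raw_edf`.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

_DIG_MIN = -32768
_DIG_MAX = 32767


def _ascii_field(value: str, width: int) -> bytes:
    s = value[:width]
    return s.ljust(width).encode("ascii")


def _num_field(value: float | int, width: int) -> bytes:
    if isinstance(value, (int, np.integer)):
        s = str(int(value))
    else:
        s = f"{value:.{width}g}"
        if len(s) > width:
            s = f"{value:.{max(1, width - 7)}e}"
    if len(s) > width:
        raise ValueError(f"numeric field {value!r} does not fit in {width} chars")
    return _ascii_field(s, width)


def _parse_back(field: bytes) -> float:
    """Physical min/max as the reader will see them (header-string precision)."""
    return float(field.decode("ascii").strip())


def edf_quantization_step(data: np.ndarray) -> float:
    """Worst-case round-trip error bound for one channel's physical range."""
    pmin, pmax = _phys_range(data)
    return (pmax - pmin) / (_DIG_MAX - _DIG_MIN)


def _phys_range(x: np.ndarray) -> tuple[float, float]:
    """Symmetric physical range covering the data, representable in 8 chars.

    The range is rounded *up* at a precision that fits the header field, so
    no sample is ever clipped; writer and reader then share the exact
    header-string value.
    """
    amp = float(np.max(np.abs(x))) if x.size else 0.0
    if amp == 0.0:
        amp = 1.0
    amp *= 1.0 + 1e-4  # keep extreme samples strictly inside the range
    for prec in (6, 5, 4, 3, 2, 1):
        for cand in (amp, amp * (1.0 + 2.0 * 10.0 ** (-prec))):
            s = f"{cand:.{prec}g}"
            if len(s) <= 7 and float(s) >= amp:  # leave room for the '-'
                v = float(s)
                return -v, v
    raise ValueError(f"cannot represent physical range {amp} in an EDF header field")


def write_edf(
    path: str | os.PathLike,
    data_uv: np.ndarray,
    sampling_rate_hz: float,
    channel_names: list[str],
    *,
    patient_id: str = "X",
    recording_id: str = "synthetic",
) -> None:
    """Write a (channels x samples) microvolt matrix as an EDF file.

    Data records are one second long, so the sampling rate must be a positive
    integer and the sample count a multiple of it.
    """
    data_uv = np.asarray(data_uv, dtype=np.float64)
    if data_uv.ndim != 2:
        raise ValueError("data must be 2-D (channels x samples)")
    n_ch, n_s = data_uv.shape
    if len(channel_names) != n_ch:
        raise ValueError(f"{len(channel_names)} names for {n_ch} channels")
    fs = int(sampling_rate_hz)
    if fs != sampling_rate_hz or fs <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    if n_s % fs != 0:
        raise ValueError(
            f"sample count {n_s} is not a whole number of 1-s records at {fs} Hz"
        )
    n_records = n_s // fs

    phys = [_phys_range(data_uv[c]) for c in range(n_ch)]
    pmin_fields = [_num_field(p[0], 8) for p in phys]
    pmax_fields = [_num_field(p[1], 8) for p in phys]
    # use the header-string values for scaling so writer and reader agree
    pmins = [_parse_back(f) for f in pmin_fields]
    pmaxs = [_parse_back(f) for f in pmax_fields]

    header_bytes = 256 * (1 + n_ch)
    head = b"".join(
        [
            _ascii_field("0", 8),
            _ascii_field(patient_id, 80),
            _ascii_field(recording_id, 80),
            _ascii_field("01.01.00", 8),
            _ascii_field("00.00.00", 8),
            _num_field(header_bytes, 8),
            _ascii_field("", 44),
            _num_field(n_records, 8),
            _num_field(1, 8),
            _num_field(n_ch, 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_ascii_field(n, 16) for n in channel_names),
            b"".join(_ascii_field("", 80) for _ in range(n_ch)),
            b"".join(_ascii_field("uV", 8) for _ in range(n_ch)),
            b"".join(pmin_fields),
            b"".join(pmax_fields),
            b"".join(_num_field(_DIG_MIN, 8) for _ in range(n_ch)),
            b"".join(_num_field(_DIG_MAX, 8) for _ in range(n_ch)),
            b"".join(_ascii_field("", 80) for _ in range(n_ch)),
            b"".join(_num_field(fs, 8) for _ in range(n_ch)),
            b"".join(_ascii_field("", 32) for _ in range(n_ch)),
        ]
    )

    scales = np.array(
        [(_DIG_MAX - _DIG_MIN) / (pmaxs[c] - pmins[c]) for c in range(n_ch)]
    )
    offsets = np.array(pmins)
    digital = np.rint(
        (data_uv - offsets[:, None]) * scales[:, None] + _DIG_MIN
    )
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(head)
        fh.write(sig)
        # record-major layout: for each 1-s record, each channel's fs samples
        rec = digital.reshape(n_ch, n_records, fs).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(rec).tobytes())


def read_edf(path: str | os.PathLike) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file; returns (data in microvolts, sampling rate, names)."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise ValueError(f"unreadable EDF file {path}: {exc}") from exc
    data = raw.get_data(units="uV")
    return np.asarray(data, dtype=np.float64), float(raw.info["sfreq"]), list(raw.ch_names)
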