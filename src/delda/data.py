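"""Domain containers for EEG trials and feature tables, plus file I/O.

A :class:`Trial` holds one labeled multichannel EEG segment (channels x
samples at a known sampling rate); a :class:`TrialSet` is an ordered,
homogeneous collection of trials; a :class:`FeatureTable` is the
trials x features matrix handed to the reduction / classification stages,
with per-column provenance (channel, band, feature kind).

Raw trials interchange as EDF (European Data Format) files with a
delimited-text label sidecar; feature tables interchange as TSV (or, for
large runs, NumPy ``.npz``).
"""

from __future__ import annotations

import io as _io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._edf import read_edf, write_edf

#: default class order: negative=0, neutral=1, positive=2
DEFAULT_CLASS_NAMES: tuple[str, ...] = ("negative", "neutral", "positive")


class FeatureColumn(NamedTuple):
    """Provenance of one feature-table column."""

    channel_name: str
    band_name: str
    feature_kind: str  # one of {"raw", "de", "lda_component"}


@dataclass
class Trial:
    """One labeled multichannel EEG segment.

    ``data`` is a real matrix of shape (channels, samples). The segment must
    be at least two seconds long so that at least one differential-entropy
    window exists under the default 1-s windowing.
    """

    trial_id: str
    subject_id: str
    session_id: str
    label: int
    sampling_rate_hz: float
    data: np.ndarray
    channel_names: Sequence[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(
                f"trial {self.trial_id!r}: data must be 2-D (channels x samples), "
                f"got ndim={self.data.ndim}"
            )
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        n_ch, n_s = self.data.shape
        if n_ch < 1:
            raise ValueError("trial must have at least one channel")
        if len(self.channel_names) != n_ch:
            raise ValueError(
                f"trial {self.trial_id!r}: {len(self.channel_names)} channel names "
                f"for {n_ch} data rows"
            )
        if n_s < 2 * self.sampling_rate_hz:
            raise ValueError(
                f"trial {self.trial_id!r}: {n_s} samples is shorter than 2 s at "
                f"{self.sampling_rate_hz} Hz"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"trial {self.trial_id!r}: non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_seconds(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def copy_with(self, data: np.ndarray) -> "Trial":
        """Same identity/labeling, new sample matrix (used by filters)."""
        return Trial(
            trial_id=self.trial_id,
            subject_id=self.subject_id,
            session_id=self.session_id,
            label=self.label,
            sampling_rate_hz=self.sampling_rate_hz,
            data=data,
            channel_names=list(self.channel_names),
        )


@dataclass
class TrialSet:
    """Ordered collection of trials sharing geometry and class vocabulary."""

    trials: list[Trial]
    class_names: Sequence[str] = DEFAULT_CLASS_NAMES

    def __post_init__(self) -> None:
        if self.trials:
            fs = self.trials[0].sampling_rate_hz
            n_ch = self.trials[0].n_channels
            for t in self.trials:
                if t.sampling_rate_hz != fs:
                    raise ValueError(
                        f"mixed sampling rates: {t.sampling_rate_hz} vs {fs} "
                        f"(trial {t.trial_id!r})"
                    )
                if t.n_channels != n_ch:
                    raise ValueError(
                        f"channel-count mismatch: trial {t.trial_id!r} has "
                        f"{t.n_channels} channels, expected {n_ch}"
                    )
                if not 0 <= t.label < len(self.class_names):
                    raise ValueError(
                        f"trial {t.trial_id!r}: label {t.label} outside "
                        f"class vocabulary of size {len(self.class_names)}"
                    )

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def labels(self) -> np.ndarray:
        return np.array([t.label for t in self.trials], dtype=np.int64)

    @property
    def trial_ids(self) -> list[str]:
        return [t.trial_id for t in self.trials]

    @property
    def sampling_rate_hz(self) -> float:
        if not self.trials:
            raise ValueError("empty TrialSet has no sampling rate")
        return self.trials[0].sampling_rate_hz

    @property
    def n_channels(self) -> int:
        if not self.trials:
            raise ValueError("empty TrialSet has no channel count")
        return self.trials[0].n_channels

    @property
    def channel_names(self) -> list[str]:
        return list(self.trials[0].channel_names)


@dataclass
class BandSpec:
    """Named frequency interval in Hz, e.g. Alpha = [8, 13]."""

    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.lo_hz < self.hi_hz):
            raise ValueError(
                f"band {self.name!r}: need 0 < lo < hi, got [{self.lo_hz}, {self.hi_hz}]"
            )


@dataclass
class FeatureTable:
    """Trials x features matrix with per-column provenance and labels."""

    values: np.ndarray
    labels: np.ndarray
    feature_meta: list[FeatureColumn]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (trials x features)")
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError(
                f"{self.values.shape[0]} rows but {self.labels.shape[0]} labels"
            )
        if self.values.shape[1] != len(self.feature_meta):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.feature_meta)} "
                "feature_meta entries"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(np.asarray(self.values, dtype=float)))
            r, c = bad[0]
            raise ValueError(f"non-finite value at row {r}, column {c}")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def column_names(self) -> list[str]:
        return [
            f"{m.feature_kind}:{m.band_name}:{m.channel_name}" for m in self.feature_meta
        ]


def concat_feature_tables(tables: Sequence[FeatureTable], provenance: str) -> FeatureTable:
    """Column-wise concatenation of aligned tables (the 'combined band')."""
    if not tables:
        raise ValueError("nothing to concatenate")
    labels = tables[0].labels
    for t in tables[1:]:
        if not np.array_equal(t.labels, labels):
            raise ValueError("cannot concatenate tables with differing labels")
    values = np.hstack([t.values for t in tables])
    meta = [m for t in tables for m in t.feature_meta]
    return FeatureTable(values=values, labels=labels, feature_meta=meta, provenance=provenance)


# ---------------------------------------------------------------------------
# EDF trials + label sidecar
# ---------------------------------------------------------------------------

def read_label_sidecar(path: str | os.PathLike) -> pd.DataFrame:
    """Read the delimited label sidecar (columns: file, subject, session, label)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"file", "subject", "session", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"label sidecar {path}: missing columns {sorted(missing)}")
    return df


def write_label_sidecar(path: str | os.PathLike, rows: Iterable[dict]) -> None:
    df = pd.DataFrame(list(rows), columns=["file", "subject", "session", "label"])
    df.to_csv(path, sep="\t", index=False)


def read_edf_trials(
    edf_paths: Sequence[str | os.PathLike],
    label_sidecar: str | os.PathLike,
    class_names: Sequence[str] = DEFAULT_CLASS_NAMES,
) -> TrialSet:
    """Read one Trial per EDF file, labeled via the sidecar.

    Channel order is taken from the first file and enforced on the rest;
    mixed sampling rates or channel counts are an error, as is any EDF
    missing from the sidecar.
    """
    if not edf_paths:
        raise ValueError("no EDF paths given")
    side = read_label_sidecar(label_sidecar)
    by_file = {row["file"]: row for _, row in side.iterrows()}
    name_to_code = {n: i for i, n in enumerate(class_names)}

    trials: list[Trial] = []
    ref_names: list[str] | None = None
    ref_fs: float | None = None
    for p in edf_paths:
        p = Path(p)
        key = p.name
        if key not in by_file:
            raise ValueError(f"label sidecar has no entry for file {key!r}")
        row = by_file[key]
        raw_label = row["label"]
        if raw_label in name_to_code:
            label = name_to_code[raw_label]
        else:
            try:
                label = int(raw_label)
            except ValueError:
                raise ValueError(
                    f"file {key!r}: label {raw_label!r} is neither a class name "
                    f"{list(class_names)} nor an integer code"
                ) from None
        data, fs, ch_names = read_edf(p)
        if ref_names is None:
            ref_names, ref_fs = ch_names, fs
        else:
            if fs != ref_fs:
                raise ValueError(f"file {key!r}: sampling rate {fs} differs from {ref_fs}")
            if len(ch_names) != len(ref_names):
                raise ValueError(
                    f"file {key!r}: {len(ch_names)} channels, expected {len(ref_names)}"
                )
            if ch_names != ref_names:
                order = [ch_names.index(n) for n in ref_names]
                data = data[order]
        trials.append(
            Trial(
                trial_id=p.stem,
                subject_id=str(row["subject"]),
                session_id=str(row["session"]),
                label=label,
                sampling_rate_hz=fs,
                data=data,
                channel_names=list(ref_names),
            )
        )
    return TrialSet(trials=trials, class_names=tuple(class_names))


def write_edf_trials(trial_set: TrialSet, out_dir: str | os.PathLike) -> tuple[list[Path], Path]:
    """Write one EDF per trial plus the label sidecar; returns (paths, sidecar)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    rows = []
    for t in trial_set:
        p = out_dir / f"{t.trial_id}.edf"
        write_edf(p, t.data, t.sampling_rate_hz, list(t.channel_names))
        paths.append(p)
        rows.append(
            {
                "file": p.name,
                "subject": t.subject_id,
                "session": t.session_id,
                "label": trial_set.class_names[t.label],
            }
        )
    sidecar = out_dir / "labels.tsv"
    write_label_sidecar(sidecar, rows)
    return paths, sidecar


# ---------------------------------------------------------------------------
# Feature-table I/O (TSV with a provenance header line; .npz for large runs)
# ---------------------------------------------------------------------------

_PROV_PREFIX = "# provenance: "


def write_feature_table(table: FeatureTable, path: str | os.PathLike) -> None:
    """Write a feature table; TSV for ``.tsv``/``.txt``, NumPy npz for ``.npz``.

    The TSV carries one comment line with the provenance string, then a header
    row of ``kind:band:channel`` column names plus a leading ``label`` column.
    """
    path = Path(path)
    if path.suffix == ".npz":
        meta = np.array(
            [[m.channel_name, m.band_name, m.feature_kind] for m in table.feature_meta],
            dtype=str,
        )
        np.savez_compressed(
            path,
            values=table.values,
            labels=table.labels,
            feature_meta=meta,
            provenance=np.array(table.provenance),
        )
        return
    names = table.column_names
    if len(set(names)) != len(names):
        raise ValueError(
            "feature table has duplicate (kind, band, channel) columns; "
            "the TSV format requires unique column names"
        )
    df = pd.DataFrame(table.values, columns=names)
    df.insert(0, "label", table.labels)
    with open(path, "w") as fh:
        fh.write(_PROV_PREFIX + table.provenance.replace("\n", " ") + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_feature_table(path: str | os.PathLike) -> FeatureTable:
    """Inverse of :func:`write_feature_table` (lossless for labels/metadata,
    <= 1e-12 relative for values in the TSV route)."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            meta = [FeatureColumn(*row) for row in z["feature_meta"]]
            return FeatureTable(
                values=z["values"],
                labels=z["labels"],
                feature_meta=meta,
                provenance=str(z["provenance"]),
            )
    with open(path) as fh:
        first = fh.readline()
        if not first:
            raise ValueError(f"{path}: empty feature-table file")
        if first.startswith(_PROV_PREFIX):
            provenance = first[len(_PROV_PREFIX):].rstrip("\n")
            body = fh.read()
        else:
            provenance = ""
            body = first + fh.read()
    if not body.strip():
        raise ValueError(f"{path}: feature-table file has no header row")
    try:
        df = pd.read_csv(_io.StringIO(body), sep="\t")
    except Exception as exc:  # malformed header / ragged rows
        raise ValueError(f"{path}: cannot parse feature table: {exc}") from exc
    if "label" not in df.columns:
        raise ValueError(f"{path}: header line 2 lacks the 'label' column")
    labels = df.pop("label").to_numpy(dtype=np.int64)
    meta: list[FeatureColumn] = []
    for col in df.columns:
        parts = col.split(":", 2)
        if len(parts) != 3:
            raise ValueError(
                f"{path}: malformed feature column name {col!r} "
                "(expected kind:band:channel)"
            )
        kind, band, channel = parts
        meta.append(FeatureColumn(channel_name=channel, band_name=band, feature_kind=kind))
    values = df.to_numpy(dtype=np.float64)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: non-finite value at data row {r}, column {df.columns[c]!r}"
        )
    return FeatureTable(values=values, labels=labels, feature_meta=meta, provenance=provenance)
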