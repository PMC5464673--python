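"""Input/output layer: spike tables, LFP matrices, and result tables.

Every downstream module consumes the two container types defined here.
Spike tables are delimited text with a configurable *dialect* (column names,
time unit, separator), because deposited multi-electrode datasets do not share
a single layout.  LFP is stored either as a flat binary matrix with a JSON
sidecar header or, for small fixtures, as TSV.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeRecording",
    "LfpMatrix",
    "SpikeDialect",
    "read_spike_dataset",
    "write_spike_dataset",
    "read_lfp",
    "write_lfp",
    "write_results",
    "read_results",
    "FormatError",
]


class FormatError(ValueError):
    """Raised when an input file does not match the declared dialect."""


@dataclass(frozen=True)
class SpikeDialect:
    """Column/units mapping for a delimited spike table.

    The default matches the package's own output: tab-separated columns
    ``electrode``, ``time_s`` and (optionally) ``state``, times in seconds.
    """

    electrode_column: str = "electrode"
    time_column: str = "time_s"
    state_column: str | None = "state"
    time_unit: float = 1.0  # seconds per unit in the file (1e-3 for ms)
    sep: str = "\t"


@dataclass
class SpikeRecording:
    """Per-electrode spike times with optional per-second state labels.

    Parameters
    ----------
    electrode_id
        Integer electrode label per spike.
    time
        Spike time in seconds per spike, globally sorted, all in
        ``[0, duration)``.
    duration
        Recording length in seconds.
    segment_labels
        Optional state label per 1 s segment ``[k, k+1)``; length must equal
        ``floor(duration)``.
    """

    electrode_id: np.ndarray
    time: np.ndarray
    duration: float
    segment_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.electrode_id = np.asarray(self.electrode_id, dtype=np.int64)
        self.time = np.asarray(self.time, dtype=np.float64)
        if self.electrode_id.shape != self.time.shape:
            raise ValueError("electrode_id and time must have equal length")
        if self.time.size:
            if self.time.min() < 0:
                raise ValueError("negative spike times")
            if self.time.max() >= self.duration:
                raise ValueError("spike time at or beyond duration")
            order = np.lexsort((self.electrode_id, self.time))
            self.time = self.time[order]
            self.electrode_id = self.electrode_id[order]
        if self.segment_labels is not None:
            self.segment_labels = np.asarray(self.segment_labels)
            if len(self.segment_labels) != int(np.floor(self.duration)):
                raise ValueError(
                    "segment_labels length must equal floor(duration)"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.time.size)

    @property
    def n_sites(self) -> int:
        """Number of distinct electrodes that fired."""
        return int(np.unique(self.electrode_id).size)

    @property
    def sites(self) -> np.ndarray:
        return np.unique(self.electrode_id)

    def spikes_of(self, electrode: int) -> np.ndarray:
        """Sorted spike times of one electrode."""
        return self.time[self.electrode_id == electrode]

    def segment_of(self, t: np.ndarray) -> np.ndarray:
        """Map times to 0-based 1 s segment indices (half-open [k, k+1))."""
        return np.floor(t).astype(np.int64)

    def state_segments(self, state) -> np.ndarray:
        """Indices of 1 s segments carrying the given state label."""
        if self.segment_labels is None:
            raise ValueError("recording has no segment labels")
        return np.flatnonzero(self.segment_labels == state)


@dataclass
class LfpMatrix:
    """Multichannel field-potential samples (channels x time)."""

    samples: np.ndarray
    fs: float = 1000.0
    channel_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.channel_ids is None:
            self.channel_ids = np.arange(self.samples.shape[0])
        else:
            self.channel_ids = np.asarray(self.channel_ids, dtype=np.int64)
            if self.channel_ids.size != self.samples.shape[0]:
                raise ValueError("channel_ids length != number of channels")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def zscored(self) -> "LfpMatrix":
        """Per-channel z-scored copy (zero-variance channels left at zero)."""
        x = self.samples - self.samples.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return LfpMatrix(x / sd, fs=self.fs, channel_ids=self.channel_ids.copy())


# ---------------------------------------------------------------------------
# spike tables


def read_spike_dataset(
    path,
    dialect: SpikeDialect = SpikeDialect(),
    duration: float | None = None,
) -> SpikeRecording:
    """Read a delimited spike table into a validated :class:`SpikeRecording`.

    ``duration`` defaults to the next whole second past the last spike (or the
    last labeled segment).  Per-spike state labels, when present, are mapped
    onto 1 s segments by majority vote; unlabeled segments inherit the nearest
    labeled neighbour (forward fill, then backward).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=dialect.sep)
    for col in (dialect.electrode_column, dialect.time_column):
        if col not in df.columns:
            raise FormatError(f"spike table {path} lacks column {col!r}")
    t = df[dialect.time_column].to_numpy(dtype=np.float64) * dialect.time_unit
    if t.size and t.min() < 0:
        raise ValueError("negative spike times in table")
    elec = df[dialect.electrode_column].to_numpy(dtype=np.int64)
    if duration is None:
        duration = float(np.ceil(t.max() + 1e-9)) if t.size else 1.0
        duration = max(duration, 1.0)

    labels = None
    if dialect.state_column is not None and dialect.state_column in df.columns:
        n_seg = int(np.floor(duration))
        seg = np.floor(t).astype(np.int64)
        lab = df[dialect.state_column].astype(str).to_numpy()
        ser = (
            pd.DataFrame({"seg": seg, "lab": lab})
            .groupby("seg")["lab"]
            .agg(lambda s: s.mode().iloc[0])
        )
        full = ser.reindex(range(n_seg)).ffill().bfill()
        labels = full.to_numpy(dtype=object)
    return SpikeRecording(elec, t, duration=float(duration), segment_labels=labels)


def write_spike_dataset(
    rec: SpikeRecording, path, dialect: SpikeDialect = SpikeDialect()
) -> Path:
    """Write a recording in the given spike-table dialect."""
    path = Path(path)
    cols = {
        dialect.electrode_column: rec.electrode_id,
        dialect.time_column: rec.time / dialect.time_unit,
    }
    df = pd.DataFrame(cols)
    if dialect.state_column is not None and rec.segment_labels is not None:
        seg = np.clip(
            np.floor(rec.time).astype(np.int64), 0, len(rec.segment_labels) - 1
        )
        df[dialect.state_column] = np.asarray(rec.segment_labels)[seg]
    df.to_csv(path, sep=dialect.sep, index=False)
    return path


def write_labels(labels, path) -> Path:
    """Write per-segment state labels as a two-column TSV."""
    path = Path(path)
    pd.DataFrame(
        {"segment": np.arange(len(labels)), "state": np.asarray(labels)}
    ).to_csv(path, sep="\t", index=False)
    return path


def read_labels(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df.sort_values("segment")["state"].to_numpy(dtype=object)


# ---------------------------------------------------------------------------
# LFP


def write_lfp(lfp: LfpMatrix, path) -> Path:
    """Write LFP as float32 flat binary plus a JSON sidecar header."""
    path = Path(path)
    lfp.samples.astype(np.float32).tofile(path)
    header = {
        "n_channels": lfp.n_channels,
        "n_samples": lfp.n_samples,
        "fs": lfp.fs,
        "dtype": "float32",
        "channel_ids": [int(c) for c in lfp.channel_ids],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(header))
    return path


def read_lfp(path) -> LfpMatrix:
    """Read LFP written by :func:`write_lfp` (binary + JSON sidecar)."""
    path = Path(path)
    header = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.fromfile(path, dtype=header["dtype"])
    samples = data.reshape(header["n_channels"], header["n_samples"])
    return LfpMatrix(
        samples.astype(np.float64),
        fs=header["fs"],
        channel_ids=np.asarray(header["channel_ids"]),
    )


# ---------------------------------------------------------------------------
# result tables


def write_results(tables: dict[str, pd.DataFrame], path) -> list[Path]:
    """Write named result tables as TSV files (one per table) under ``path``.

    Floats are written with full repr precision so that
    ``read_results(write_results(x)) == x`` bit-exactly.
    """
    out = Path(path)
    if not tables:
        warnings.warn("write_results called with no tables; nothing written")
        return []
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written.append(p)
        logger.info("wrote %s (%d rows)", p, len(df))
    return written


def read_results(path) -> dict[str, pd.DataFrame]:
    """Read back a directory of TSV result tables."""
    out = Path(path)
    return {p.stem: pd.read_csv(p, sep="\t") for p in sorted(out.glob("*.tsv"))}
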