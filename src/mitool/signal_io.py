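"""Containers and I/O for epoched multichannel EEG.

The in-memory unit is microvolts throughout the package.  EDF files are read
with :mod:`mne` (the physical-dimension field is honored and converted to µV);
a minimal 16-bit EDF writer is provided so fixtures and synthetic recordings
can be produced without an external exporter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml


class FormatError(ValueError):
    """Raised for unreadable or unsupported on-disk data."""


@dataclass
class EpochSet:
    """Labeled multichannel signal epochs.

    Parameters
    ----------
    data : ndarray, shape (n_epochs, n_channels, n_samples)
        Signal in µV.
    labels : ndarray of int, shape (n_epochs,)
        Class id per epoch, values in a contiguous set {1..K}.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError(f"data must be epochs × channels × samples, got shape {self.data.shape}")
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError("labels must have one entry per epoch")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.data.shape[0] > 0 and self.data.shape[2] < 2:
            raise ValueError("epochs must contain at least 2 samples")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must match channel count")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def classes(self) -> np.ndarray:
        """Sorted unique class ids present."""
        return np.unique(self.labels)

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Subset of epochs by boolean mask or index array."""
        return EpochSet(self.data[mask], self.labels[mask], self.fs, list(self.channel_names))

    def copy_with(self, data: np.ndarray) -> "EpochSet":
        """Same metadata, new data array (shape-checked by the constructor)."""
        return EpochSet(data, self.labels.copy(), self.fs, list(self.channel_names))


@dataclass
class Montage:
    """Channel names plus scalp-neighbor structure for Laplacian filtering.

    ``neighbors[i]`` lists neighbor channel indices of channel ``i`` (never
    including ``i`` itself); ``distances``, when given, maps ``(i, j)`` pairs
    to scalp distances in cm and must be symmetric and positive.
    """

    channel_names: list[str]
    neighbors: list[list[int]] = field(default_factory=list)
    distances: dict[tuple[int, int], float] | None = None

    def __post_init__(self) -> None:
        n = len(self.channel_names)
        if not self.neighbors:
            self.neighbors = [[] for _ in range(n)]
        if len(self.neighbors) != n:
            raise ValueError("neighbors must have one list per channel")
        for i, nb in enumerate(self.neighbors):
            for j in nb:
                if not 0 <= j < n:
                    raise ValueError(f"channel {i}: neighbor index {j} out of range")
                if j == i:
                    raise ValueError(f"channel {i} listed as its own neighbor")
        if self.distances is not None:
            sym = dict(self.distances)
            for (i, j), d in self.distances.items():
                if d <= 0:
                    raise ValueError(f"distance for pair ({i},{j}) must be positive")
                other = sym.get((j, i))
                if other is None:
                    sym[(j, i)] = d
                elif abs(other - d) > 1e-9:
                    raise ValueError(f"distances for ({i},{j}) and ({j},{i}) disagree")
            self.distances = sym

    def distance(self, i: int, j: int) -> float:
        if self.distances is None:
            raise ValueError("montage has no distances")
        return self.distances[(i, j)]

    @classmethod
    def from_file(cls, path: str | Path) -> "Montage":
        """Load a montage from a YAML/JSON document.

        Schema: ``{channels: [...], neighbors: {name: [name, ...]},
        distances: {"A-B": cm}}``.
        """
        path = Path(path)
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        names = list(doc["channels"])
        idx = {name: k for k, name in enumerate(names)}
        neighbors = [[] for _ in names]
        for name, nbs in (doc.get("neighbors") or {}).items():
            neighbors[idx[name]] = [idx[nb] for nb in nbs]
        distances = None
        if doc.get("distances"):
            distances = {}
            for key, cm in doc["distances"].items():
                a, b = key.split("-")
                distances[(idx[a], idx[b])] = float(cm)
        return cls(names, neighbors, distances)

    def to_file(self, path: str | Path) -> None:
        doc: dict = {"channels": list(self.channel_names)}
        doc["neighbors"] = {
            self.channel_names[i]: [self.channel_names[j] for j in nb]
            for i, nb in enumerate(self.neighbors)
            if nb
        }
        if self.distances:
            doc["distances"] = {
                f"{self.channel_names[i]}-{self.channel_names[j]}": float(d)
                for (i, j), d in self.distances.items()
                if i < j
            }
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix == ".json":
                json.dump(doc, fh, indent=2)
            else:
                yaml.safe_dump(doc, fh)


# ---------------------------------------------------------------------------
# EDF


def read_edf(path: str | Path) -> tuple[EpochSet, Montage]:
    """Read an EDF/EDF+ recording as a single continuous epoch.

    Returns the recording (1 × channels × samples, µV, channel order
    preserved) and a names-only :class:`Montage`.  Mixed per-channel sampling
    rates are not supported.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types for corrupt files
        raise FormatError(f"could not read EDF file {path}: {exc}") from exc
    sfreqs = {int(round(raw.info["sfreq"]))}
    if len(sfreqs) != 1:
        raise FormatError(f"{path}: mixed per-channel sampling rates are unsupported")
    data_uv = raw.get_data() * 1e6  # mne returns SI volts for EEG channels
    epochs = EpochSet(
        data_uv[np.newaxis],
        labels=np.zeros(1, dtype=int) + 1,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
    )
    return epochs, Montage(list(raw.ch_names))


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, data_uv: np.ndarray, fs: float, channel_names: Sequence[str]) -> None:
    """Write a channels × samples µV array as a minimal EDF file.

    Single data record spanning the full signal, 16-bit samples, physical
    dimension ``uV``.  Amplitude resolution is the physical range divided by
    the 16-bit digital span.
    """
    data_uv = np.asarray(data_uv, dtype=float)
    if data_uv.ndim != 2:
        raise ValueError("data must be channels × samples")
    n_ch, n_samp = data_uv.shape
    duration = n_samp / fs
    dur_str = f"{duration:.6f}".rstrip("0").rstrip(".")[:8]

    phys_max = max(float(np.max(np.abs(data_uv))), 1.0)
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (2 * phys_max)
    digital = np.clip(np.round((data_uv + phys_max) * scale) + dig_min, dig_min, dig_max).astype("<i2")

    header = b""
    header += _edf_field("0", 8)
    header += _edf_field("X X X X", 80)
    header += _edf_field("Startdate 01-JAN-2000 X X X", 80)
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(256 * (n_ch + 1), 8)
    header += _edf_field("", 44)
    header += _edf_field(1, 8)  # one data record
    header += _edf_field(dur_str, 8)
    header += _edf_field(n_ch, 4)
    for name in channel_names:
        header += _edf_field(name, 16)
    header += _edf_field("", 80) * n_ch
    header += _edf_field("uV", 8) * n_ch
    header += _edf_field(f"{-phys_max:.3f}"[:8], 8) * n_ch
    header += _edf_field(f"{phys_max:.3f}"[:8], 8) * n_ch
    header += _edf_field(dig_min, 8) * n_ch
    header += _edf_field(dig_max, 8) * n_ch
    header += _edf_field("", 80) * n_ch
    header += _edf_field(n_samp, 8) * n_ch
    header += _edf_field("", 32) * n_ch

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())


# ---------------------------------------------------------------------------
# Delimited text


def read_delimited(
    path: str | Path,
    fs: float,
    layout: str = "channels-as-rows",
    delimiter: str | None = None,
) -> EpochSet:
    """Read a numeric delimited-text matrix as a single continuous epoch.

    ``layout`` states the on-disk orientation; the returned array is always
    channels × samples.  A non-numeric cell raises a parse error naming its
    row and column.
    """
    if layout not in ("channels-as-rows", "channels-as-columns"):
        raise ValueError(f"unknown layout {layout!r}")
    rows: list[list[float]] = []
    with open(path) as fh:
        for r, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            cells = line.split(delimiter) if delimiter else line.replace(",", " ").split()
            row = []
            for c, cell in enumerate(cells):
                try:
                    row.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric cell {cell!r} at row {r + 1}, column {c + 1}"
                    ) from None
            rows.append(row)
    if not rows:
        raise FormatError(f"{path}: empty table")
    if len({len(r) for r in rows}) != 1:
        raise FormatError(f"{path}: ragged rows")
    mat = np.asarray(rows, dtype=float)
    if layout == "channels-as-columns":
        mat = mat.T
    names = [f"ch{i + 1}" for i in range(mat.shape[0])]
    return EpochSet(mat[np.newaxis], np.ones(1, dtype=int), fs, names)


def epoch(
    continuous: EpochSet,
    onsets: Sequence[int],
    length: int,
    labels: Sequence[int],
) -> EpochSet:
    """Cut labeled epochs out of a continuous recording.

    Windows are half-open ``[onset, onset + length)`` in 0-based samples.
    """
    if len(onsets) != len(labels):
        raise ValueError("onsets and labels must have equal length")
    if continuous.n_epochs != 1:
        raise ValueError("continuous input must hold exactly one epoch")
    rec = continuous.data[0]
    n = rec.shape[1]
    if len(onsets) == 0:
        empty = np.empty((0, continuous.n_channels, length), dtype=float)
        return EpochSet(empty, np.empty(0, dtype=int), continuous.fs, list(continuous.channel_names))
    out = np.empty((len(onsets), continuous.n_channels, length), dtype=float)
    for e, onset in enumerate(onsets):
        if onset < 0 or onset + length > n:
            raise IndexError(
                f"epoch window [{onset}, {onset + length}) exceeds the {n}-sample record"
            )
        out[e] = rec[:, onset : onset + length]
    return EpochSet(out, np.asarray(labels, dtype=int), continuous.fs, list(continuous.channel_names))
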