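"""Spatial re-referencing and frequency-domain filtering.

Two spatial filters are provided: the common average reference (each channel
minus the instantaneous mean of all channels) and the small Laplacian (each
channel minus a weighted average of its scalp neighbors, weights either
uniform over exactly four neighbors or inverse-distance normalized).
Frequency-domain filtering covers the motor-imagery band (default 8–26 Hz,
covering the µ and β rhythms) and 50 Hz line-noise notching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signal_io import EpochSet, Montage


@dataclass
class FilterSpec:
    """Rational transfer function H(z) = numerator(z) / denominator(z).

    FIR filters have a denominator of [1]; IIR filters must be stable (all
    poles strictly inside the unit circle).
    """

    kind: str  # "FIR" | "IIR"
    numerator: np.ndarray
    denominator: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.numerator = np.atleast_1d(np.asarray(self.numerator, dtype=float))
        self.denominator = np.atleast_1d(np.asarray(self.denominator, dtype=float))
        if abs(self.denominator[0] - 1.0) > 1e-12:
            raise ValueError("denominator leading coefficient must be 1")
        is_fir = self.denominator.size == 1
        if self.kind == "FIR" and not is_fir:
            raise ValueError("FIR spec must have a trivial denominator")
        if self.kind == "IIR":
            if is_fir:
                raise ValueError("IIR spec needs a non-trivial denominator")
            poles = np.roots(self.denominator)
            if np.any(np.abs(poles) >= 1.0):
                raise ValueError("unstable IIR design: pole on or outside the unit circle")
        if self.kind not in ("FIR", "IIR"):
            raise ValueError(f"kind must be FIR or IIR, got {self.kind!r}")

    @property
    def order(self) -> int:
        return max(self.numerator.size, self.denominator.size) - 1

    def response(self, freqs_hz: np.ndarray, fs: float) -> np.ndarray:
        """Complex frequency response at the given frequencies."""
        _, h = sps.freqz(self.numerator, self.denominator, worN=np.atleast_1d(freqs_hz), fs=fs)
        return h


def car(epochs: EpochSet) -> EpochSet:
    """Common average reference: subtract the cross-channel mean per sample."""
    if epochs.n_channels < 2:
        raise ValueError("CAR is undefined for single-channel data")
    out = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return epochs.copy_with(out)


def laplacian(epochs: EpochSet, montage: Montage, mode: str = "four-neighbor-mean") -> EpochSet:
    """Small Laplacian re-reference.

    ``four-neighbor-mean`` subtracts the plain average of exactly four
    neighbors; ``distance-weighted`` uses weights g_ij = (1/d_ij) / Σ(1/d_ij)
    over the neighbor set, which sum to one per channel.
    """
    if mode not in ("distance-weighted", "four-neighbor-mean"):
        raise ValueError(f"unknown Laplacian mode {mode!r}")
    if len(montage.channel_names) != epochs.n_channels:
        raise ValueError("montage channel count does not match data")
    out = np.empty_like(epochs.data)
    for i in range(epochs.n_channels):
        nb = montage.neighbors[i]
        if not nb:
            raise ValueError(f"channel {montage.channel_names[i]!r} has no neighbors in the montage")
        if mode == "four-neighbor-mean":
            if len(nb) != 4:
                raise ValueError(
                    f"four-neighbor Laplacian requires exactly 4 neighbors, channel "
                    f"{montage.channel_names[i]!r} has {len(nb)}"
                )
            weights = np.full(4, 0.25)
        else:
            if montage.distances is None:
                raise ValueError("distance-weighted Laplacian requires montage distances")
            inv = np.array([1.0 / montage.distance(i, j) for j in nb])
            weights = inv / inv.sum()
        out[:, i, :] = epochs.data[:, i, :] - np.tensordot(
            weights, epochs.data[:, nb, :], axes=(0, 1)
        )
    return epochs.copy_with(out)


def design_bandpass(low: float, high: float, fs: float, kind: str = "IIR", order: int = 4) -> FilterSpec:
    """Design a bandpass filter (Butterworth IIR or Hamming-window FIR)."""
    if not (0 < low < high < fs / 2):
        raise ValueError(f"band edges must satisfy 0 < {low} < {high} < fs/2 = {fs / 2}")
    meta = {"low_hz": low, "high_hz": high, "fs": fs, "order": order}
    if kind == "IIR":
        b, a = sps.butter(order, [low, high], btype="bandpass", fs=fs)
        return FilterSpec("IIR", b, a, {**meta, "design": "butterworth"})
    if kind == "FIR":
        numtaps = order + 1
        if numtaps % 2 == 0:
            numtaps += 1  # bandpass needs an odd-length (type I) design
        b = sps.firwin(numtaps, [low, high], pass_zero=False, fs=fs)
        return FilterSpec("FIR", b, [1.0], {**meta, "design": "firwin-hamming"})
    raise ValueError(f"kind must be FIR or IIR, got {kind!r}")


def design_notch(freq: float, fs: float, q: float = 30.0) -> FilterSpec:
    """Design an IIR notch (default for 50 Hz power-line interference)."""
    if not (0 < freq < fs / 2):
        raise ValueError(f"notch frequency {freq} outside (0, fs/2)")
    b, a = sps.iirnotch(freq, q, fs=fs)
    return FilterSpec("IIR", b, a, {"freq_hz": freq, "q": q, "fs": fs, "design": "iirnotch"})


def apply_filter(epochs: EpochSet, spec: FilterSpec, zero_phase: bool = True) -> EpochSet:
    """Filter every channel of every epoch independently.

    ``zero_phase`` applies forward-backward filtering (no phase lag, squared
    magnitude response) and requires epochs longer than 3 × the filter order.
    """
    if zero_phase:
        padlen = 3 * spec.order
        if epochs.n_samples <= padlen:
            raise ValueError(
                f"epoch length {epochs.n_samples} too short for zero-phase filtering "
                f"(needs > {padlen} samples)"
            )
        out = sps.filtfilt(spec.numerator, spec.denominator, epochs.data, axis=-1)
    else:
        out = sps.lfilter(spec.numerator, spec.denominator, epochs.data, axis=-1)
    return epochs.copy_with(out)


def preprocess(
    epochs: EpochSet,
    montage: Montage | None = None,
    config: dict | None = None,
) -> EpochSet:
    """Run the default preprocessing chain: notch → bandpass → spatial filter.

    ``config`` follows the keys ``notch {enabled, freq, q}``, ``bandpass
    {enabled, low, high, order, kind, zero_phase}``, ``spatial {method,
    laplacian_mode}``; missing keys fall back to the defaults below.
    """
    cfg = {
        "notch": {"enabled": True, "freq": 50.0, "q": 30.0},
        "bandpass": {"enabled": True, "low": 8.0, "high": 26.0, "order": 4, "kind": "IIR", "zero_phase": True},
        "spatial": {"method": "car", "laplacian_mode": "four-neighbor-mean"},
    }
    for key, sub in (config or {}).items():
        cfg.setdefault(key, {}).update(sub)
    out = epochs
    if cfg["notch"]["enabled"]:
        spec = design_notch(cfg["notch"]["freq"], epochs.fs, cfg["notch"]["q"])
        out = apply_filter(out, spec, zero_phase=True)
    if cfg["bandpass"]["enabled"]:
        bp = cfg["bandpass"]
        spec = design_bandpass(bp["low"], bp["high"], epochs.fs, bp["kind"], bp["order"])
        out = apply_filter(out, spec, zero_phase=bp["zero_phase"])
    method = cfg["spatial"]["method"]
    if method == "car":
        out = car(out)
    elif method == "laplacian":
        if montage is None:
            raise ValueError("laplacian preprocessing requires a montage")
        out = laplacian(out, montage, cfg["spatial"]["laplacian_mode"])
    elif method not in (None, "none"):
        raise ValueError(f"unknown spatial method {method!r}")
    return out
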