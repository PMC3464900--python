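"""Locating the circadian clock frequency range (CCFR) from core clock genes.

The core oscillator genes (in Arabidopsis: CCA1, LHY, PRR7, PRR9, ELF4, GI,
LUX and TOC1) keep oscillating near one cycle per day even when a stress
treatment damps or phase-shifts them, so their spectra mark where "clock"
energy lives.  Bins whose relative amplitude exceeds a threshold (default 0.7,
i.e. half-maximum power) are dominant; the union of dominant bins across the
clock genes defines the CCFR [c_min, c_max].  Within the CCFR each bin gets a
weight: the clock genes' summed power, min-max normalized — the gain curve of
a tapering band-pass filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral import AmplitudeSpectrum, Spectrum

__all__ = [
    "CORE_CLOCK_GENES",
    "ClockVector",
    "CcfrError",
    "dominant_frequencies",
    "ccfr",
    "clock_weights",
    "clock_vector_report",
]

#: Arabidopsis core circadian oscillator gene symbols, the default reference set.
CORE_CLOCK_GENES = ("CCA1", "LHY", "PRR7", "PRR9", "ELF4", "GI", "LUX", "TOC1")

DEFAULT_THRESHOLD = 0.7


class CcfrError(ValueError):
    """No clock gene shows a dominant frequency bin.

    Callers should fall back to the configured default band (one cycle per day
    plus/minus one bin) and warn, rather than proceed silently.
    """


@dataclass
class ClockVector:
    """The CCFR bin range and per-bin tapering weights for one condition/frame."""

    c_min: int
    c_max: int
    weights: np.ndarray
    summed_power: np.ndarray
    condition: str = ""
    frame_index: int = -1

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.summed_power = np.asarray(self.summed_power, dtype=float)
        if not (1 <= self.c_min <= self.c_max):
            raise ValueError("require 1 <= c_min <= c_max")
        if self.weights.size != self.c_max - self.c_min + 1:
            raise ValueError("one weight per CCFR bin required")
        if np.any((self.weights < 0) | (self.weights > 1)):
            raise ValueError("weights must lie in [0, 1]")


def dominant_frequencies(
    a: AmplitudeSpectrum, threshold: float = DEFAULT_THRESHOLD
) -> set[int]:
    """Bins (n >= 1) whose relative amplitude exceeds ``threshold``.

    Bin 0 is excluded: mean-shifting has already zeroed it, and admitting it
    would re-introduce the zero-frequency bias the shift removes.
    """
    if a.degenerate:
        return set()
    rel = a.relative_amplitudes
    return {int(n) for n in range(1, rel.size) if rel[n] > threshold}


def ccfr(
    clock_spectra: list[AmplitudeSpectrum], threshold: float = DEFAULT_THRESHOLD
) -> tuple[int, int]:
    """CCFR bounds: min and max over the union of the genes' dominant bins."""
    union: set[int] = set()
    for a in clock_spectra:
        union |= dominant_frequencies(a, threshold)
    if not union:
        raise CcfrError(
            "no clock gene has a dominant frequency bin; fall back to the "
            "configured default band"
        )
    return min(union), max(union)


def clock_weights(
    clock_spectra: list[Spectrum],
    c_min: int,
    c_max: int,
    condition: str = "",
    frame_index: int = -1,
) -> ClockVector:
    """Min-max-normalized summed clock-gene power per CCFR bin.

    w_n = (P_n - min P) / (max P - min P) with P_n = sum_m |G_mn|^2 over the
    clock genes.  A single-bin CCFR (or equal power everywhere) makes the
    normalization 0/0; the band must still pass its component(s), so all
    weights are then 1.
    """
    n_bins = clock_spectra[0].N // 2
    if not (1 <= c_min <= c_max <= n_bins):
        raise ValueError(f"CCFR [{c_min}, {c_max}] outside spectrum bins [1, {n_bins}]")
    bins = np.arange(c_min, c_max + 1)
    power = np.zeros(bins.size)
    for sp in clock_spectra:
        power += np.abs(sp.coefficients[bins]) ** 2
    lo, hi = power.min(), power.max()
    if hi - lo <= 0:
        weights = np.ones_like(power)
    else:
        weights = (power - lo) / (hi - lo)
    return ClockVector(c_min, c_max, weights, power, condition, frame_index)


def clock_vector_report(
    vectors: list[ClockVector], bin_spacing_cpd: dict[int, float] | None = None
) -> pd.DataFrame:
    """Tabulate per-condition, per-frame clock vectors for inspection.

    ``bin_spacing_cpd`` maps frame index to that frame's bin spacing in cycles
    per day (1 / (N * T) * 24); when given, band boundaries are reported in
    cycles/day as well as bin indices.  One row per vector.
    """
    rows = []
    for v in vectors:
        row = {
            "condition": v.condition,
            "frame": v.frame_index,
            "c_min": v.c_min,
            "c_max": v.c_max,
            "weights": ",".join(format(w, ".6g") for w in v.weights),
        }
        if bin_spacing_cpd is not None and v.frame_index in bin_spacing_cpd:
            step = bin_spacing_cpd[v.frame_index]
            row["f_min_cpd"] = v.c_min * step
            row["f_max_cpd"] = v.c_max * step
        rows.append(row)
    return pd.DataFrame(rows)


def fallback_vector(
    n_bins_half: int,
    bin_spacing_cpd: float,
    condition: str = "",
    frame_index: int = -1,
    centre_cpd: float = 1.0,
) -> ClockVector:
    """Default band of one cycle/day +- one bin, used when no bin is dominant."""
    centre = int(round(centre_cpd / bin_spacing_cpd))
    c_min = max(1, centre - 1)
    c_max = min(n_bins_half, centre + 1)
    warnings.warn(
        f"no dominant clock bins; falling back to default band "
        f"[{c_min}, {c_max}] around {centre_cpd} cycles/day",
        stacklevel=2,
    )
    n = c_max - c_min + 1
    return ClockVector(c_min, c_max, np.ones(n), np.zeros(n), condition, frame_index)
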