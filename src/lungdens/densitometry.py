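"""Voxel-histogram lung densitometry: LAA, Perc15 and PD15.

The endpoints are the standard quantitative-CT emphysema indices computed on
the Hounsfield values of the segmented lung parenchyma:

* ``LAA(c)`` — the low attenuation area at cutoff ``c``: the percentage of
  lung voxels with HU strictly below ``c`` (cutoffs -950 and -910 HU by
  default).  "Below" is read as strict inequality; at integer HU the choice
  is visible only for voxels exactly at the cutoff.
* ``Perc15`` — the HU value below which 15% of the lowest-density voxels
  lie, i.e. the nearest-rank inverse empirical CDF at fraction 0.15: sort
  ascending and take the element at rank ``ceil(0.15 * N)`` (1-indexed).
  A linearly interpolated convention is available for sensitivity checks.
* ``PD15`` — the same point expressed as a density in g/L, ``Perc15 + 1000``
  (air = -1000 HU = 0 g/L, water = 0 HU = 1000 g/L).

Both endpoints can equivalently be read off a voxel-frequency histogram; with
1-HU bins and integer HU the histogram route is lossless and agrees exactly
with the direct computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_ct import CTVolume, MaskVolume, GeometryError, ParameterError


class EmptyRegionError(ParameterError):
    """Raised when densitometry is asked for on an empty voxel population."""


def extract_lung_hu(vol: CTVolume, mask: MaskVolume) -> np.ndarray:
    """Return the multiset of HU values at true-mask voxels."""
    mask.check_aligned(vol)
    if not mask.flags.any():
        raise EmptyRegionError("mask selects no voxels")
    return vol.voxels[mask.flags]


def compute_laa(values, cutoff: float) -> float:
    """Percentage of values strictly below *cutoff*."""
    v = np.asarray(values)
    if v.size == 0:
        raise EmptyRegionError("LAA of an empty voxel population is undefined")
    return 100.0 * np.count_nonzero(v < cutoff) / v.size


def compute_percentile_point(values, fraction: float = 0.15,
                             convention: str = "nearest_rank") -> float:
    """Inverse empirical CDF of the voxel values at *fraction*.

    ``nearest_rank`` (default) returns the order statistic at rank
    ``ceil(fraction * N)``, the smallest value whose empirical CDF reaches
    *fraction*.  ``linear`` uses linearly interpolated quantiles instead.
    """
    v = np.asarray(values).ravel()
    if v.size == 0:
        raise EmptyRegionError("percentile of an empty voxel population is undefined")
    if not 0.0 < fraction < 1.0:
        raise ParameterError(f"fraction must lie in (0, 1), got {fraction}")
    if convention == "nearest_rank":
        rank = math.ceil(fraction * v.size)  # 1-indexed
        return float(np.partition(v, rank - 1)[rank - 1])
    if convention == "linear":
        return float(np.quantile(v, fraction))
    raise ParameterError(f"unknown percentile convention {convention!r}")


def perc15_to_pd15(perc15: float) -> float:
    """Express a percentile point (HU) as pulmonary density in g/L."""
    return perc15 + 1000.0


@dataclass
class DensityHistogram:
    """Uniform-width voxel-frequency histogram of lung HU values."""

    bin_edges: np.ndarray   # length nbins + 1, strictly increasing
    counts: np.ndarray      # length nbins, non-negative integers
    total: int

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.sum() != self.total:
            raise ParameterError("histogram counts do not sum to total")


def compute_histogram(values, bin_width: float = 1.0) -> DensityHistogram:
    """Histogram the voxel population into uniform *bin_width*-HU bins.

    Bins are half-open ``[edge, edge + width)`` anchored at
    ``floor(min / width) * width`` so integer HU with 1-HU bins map each
    distinct value to its own bin (the lossless case).
    """
    v = np.asarray(values).ravel()
    if v.size == 0:
        raise EmptyRegionError("histogram of an empty voxel population is undefined")
    if bin_width <= 0:
        raise ParameterError(f"bin width must be positive, got {bin_width}")
    lo = math.floor(v.min() / bin_width) * bin_width
    n_bins = int(math.floor((v.max() - lo) / bin_width)) + 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(v, bins=edges)
    return DensityHistogram(edges, counts, int(v.size))


def laa_from_histogram(hist: DensityHistogram, cutoff: float) -> float:
    """LAA recomputed from a histogram; exact when *cutoff* lies on a bin edge
    (always the case for integer cutoffs with 1-HU bins)."""
    full = hist.bin_edges[1:] <= cutoff   # bins entirely below the cutoff
    return 100.0 * hist.counts[full].sum() / hist.total


def percentile_from_histogram(hist: DensityHistogram, fraction: float = 0.15) -> float:
    """Nearest-rank percentile read off the cumulative histogram.

    Returns the left edge of the bin where the cumulative count reaches
    ``ceil(fraction * total)``; for integer HU with 1-HU bins every value in
    a bin equals its left edge, so this matches the direct route exactly.
    """
    if not 0.0 < fraction < 1.0:
        raise ParameterError(f"fraction must lie in (0, 1), got {fraction}")
    rank = math.ceil(fraction * hist.total)
    cum = np.cumsum(hist.counts)
    idx = int(np.searchsorted(cum, rank))
    return float(hist.bin_edges[idx])


@dataclass
class DensitometryResult:
    """Per-case densitometry summary of the masked lung voxel population."""

    laa950: float      # % voxels < -950 HU (first configured cutoff)
    laa910: float      # % voxels < -910 HU (second configured cutoff)
    perc15: float      # HU at the 15th percentile point
    pd15: float        # perc15 + 1000, g/L
    volume_ml: float
    n_voxels: int
    mean_hu: float

    def as_dict(self) -> dict:
        return {
            "laa950_pct": self.laa950,
            "laa910_pct": self.laa910,
            "perc15_hu": self.perc15,
            "pd15_gl": self.pd15,
            "volume_ml": self.volume_ml,
            "n_voxels": self.n_voxels,
            "mean_hu": self.mean_hu,
        }


def summarize_case(vol: CTVolume, mask: MaskVolume,
                   cutoffs: tuple[float, float] = (-950.0, -910.0),
                   fraction: float = 0.15,
                   convention: str = "nearest_rank") -> DensitometryResult:
    """Compute every densitometry endpoint from one pass over the masked voxels."""
    hu = extract_lung_hu(vol, mask)
    cut_lo, cut_hi = cutoffs
    perc = compute_percentile_point(hu, fraction, convention)
    n = int(hu.size)
    return DensitometryResult(
        laa950=compute_laa(hu, cut_lo),
        laa910=compute_laa(hu, cut_hi),
        perc15=perc,
        pd15=perc15_to_pd15(perc),
        volume_ml=n * vol.voxel_volume_mm3 / 1000.0,
        n_voxels=n,
        mean_hu=float(hu.mean()),
    )
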