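"""Pair-correlation function (PCF) estimation from point coordinates.

The PCF C(r) is the average density of cell pairs at separation r, normalized
by the squared average density so that a completely random (Poisson) pattern
gives C = 1 in every bin. Distances are binned into half-open annuli
``((k-1) dr, k dr]`` with centers ``(k - 1/2) dr``, each ordered pair (i, j),
i != j, contributing once (so every unordered pair counts twice), and bin k's
count is normalized by ``n (n-1) 2 pi r_k dr / (Lx Ly)``.

Periodic estimation uses minimum-image distances, appropriate for simulation
output on a torus. Non-periodic estimation uses raw Euclidean distances with
no edge correction: for finite windows the estimate then falls below 1 at
separations comparable to the window size, which is deliberate — corrections
can bias structured patterns, so the raw pair distances are reported as-is.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .ibm import Domain, periodic_displacement

__all__ = ["PairCorrelation", "pairwise_distances", "compute_pcf", "average_pcf"]


@dataclass
class PairCorrelation:
    """Binned C(r) with its bin geometry and normalization metadata."""

    bin_centers: np.ndarray  # µm, (k - 1/2) * delta_r
    values: np.ndarray  # C per bin, dimensionless
    delta_r: float  # bin width µm
    domain_area: float  # Lx * Ly µm^2
    n: object  # point count (or sequence of counts after averaging)
    periodic: bool
    counts: np.ndarray | None = None  # ordered-pair tallies per bin
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_centers.shape != self.values.shape:
            raise ValueError("bin_centers and values must have matching shapes")

    def same_bins(self, other: "PairCorrelation") -> bool:
        return (
            self.bin_centers.shape == other.bin_centers.shape
            and np.allclose(self.bin_centers, other.bin_centers)
            and math.isclose(self.delta_r, other.delta_r)
        )


def pairwise_distances(points, domain: Domain, periodic: bool = True) -> np.ndarray:
    """All ordered-pair distances (i != j); each unordered pair appears twice.

    ``periodic`` selects minimum-image distances on the torus defined by the
    domain. Returns an empty array (with a warning) for fewer than 2 points.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = pts.shape[0]
    if n < 2:
        warnings.warn("fewer than 2 points: no pair distances", stacklevel=2)
        return np.empty(0)
    dom = Domain(domain.Lx, domain.Ly, periodic=periodic)
    d = periodic_displacement(pts[:, None, :], pts[None, :, :], dom)
    dist = np.sqrt(np.sum(d * d, axis=-1))
    mask = ~np.eye(n, dtype=bool)
    return dist[mask]


def compute_pcf(points, domain: Domain, delta_r: float, r_max: float | None = None,
                periodic: bool = True) -> PairCorrelation:
    """Estimate C(r) from one configuration of points.

    ``r_max`` defaults to min(Lx, Ly)/2 in periodic mode (the validity limit of
    the minimum image) and must be supplied for non-periodic input. It is
    rounded down to a whole number of bins. Distances exactly on a bin edge go
    to the lower bin.
    """
    if delta_r <= 0:
        raise ParameterError(f"delta_r must be > 0, got {delta_r}")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = pts.shape[0]
    if n < 2:
        raise ParameterError("at least 2 points are required for a PCF")
    if r_max is None:
        if not periodic:
            raise ParameterError("r_max must be given for non-periodic estimation")
        r_max = min(domain.Lx, domain.Ly) / 2.0
    n_bins = int(round(r_max / delta_r))
    if n_bins < 1 or not math.isclose(n_bins * delta_r, r_max, rel_tol=1e-9):
        raise ParameterError("r_max must be a positive multiple of delta_r")
    dist = pairwise_distances(pts, domain, periodic=periodic)
    positive = dist[dist > 0.0]
    if positive.size < dist.size:
        warnings.warn("coincident points: zero distances excluded from the PCF", stacklevel=2)
    # bin index k = ceil(d / dr): half-open upper edge, edge values to the lower bin
    k = np.ceil(positive / delta_r - 1e-12).astype(np.int64)
    counts = np.bincount(k[(k >= 1) & (k <= n_bins)], minlength=n_bins + 1)[1:].astype(float)
    centers = (np.arange(1, n_bins + 1) - 0.5) * delta_r
    norm = n * (n - 1) * 2.0 * math.pi * centers * delta_r / domain.area
    return PairCorrelation(centers, counts / norm, delta_r, domain.area, n, periodic,
                           counts=counts)


def average_pcf(pcfs) -> PairCorrelation:
    """Bin-wise arithmetic mean of PCFs with identical bin geometry."""
    pcfs = list(pcfs)
    if not pcfs:
        raise ValueError("need at least one PCF to average")
    first = pcfs[0]
    for p in pcfs[1:]:
        if not first.same_bins(p):
            raise ValueError("PCFs have mismatched bin geometry")
    values = np.mean([p.values for p in pcfs], axis=0)
    counts = None
    if all(p.counts is not None for p in pcfs):
        counts = np.sum([p.counts for p in pcfs], axis=0)
    sem = (np.std([p.values for p in pcfs], axis=0, ddof=1) / math.sqrt(len(pcfs))
           if len(pcfs) > 1 else np.zeros_like(values))
    return PairCorrelation(
        first.bin_centers.copy(), values, first.delta_r, first.domain_area,
        tuple(p.n for p in pcfs), first.periodic, counts=counts,
        meta={"n_patterns": len(pcfs), "sem": sem},
    )
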