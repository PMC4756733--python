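"""Seeded synthetic point patterns: Poisson, Matérn cluster, hard core.

These generators provide ground-truth spatial structure for exercising the
pair-correlation estimators: the Poisson pattern is completely random
(C = 1), the Matérn cluster process has an excess of short-separation pairs
(C > 1 below the cluster diameter), and the sequential hard-core process
forbids pairs closer than the core radius (C = 0 there). All use the
periodic (toroidal) metric so the patterns are statistically homogeneous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import PackingError, ParameterError
from .ibm import CellConfiguration, Domain, periodic_displacement

__all__ = ["PointPatternSpec", "generate_pattern"]

_KINDS = ("poisson", "matern_cluster", "hard_core")


@dataclass(frozen=True)
class PointPatternSpec:
    """Recipe for one synthetic pattern.

    ``n`` fixes the point count exactly; alternatively ``intensity`` (points
    per µm^2) draws the count from a Poisson law. Matérn clusters need
    ``n_parents``, ``mean_offspring`` and ``cluster_radius``; hard cores need
    ``core_radius``.
    """

    kind: str
    Lx: float
    Ly: float
    seed: int = 0
    n: int | None = None
    intensity: float | None = None
    n_parents: int | None = None
    mean_offspring: float | None = None
    cluster_radius: float | None = None
    core_radius: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ParameterError(f"unknown pattern kind {self.kind!r}; choose from {_KINDS}")
        if self.Lx <= 0 or self.Ly <= 0:
            raise ParameterError("domain sides must be > 0")
        if self.kind in ("poisson", "hard_core") and (self.n is None) == (self.intensity is None):
            raise ParameterError("give exactly one of n or intensity")
        if self.kind == "matern_cluster":
            for name in ("n_parents", "mean_offspring", "cluster_radius"):
                if getattr(self, name) is None or getattr(self, name) <= 0:
                    raise ParameterError(f"matern_cluster requires positive {name}")
        if self.kind == "hard_core":
            if self.core_radius is None or self.core_radius <= 0:
                raise ParameterError("hard_core requires positive core_radius")


def _count(spec: PointPatternSpec, rng: np.random.Generator) -> int:
    if spec.n is not None:
        return int(spec.n)
    return int(rng.poisson(spec.intensity * spec.Lx * spec.Ly))


def generate_pattern(spec: PointPatternSpec, rng: np.random.Generator | None = None) -> CellConfiguration:
    """Generate one pattern; deterministic given ``spec.seed`` (or a supplied rng)."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    domain = Domain(spec.Lx, spec.Ly, periodic=True)
    if spec.kind == "poisson":
        n = _count(spec, rng)
        pts = np.column_stack([rng.uniform(0, spec.Lx, n), rng.uniform(0, spec.Ly, n)])
    elif spec.kind == "matern_cluster":
        parents = np.column_stack([
            rng.uniform(0, spec.Lx, spec.n_parents),
            rng.uniform(0, spec.Ly, spec.n_parents),
        ])
        chunks = []
        for p in parents:
            k = rng.poisson(spec.mean_offspring)
            if k == 0:
                continue
            radii = spec.cluster_radius * np.sqrt(rng.uniform(size=k))
            angles = rng.uniform(0, 2 * np.pi, k)
            offs = p + np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
            chunks.append(offs)
        pts = np.vstack(chunks) if chunks else np.empty((0, 2))
        pts[:, 0] %= spec.Lx
        pts[:, 1] %= spec.Ly
    else:  # hard_core: sequential dart throwing with the periodic metric
        n = _count(spec, rng)
        packing = n * np.pi * spec.core_radius**2 / 4.0
        if packing > 0.5 * domain.area:
            raise PackingError(
                f"hard-core spec infeasible: {n} discs of radius {spec.core_radius / 2:g} "
                f"cover {packing / domain.area:.0%} of the domain"
            )
        pts = np.empty((n, 2))
        placed = 0
        tries = 0
        max_tries = max(10_000, 2_000 * n)
        while placed < n:
            if tries >= max_tries:
                raise PackingError(
                    f"hard-core packing gave up after {tries} proposals "
                    f"({placed}/{n} points placed)"
                )
            cand = np.array([rng.uniform(0, spec.Lx), rng.uniform(0, spec.Ly)])
            tries += 1
            if placed:
                d = periodic_displacement(pts[:placed], cand, domain)
                if np.min(np.hypot(d[:, 0], d[:, 1])) < spec.core_radius:
                    continue
            pts[placed] = cand
            placed += 1
    return CellConfiguration(pts, 0.0, domain)
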