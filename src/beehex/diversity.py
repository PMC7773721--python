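"""Floral color diversity: convex-polygon area in hexagon space.

Color diversity of a species set is summarized as the area of the
minimum convex polygon (MCP, the convex hull) enclosing its color loci.
Because hull area grows with sample size, groups of unequal richness
are compared by rarefaction: repeated equal-size subsampling without
replacement, summarizing the distribution of subsample areas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .colorspace import ColorLocus

__all__ = ["DiversityResult", "RarefactionResult", "mcp_area", "rarefied_mcp"]

#: Collinearity tolerance (hexagon units) for degenerate hulls.
_COLLINEAR_TOL = 1e-12

#: Area of the full hexagon of circumradius 1 — an upper bound on any MCP.
FULL_HEXAGON_AREA = 3.0 * np.sqrt(3.0) / 2.0


@dataclass
class DiversityResult:
    group_id: str
    n: int
    mcp_area: float


@dataclass
class RarefactionResult:
    """Distribution of MCP areas over equal-size subsamples of a group."""

    group_id: str
    n_sub: int
    reps: int
    areas: np.ndarray
    q025: float
    median: float
    q975: float


def _points(loci: list[ColorLocus] | np.ndarray) -> np.ndarray:
    if isinstance(loci, np.ndarray):
        return np.asarray(loci, dtype=float)
    return np.array([[l.x, l.y] for l in loci], dtype=float)


def mcp_area(loci: list[ColorLocus] | np.ndarray) -> float:
    """Area of the convex hull of the loci; 0 for degenerate inputs.

    Fewer than three points, or points collinear to within the
    cross-product tolerance, give area 0 rather than an error.
    """
    pts = _points(loci)
    if len(pts) < 3:
        return 0.0
    # collinearity: cross products of every offset against the longest offset
    base = pts - pts[0]
    far = base[np.argmax(np.einsum("ij,ij->i", base, base))]
    cross = base[:, 0] * far[1] - base[:, 1] * far[0]
    if np.all(np.abs(cross) < _COLLINEAR_TOL):
        return 0.0
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return 0.0
    return float(hull.volume)  # in 2-D, .volume is the area


def rarefied_mcp(
    groups: dict[str, list[ColorLocus]],
    n_sub: int | None = None,
    reps: int = 1000,
    seed: int = 0,
) -> dict[str, RarefactionResult]:
    """Rarefied MCP areas per group.

    For each group, draw ``n_sub`` loci without replacement, compute the
    MCP area, and repeat ``reps`` times with a seeded stream.  The
    default ``n_sub`` is the smallest group size, so every group is
    summarized at a common richness.  Two groups are conventionally
    declared separated when their central 95% intervals do not overlap.
    """
    if n_sub is None:
        n_sub = min(len(v) for v in groups.values())
    if reps < 1:
        raise ValueError("reps must be >= 1")
    for gid, loci in groups.items():
        if n_sub > len(loci):
            raise ValueError(f"n_sub={n_sub} exceeds size of group {gid!r} ({len(loci)})")
    rng = np.random.default_rng(seed)
    out: dict[str, RarefactionResult] = {}
    for gid in sorted(groups):
        pts = _points(groups[gid])
        areas = np.empty(reps)
        for k in range(reps):
            idx = rng.choice(len(pts), size=n_sub, replace=False)
            areas[k] = mcp_area(pts[idx])
        q025, med, q975 = np.quantile(areas, [0.025, 0.5, 0.975])
        out[gid] = RarefactionResult(gid, n_sub, reps, areas, float(q025), float(med), float(q975))
    return out
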