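"""Community assembly statistics on color and phylogenetic distances.

Whether co-occurring species are more similar (clustered), less similar
(overdispersed) or indistinguishable from random draws of the regional
species pool is assessed with mean pairwise distance (MPD) and mean
nearest taxon distance (MNTD) against a richness-preserving
randomization null: each null replicate draws the same number of
species uniformly without replacement from the full pool.  The
standardized effect size is (observed - null mean) / null sd and the
p-value is the lower-tail rank of the observed statistic in the null
distribution, so small p indicates clustering and large p indicates
overdispersion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .colorspace import ColorLocus

__all__ = [
    "DistanceMatrix",
    "NullModelResult",
    "read_community",
    "mpd",
    "mntd",
    "null_test",
    "cophenetic_matrix",
    "color_distance_matrix",
    "fca_table",
    "phylo_structure_table",
]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix over labeled species."""

    ids: list[str]
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} ids")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate species ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0.0):
            raise ValueError("distances must be nonnegative")
        self._index = {sid: i for i, sid in enumerate(self.ids)}

    def indices(self, subset: Sequence[str]) -> np.ndarray:
        missing = [s for s in subset if s not in self._index]
        if missing:
            raise KeyError(f"unknown species: {', '.join(map(str, missing))}")
        return np.array([self._index[s] for s in subset], dtype=int)

    def submatrix(self, subset: Sequence[str]) -> np.ndarray:
        idx = self.indices(subset)
        return self.values[np.ix_(idx, idx)]


@dataclass
class NullModelResult:
    group_id: str
    n: int
    statistic_name: str
    actual: float
    null_mean: float
    null_sd: float
    ses: float
    p: float
    reps: int
    seed: int


def read_community(path: str | Path) -> pd.DataFrame:
    """Read a community table (species_id, group, optional pollinator_class,
    optional endemic flag) from CSV/TSV with delimiter auto-detection."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).lower() for c in df.columns]
    for required in ("species_id", "group"):
        if required not in df.columns:
            raise ValueError(f"{path}: community table needs a {required!r} column")
    df["species_id"] = df["species_id"].astype(str)
    if df["species_id"].duplicated().any():
        dup = df.loc[df["species_id"].duplicated(), "species_id"].iloc[0]
        raise ValueError(f"{path}: duplicate species_id {dup!r}")
    return df


# ---------------------------------------------------------------------------
# statistics


def _mpd_from_sub(sub: np.ndarray) -> float:
    n = sub.shape[0]
    return float(sub.sum() / (n * (n - 1)))


def _mntd_from_sub(sub: np.ndarray) -> float:
    s = sub.copy()
    np.fill_diagonal(s, np.inf)
    return float(s.min(axis=1).mean())


def mpd(d: DistanceMatrix, subset: Sequence[str]) -> float:
    """Mean pairwise distance over all unordered pairs within subset."""
    if len(subset) < 2:
        raise ValueError("mpd needs at least 2 species")
    return _mpd_from_sub(d.submatrix(subset))


def mntd(d: DistanceMatrix, subset: Sequence[str]) -> float:
    """Mean, over members, of the distance to the nearest other member."""
    if len(subset) < 2:
        raise ValueError("mntd needs at least 2 species")
    return _mntd_from_sub(d.submatrix(subset))


_STATS = {"MPD": _mpd_from_sub, "MNTD": _mntd_from_sub}


def null_test(
    d: DistanceMatrix,
    group: Sequence[str],
    pool: Sequence[str] | None = None,
    statistic: str = "MPD",
    reps: int = 1000,
    seed: int = 0,
    group_id: str = "",
) -> NullModelResult:
    """Randomization null test of a distance statistic for one group.

    ``reps`` draws of ``len(group)`` species are taken uniformly without
    replacement from ``pool`` (default: all species in ``d``); the
    statistic is recomputed on each draw.  The p-value is lower-tail
    with add-one smoothing and ties counted as half:
    ``p = (#{null < actual} + #{null == actual}/2 + 1) / (reps + 1)``.
    When the group exhausts the pool every draw reproduces the observed
    statistic; that degenerate case reports null_sd = 0, ses = 0, p = 1.
    """
    if statistic not in _STATS:
        raise ValueError(f"statistic must be one of {sorted(_STATS)}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    pool = list(pool) if pool is not None else list(d.ids)
    group = list(group)
    n = len(group)
    if n > len(pool):
        raise ValueError(f"group size {n} exceeds pool size {len(pool)}")
    stat = _STATS[statistic]
    actual = stat(d.submatrix(group))
    pool_idx = d.indices(pool)
    if n == len(pool) and set(group) == set(pool):
        # every draw is the whole pool: the null is a point mass at actual
        return NullModelResult(
            group_id=group_id, n=n, statistic_name=statistic, actual=actual,
            null_mean=actual, null_sd=0.0, ses=0.0, p=1.0, reps=reps, seed=seed,
        )
    rng = np.random.default_rng(seed)
    nulls = np.empty(reps)
    for k in range(reps):
        idx = rng.choice(pool_idx, size=n, replace=False)
        nulls[k] = stat(d.values[np.ix_(idx, idx)])
    null_mean = float(nulls.mean())
    null_sd = float(nulls.std(ddof=1)) if reps > 1 else 0.0
    if null_sd == 0.0 and np.allclose(nulls, actual):
        ses, p = 0.0, 1.0
    else:
        ses = (actual - null_mean) / null_sd if null_sd > 0 else np.inf * np.sign(actual - null_mean)
        below = int(np.sum(nulls < actual))
        ties = int(np.sum(nulls == actual))
        p = (below + ties / 2.0 + 1.0) / (reps + 1.0)
    return NullModelResult(
        group_id=group_id, n=n, statistic_name=statistic, actual=actual,
        null_mean=null_mean, null_sd=null_sd, ses=float(ses), p=float(p),
        reps=reps, seed=seed,
    )


# ---------------------------------------------------------------------------
# distance matrices


def color_distance_matrix(loci: Sequence[ColorLocus]) -> DistanceMatrix:
    """Pairwise Euclidean distances between hexagon color loci."""
    ids = [l.species_id for l in loci]
    pts = np.array([[l.x, l.y] for l in loci])
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(ids=ids, values=d, units="hexagon")


def cophenetic_matrix(tree: dendropy.Tree, units: str = "branch-length") -> DistanceMatrix:
    """Tree-path (cophenetic) distances between all pairs of tips.

    Every non-root edge must carry a branch length; polytomies are
    allowed.  Tip labels must be unique.
    """
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels in tree")
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None and edge.length is None:
            head = edge.head_node
            name = head.taxon.label if head.taxon else "<internal>"
            raise ValueError(f"missing branch length on edge above {name}")
    labels = sorted(labels)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {leaf.taxon.label: leaf.taxon for leaf in tree.leaf_node_iter()}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(ids=labels, values=d, units=units)


# ---------------------------------------------------------------------------
# table-level drivers


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-row seeds derived from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def fca_table(
    loci: Sequence[ColorLocus],
    groups: pd.DataFrame,
    reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Floral color assembly: one MPD-on-color null test per group.

    The pool is the full species list in ``groups``.  If a
    ``pollinator_class`` column is present, additional rows test each
    (group, class) subset against the *unchanged* full pool, so their
    null distributions match the all-species rows.
    """
    have = {l.species_id for l in loci}
    missing = sorted(set(groups["species_id"]) - have)
    if missing:
        raise ValueError(f"species without color loci: {', '.join(missing[:10])}")
    dm = color_distance_matrix([l for l in loci if l.species_id in set(groups["species_id"])])
    tasks: list[tuple[str, list[str]]] = []
    for gid, sub in groups.groupby("group", sort=True):
        tasks.append((str(gid), list(sub["species_id"])))
    if "pollinator_class" in groups.columns:
        for (gid, pc), sub in groups.groupby(["group", "pollinator_class"], sort=True):
            if pd.isna(pc) or len(sub) < 2:
                continue
            tasks.append((f"{gid}:{pc}", list(sub["species_id"])))
    seeds = _spawn_seeds(seed, len(tasks))
    rows = []
    for (gid, members), s in zip(tasks, seeds):
        res = null_test(dm, members, statistic="MPD", reps=reps, seed=s, group_id=gid)
        rows.append(res)
    return _results_frame(rows)


def phylo_structure_table(
    tree: dendropy.Tree,
    groups: pd.DataFrame,
    reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Phylogenetic community structure: MPD and MNTD null tests per group."""
    dm = cophenetic_matrix(tree)
    missing = sorted(set(groups["species_id"]) - set(dm.ids))
    if missing:
        raise ValueError(f"species absent from tree: {', '.join(missing[:10])}")
    pool = [s for s in dm.ids if s in set(groups["species_id"])]
    tasks = [(str(gid), list(sub["species_id"])) for gid, sub in groups.groupby("group", sort=True)]
    seeds = _spawn_seeds(seed, 2 * len(tasks))
    rows = []
    for i, (gid, members) in enumerate(tasks):
        for j, stat in enumerate(("MPD", "MNTD")):
            res = null_test(
                dm, members, pool=pool, statistic=stat,
                reps=reps, seed=seeds[2 * i + j], group_id=gid,
            )
            rows.append(res)
    return _results_frame(rows)


def _results_frame(rows: list[NullModelResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": [r.group_id for r in rows],
            "n": [r.n for r in rows],
            "statistic": [r.statistic_name for r in rows],
            "actual": [r.actual for r in rows],
            "null_mean": [r.null_mean for r in rows],
            "null_sd": [r.null_sd for r in rows],
            "ses": [r.ses for r in rows],
            "p": [r.p for r in rows],
            "reps": [r.reps for r in rows],
            "seed": [r.seed for r in rows],
        }
    )
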