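"""Phylogenetic signal of color descriptors: Blomberg's K and Mantel.

Blomberg's K compares the observed ratio of trait variance among tips
to the variance expected under Brownian motion on the given tree:

    K = (MSE0 / MSE) / E[MSE0 / MSE]

where MSE0 is the trait mean squared error around the phylogenetically
weighted mean, MSE is the same error measured in the metric of the
Brownian covariance matrix V (V_ij = shared root-to-MRCA path length),
and the expectation E[MSE0/MSE] = (tr V - n / sum(V^-1)) / (n - 1)
makes K = 1 the Brownian benchmark on any tree.  K near 0 means trait
values are independent of phylogeny; significance comes from a
permutation test that shuffles trait values across tips and compares
the phylogenetically corrected error MSE.

The Mantel test correlates the lower triangles of two distance
matrices (here: hexagon color distance vs cophenetic distance) and
obtains a one-tailed p by jointly permuting rows and columns of the
color matrix, preserving the tree matrix's structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .assembly import DistanceMatrix, cophenetic_matrix, color_distance_matrix
from .colorspace import ColorLocus

__all__ = [
    "SignalResult",
    "read_tree",
    "prune_tree",
    "phylo_covariance",
    "blomberg_k",
    "blomberg_k_test",
    "mantel_test",
    "signal_table",
]


@dataclass
class SignalResult:
    group_id: str
    trait_name: str
    n: int
    k: float
    p_k: float
    mantel_r: float
    p_mantel: float
    reps: int
    seed: int


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    return tree


def prune_tree(tree: dendropy.Tree, tips: Sequence[str]) -> dendropy.Tree:
    """Subtree induced by ``tips``; path lengths between kept tips are
    preserved (unifurcations are collapsed by summing edge lengths)."""
    sub = tree.extract_tree_with_taxa_labels(labels=set(tips))
    # bind to a fresh namespace so the source tree's is left untouched
    sub.migrate_taxon_namespace(dendropy.TaxonNamespace())
    return sub


# ---------------------------------------------------------------------------
# Brownian covariance


def phylo_covariance(tree: dendropy.Tree, tips: Sequence[str] | None = None) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance matrix for a set of tips.

    V(i, j) is the shared path length from the root to the most recent
    common ancestor of tips i and j; V(i, i) is the root-to-tip
    distance.  When ``tips`` is a proper subset, the tree is implicitly
    rooted at the subset's MRCA, matching pruned-subtree semantics.

    Returns (sorted tip labels, V).
    """
    leaf_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if tips is None:
        tips = sorted(leaf_labels)
    else:
        missing = sorted(set(tips) - leaf_labels)
        if missing:
            raise ValueError(f"tips not in tree: {', '.join(missing)}")
        tips = sorted(set(tips))
    index = {label: i for i, label in enumerate(tips)}
    n = len(tips)
    V = np.zeros((n, n))

    depth: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge_len = node.edge.length if (parent is not None and node.edge.length is not None) else 0.0
        depth[node] = (depth[parent] if parent is not None else 0.0) + edge_len

    # postorder sweep: pairs of tips split at their MRCA
    below: dict[dendropy.Node, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label in index:
                i = index[label]
                V[i, i] = depth[node]
                below[node] = [i]
            else:
                below[node] = []
            continue
        kids = [below[c] for c in node.child_nodes()]
        d = depth[node]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for i in kids[a]:
                    for j in kids[b]:
                        V[i, j] = V[j, i] = d
        below[node] = [i for k in kids for i in k]

    # re-root at the subset MRCA: subtract the depth shared by all tips
    if n >= 2:
        d0 = V[~np.eye(n, dtype=bool)].min()
        if d0 > 0:
            V = V - d0
    return list(tips), V


# ---------------------------------------------------------------------------
# Blomberg's K


def _k_ingredients(V: np.ndarray, ridge: float = 0.0):
    n = V.shape[0]
    Vr = V + ridge * np.eye(n) if ridge > 0 else V
    try:
        factor = cho_factor(Vr)
    except LinAlgError as exc:
        raise ValueError(
            "phylogenetic covariance matrix is singular (zero-length cherries?); "
            "consider the ridge epsilon option"
        ) from exc
    ones = np.ones(n)
    Vinv_1 = cho_solve(factor, ones)
    s = float(ones @ Vinv_1)  # 1' V^-1 1
    expectation = (np.trace(Vr) - n / s) / (n - 1)
    return factor, Vinv_1, s, expectation


def _mse_pair(x: np.ndarray, factor, Vinv_1: np.ndarray, s: float) -> tuple[float, float]:
    n = x.size
    a_hat = float(Vinv_1 @ x) / s
    resid = x - a_hat
    mse0 = float(resid @ resid) / (n - 1)
    mse = float(resid @ cho_solve(factor, resid)) / (n - 1)
    return mse0, mse


def blomberg_k(
    tree: dendropy.Tree, trait: dict[str, float] | pd.Series, ridge: float = 0.0
) -> float:
    """Blomberg's K for a continuous trait on a tree.

    ``trait`` maps tip labels to values and must cover every tip used.
    ``ridge`` optionally adds a small epsilon to the diagonal of V for
    trees with zero-length edges (off by default).
    """
    trait = pd.Series(trait)
    tips, V = phylo_covariance(tree, list(trait.index))
    x = trait.loc[tips].to_numpy(float)
    if np.ptp(x) == 0.0:
        raise ValueError("constant trait: K undefined (MSE0 = 0)")
    factor, Vinv_1, s, expectation = _k_ingredients(V, ridge)
    mse0, mse = _mse_pair(x, factor, Vinv_1, s)
    return (mse0 / mse) / expectation


def blomberg_k_test(
    tree: dendropy.Tree,
    trait: dict[str, float] | pd.Series,
    reps: int = 999,
    seed: int = 0,
    ridge: float = 0.0,
) -> tuple[float, float]:
    """Blomberg's K with a tip-shuffling permutation test.

    Significance is judged on the phylogenetically corrected error:
    a trait tracking the tree has a *small* MSE in the V metric, so
    ``p_K = (#{permuted MSE <= observed MSE} + 1) / (reps + 1)``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    trait = pd.Series(trait)
    tips, V = phylo_covariance(tree, list(trait.index))
    x = trait.loc[tips].to_numpy(float)
    if np.ptp(x) == 0.0:
        raise ValueError("constant trait: K undefined (MSE0 = 0)")
    factor, Vinv_1, s, expectation = _k_ingredients(V, ridge)
    mse0, mse = _mse_pair(x, factor, Vinv_1, s)
    k = (mse0 / mse) / expectation

    # vectorized permuted MSEs: MSE(x) = (x'Wx - (1'Wx)^2 / s) / (n - 1)
    n = x.size
    W = cho_solve(factor, np.eye(n))
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(x) for _ in range(reps)])
    XW = perms @ W
    quad = np.einsum("ij,ij->i", XW, perms)
    lin = perms @ Vinv_1
    perm_mse = (quad - lin**2 / s) / (n - 1)
    p_k = (int(np.sum(perm_mse <= mse)) + 1) / (reps + 1)
    return float(k), float(p_k)


# ---------------------------------------------------------------------------
# Mantel


def mantel_test(
    d1: DistanceMatrix, d2: DistanceMatrix, reps: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the lower-triangle entries; the
    one-tailed p (positive association) comes from jointly permuting
    rows and columns of ``d1`` while holding ``d2`` fixed, with add-one
    smoothing.  Requires identical id sets in identical order, n >= 3.
    """
    if d1.ids != d2.ids:
        raise ValueError("distance matrices must share ids in the same order")
    n = len(d1.ids)
    if n < 3:
        raise ValueError("mantel test needs at least 3 species")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    tri = np.tril_indices(n, k=-1)
    v1 = d1.values[tri]
    v2 = d2.values[tri]
    if np.ptp(v1) == 0.0 or np.ptp(v2) == 0.0:
        raise ValueError("zero variance in a distance triangle")
    r_obs = float(np.corrcoef(v1, v2)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(reps):
        perm = rng.permutation(n)
        v1p = d1.values[np.ix_(perm, perm)][tri]
        if float(np.corrcoef(v1p, v2)[0, 1]) >= r_obs:
            count += 1
    p = (count + 1) / (reps + 1)
    return r_obs, float(p)


# ---------------------------------------------------------------------------
# driver


def signal_table(
    tree: dendropy.Tree,
    loci: Sequence[ColorLocus],
    groups: pd.DataFrame,
    reps: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Phylogenetic signal of hue and contrast per community group.

    For each group: Blomberg's K (with permutation p) of the hue angle
    theta and the chromatic contrast r on the pruned subtree, plus a
    Mantel test of the full 2-D color distance against the cophenetic
    distance.  Hue is treated as a linear variable in degrees.
    """
    by_id = {l.species_id: l for l in loci}
    rows: list[SignalResult] = []
    ss = np.random.SeedSequence(seed)
    tasks = list(groups.groupby("group", sort=True))
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3 * len(tasks))]
    for t, (gid, sub) in enumerate(tasks):
        members = sorted(sub["species_id"])
        if len(members) < 3:
            raise ValueError(f"group {gid!r} has fewer than 3 species")
        missing = [m for m in members if m not in by_id]
        if missing:
            raise ValueError(f"group {gid!r} members without loci: {', '.join(missing)}")
        subtree = prune_tree(tree, members)
        group_loci = [by_id[m] for m in members]
        coph = cophenetic_matrix(subtree)
        cdm = color_distance_matrix(sorted(group_loci, key=lambda l: l.species_id))
        r_m, p_m = mantel_test(cdm, coph, reps=reps, seed=seeds[3 * t + 2])
        for j, (trait_name, values) in enumerate(
            (
                ("hue_theta", {l.species_id: l.theta for l in group_loci}),
                ("contrast_r", {l.species_id: l.r for l in group_loci}),
            )
        ):
            k, p_k = blomberg_k_test(subtree, values, reps=reps, seed=seeds[3 * t + j])
            rows.append(
                SignalResult(str(gid), trait_name, len(members), k, p_k, r_m, p_m, reps, seed)
            )
    return pd.DataFrame(
        {
            "group": [r.group_id for r in rows],
            "trait": [r.trait_name for r in rows],
            "n": [r.n for r in rows],
            "K": [r.k for r in rows],
            "p_K": [r.p_k for r in rows],
            "mantel_r": [r.mantel_r for r in rows],
            "p_mantel": [r.p_mantel for r in rows],
            "reps": [r.reps for r in rows],
            "seed": [r.seed for r in rows],
        }
    )
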