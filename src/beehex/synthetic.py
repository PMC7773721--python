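"""Synthetic studies: spectra archetypes, Yule trees, Brownian traits,
and community structures.

The generator emulates the statistical features the analysis pipeline
assumes in field data:

* flower reflectance archetypes — UV-absorbing white (sigmoid step near
  400 nm), yellow with and without a UV reflectance bump, blue, purple
  and long-wavelength red, plus a leaf-green background spectrum;
* a pure-birth (Yule) phylogeny with ultrametric branch lengths;
* Brownian trait evolution along the tree (1-D or 2-D);
* community samples that are color-clustered (a focal species and its
  nearest color neighbors), random, or overdispersed (greedy max-min
  spread).

Every artifact is reproducible bit-for-bit from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .spectra import DEFAULT_GRID, ReflectanceSpectrum

__all__ = [
    "SpectrumArchetype",
    "ARCHETYPES",
    "StudyConfig",
    "gen_flower_spectrum",
    "gen_leaf_spectrum",
    "gen_yule_tree",
    "evolve_bm",
    "gen_community",
    "gen_dataset",
]


@dataclass(frozen=True)
class SpectrumArchetype:
    """Parametric flower-reflectance shape: logistic step + Gaussian bump.

    The base curve is ``plateau / (1 + exp(-(lambda - step_mid) / step_width))``
    plus an optional Gaussian bump of amplitude ``bump_amp`` centered at
    ``bump_center`` (used both for UV reflectance bumps and for
    short-wavelength peaks like blue).  Seeded Gaussian noise of sd
    ``noise_sd`` is added and the result clipped to [0, 1].
    """

    name: str
    plateau: float
    step_mid: float
    step_width: float
    bump_amp: float = 0.0
    bump_center: float = 350.0
    bump_width: float = 25.0
    noise_sd: float = 0.01


#: Fixed archetype parameters (constants so golden tests stay stable).
ARCHETYPES: dict[str, SpectrumArchetype] = {
    a.name: a
    for a in [
        SpectrumArchetype("white_uv_absorbing", plateau=0.8, step_mid=400.0, step_width=20.0),
        SpectrumArchetype("yellow_uv_absent", plateau=0.8, step_mid=500.0, step_width=20.0),
        SpectrumArchetype(
            "yellow_uv_present", plateau=0.8, step_mid=500.0, step_width=20.0,
            bump_amp=0.30, bump_center=350.0, bump_width=25.0,
        ),
        SpectrumArchetype(
            "blue", plateau=0.0, step_mid=500.0, step_width=20.0,
            bump_amp=0.55, bump_center=450.0, bump_width=40.0,
        ),
        SpectrumArchetype(
            "purple", plateau=0.45, step_mid=620.0, step_width=15.0,
            bump_amp=0.40, bump_center=440.0, bump_width=35.0,
        ),
        SpectrumArchetype("red_long", plateau=0.7, step_mid=600.0, step_width=15.0),
        SpectrumArchetype(
            "leaf_green", plateau=0.05, step_mid=200.0, step_width=10.0,
            bump_amp=0.12, bump_center=550.0, bump_width=50.0, noise_sd=0.005,
        ),
    ]
}


def gen_flower_spectrum(
    archetype: SpectrumArchetype | str,
    seed: int,
    species_id: str | None = None,
    grid: np.ndarray | None = None,
) -> ReflectanceSpectrum:
    """Generate one reflectance spectrum from an archetype."""
    if isinstance(archetype, str):
        archetype = ARCHETYPES[archetype]
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, dtype=float)
    base = archetype.plateau / (1.0 + np.exp(-(grid - archetype.step_mid) / archetype.step_width))
    if archetype.bump_amp:
        base = base + archetype.bump_amp * np.exp(
            -((grid - archetype.bump_center) ** 2) / (2.0 * archetype.bump_width**2)
        )
    if not np.any(base > 0.0):
        raise ValueError(f"archetype {archetype.name!r} produces an all-zero spectrum")
    rng = np.random.default_rng(seed)
    if archetype.noise_sd > 0:
        base = base + rng.normal(0.0, archetype.noise_sd, size=grid.size)
    refl = np.clip(base, 0.0, 1.0)
    sid = species_id if species_id is not None else f"{archetype.name}_{seed}"
    return ReflectanceSpectrum(sid, grid.copy(), refl)


def gen_leaf_spectrum(
    seed: int, species_id: str | None = None, grid: np.ndarray | None = None
) -> ReflectanceSpectrum:
    """A leaf-green background spectrum: low baseline, green peak at 550 nm."""
    sid = species_id if species_id is not None else f"leaf_{seed}"
    return gen_flower_spectrum(ARCHETYPES["leaf_green"], seed, species_id=sid, grid=grid)


# ---------------------------------------------------------------------------
# trees and traits


def gen_yule_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Simulate a pure-birth (Yule) tree with ``n_tips`` extant tips.

    Starting from the root bifurcation (two lineages), waiting times
    between speciations are exponential with rate (number of lineages)
    times ``birth_rate``; a random lineage splits at each event.  After
    the last split every lineage is extended by a final exponential
    waiting time, so the tree is ultrametric with nonzero terminal
    branches.  Expected root-to-tip depth is
    ``sum_{k=2..n} 1 / (k * birth_rate)``.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node.edge.length = 0.0
    active = []
    for _ in range(2):
        child = tree.seed_node.new_child(edge_length=0.0)
        active.append(child)
    k = 2
    while k < n_tips:
        wait = rng.exponential(1.0 / (k * birth_rate))
        for node in active:
            node.edge.length += wait
        parent = active.pop(int(rng.integers(len(active))))
        for _ in range(2):
            active.append(parent.new_child(edge_length=0.0))
        k += 1
    final = rng.exponential(1.0 / (n_tips * birth_rate))
    for node in active:
        node.edge.length += final
    width = len(str(n_tips))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.new_taxon(f"s{i:0{width}d}")
    return tree


def evolve_bm(
    tree: dendropy.Tree,
    sigma2: float = 1.0,
    root_value: float = 0.0,
    seed: int = 0,
    dims: int = 1,
) -> pd.DataFrame:
    """Evolve a continuous trait along the tree under Brownian motion.

    Each branch adds an independent Gaussian increment of variance
    ``sigma2`` times branch length; dimensions evolve independently in
    2-D mode.  Returns a DataFrame indexed by tip label with columns
    ``trait`` (1-D) or ``x, y`` (2-D).
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    rng = np.random.default_rng(seed)
    values: dict[int, np.ndarray] = {}
    out: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            values[id(node)] = np.full(dims, float(root_value))
        else:
            length = node.edge.length or 0.0
            step = rng.normal(0.0, np.sqrt(sigma2 * length), size=dims)
            values[id(node)] = values[id(parent)] + step
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    cols = ["trait"] if dims == 1 else ["x", "y"][:dims]
    df = pd.DataFrame.from_dict(out, orient="index", columns=cols)
    return df.sort_index()


# ---------------------------------------------------------------------------
# community structures


def gen_community(
    loci_pool, structure: str, n: int, seed: int = 0
) -> list[str]:
    """Select a species subset with a prescribed color structure.

    * ``random`` — uniform draw without replacement;
    * ``clustered`` — a random focal species plus its n - 1 nearest
      color neighbors;
    * ``overdispersed`` — greedy max-min: start from the most distant
      pair, then repeatedly add the species whose minimum distance to
      the selected set is largest.
    """
    ids = [l.species_id for l in loci_pool]
    pts = np.array([[l.x, l.y] for l in loci_pool])
    if not 2 <= n <= len(ids):
        raise ValueError(f"n={n} must be in [2, {len(ids)}]")
    rng = np.random.default_rng(seed)
    if structure == "random":
        picks = rng.choice(len(ids), size=n, replace=False)
    elif structure == "clustered":
        focal = int(rng.integers(len(ids)))
        dist = np.hypot(*(pts - pts[focal]).T)
        picks = np.argsort(dist, kind="stable")[:n]
    elif structure == "overdispersed":
        diff = pts[:, None, :] - pts[None, :, :]
        d = np.sqrt((diff**2).sum(axis=-1))
        i, j = np.unravel_index(np.argmax(d), d.shape)
        chosen = [int(i), int(j)]
        mind = np.minimum(d[i], d[j])
        while len(chosen) < n:
            mind[chosen] = -1.0
            nxt = int(np.argmax(mind))
            chosen.append(nxt)
            mind = np.minimum(mind, d[nxt])
        picks = np.array(chosen)
    else:
        raise ValueError(f"unknown structure {structure!r}")
    return [ids[i] for i in picks]


# ---------------------------------------------------------------------------
# full study bundles


@dataclass
class StudyConfig:
    """Configuration of a complete synthetic study.

    Defaults mirror the field-study conditions the pipeline targets:
    three altitude groups of 399 / 186 / 142 species, an archetype
    mixture dominated by UV-absorbing white and yellow flowers, a Yule
    phylogeny over all species, and per-group color-assembly structure
    (low random, middle clustered, high overdispersed).
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"low": 399, "middle": 186, "high": 142}
    )
    structures: dict[str, str] = field(
        default_factory=lambda: {"low": "random", "middle": "clustered", "high": "overdispersed"}
    )
    mixture: dict[str, float] = field(
        default_factory=lambda: {
            "white_uv_absorbing": 0.47,
            "purple": 0.25,
            "yellow_uv_present": 0.13,
            "yellow_uv_absent": 0.06,
            "blue": 0.05,
            "red_long": 0.04,
        }
    )
    clade_group: str | None = None
    n_leaves: int = 10
    birth_rate: float = 1.0
    oversample: float = 3.0
    bee_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.mixture.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"mixture weights sum to {total}, expected 1")
        if any(w < 0 for w in self.mixture.values()):
            raise ValueError("mixture weights must be nonnegative")
        if any(n < 3 for n in self.group_sizes.values()):
            raise ValueError("each group needs at least 3 species")
        if set(self.structures) != set(self.group_sizes):
            raise ValueError("structures and group_sizes must name the same groups")


def _candidate_loci(archetypes, seeds, grid):
    """Generate spectra for candidate species and map them to loci."""
    from .colorspace import spectrum_to_locus
    from .spectra import bee_sensitivities, d65_photon_flux, mean_background

    leaf_seeds = range(10_000, 10_010)
    leaves = [gen_leaf_spectrum(s, grid=grid) for s in leaf_seeds]
    background = mean_background(leaves)
    sens = bee_sensitivities(grid=grid)
    ill = d65_photon_flux(grid=grid)
    spectra = [
        gen_flower_spectrum(a, s, species_id=f"cand{i}", grid=grid)
        for i, (a, s) in enumerate(zip(archetypes, seeds))
    ]
    loci = [spectrum_to_locus(sp, background, sens, ill) for sp in spectra]
    return spectra, loci


def gen_dataset(config: StudyConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete synthetic study to disk.

    Produces, in the pipeline's own input dialects:

    * ``spectra.csv`` — wide table, one column per species;
    * ``leaves.csv`` — wide table of leaf background spectra;
    * ``tree.nwk`` — Newick Yule phylogeny over all species;
    * ``community.tsv`` — species_id, group, pollinator_class, endemic.

    Group structure is imposed by selection: each structured group
    draws its members from an oversampled candidate set of archetype
    spectra (clustered by color neighborhood, overdispersed by greedy
    max-min); the ``clade_group``, if named, has its species placed on
    the tips of a single clade of the phylogeny.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grid = DEFAULT_GRID
    rng = np.random.default_rng(config.seed)
    total = sum(config.group_sizes.values())

    # candidate spectra per group, oversampled so selection has room
    names = list(config.mixture)
    weights = np.array([config.mixture[n] for n in names])
    spectra_by_species: dict[str, ReflectanceSpectrum] = {}
    group_of: dict[str, str] = {}
    counter = 0
    for gid in sorted(config.group_sizes):
        n = config.group_sizes[gid]
        structure = config.structures[gid]
        n_cand = n if structure == "random" else max(n, int(round(config.oversample * n)))
        archs = rng.choice(names, size=n_cand, p=weights)
        seeds = rng.integers(0, 2**31, size=n_cand)
        cand_spectra, cand_loci = _candidate_loci(archs, seeds, grid)
        keep = gen_community(cand_loci, structure, n, seed=int(rng.integers(2**31)))
        keep_set = set(keep)
        for sp, locus in zip(cand_spectra, cand_loci):
            if locus.species_id in keep_set:
                counter += 1
                sid = f"sp{counter:04d}"
                spectra_by_species[sid] = ReflectanceSpectrum(sid, sp.wavelengths, sp.reflectance)
                group_of[sid] = gid

    species = sorted(spectra_by_species)

    # phylogeny over all species; optionally confine one group to a clade
    tree = gen_yule_tree(total, birth_rate=config.birth_rate, seed=int(rng.integers(2**31)))
    tip_labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    mapping = _assign_tips(tree, tip_labels, species, group_of, config.clade_group, rng)
    for leaf in tree.leaf_node_iter():
        leaf.taxon.label = mapping[leaf.taxon.label]
    tree.taxon_namespace.sort(key=lambda t: t.label)

    # write artifacts
    spectra_path = out_dir / "spectra.csv"
    wide = pd.DataFrame(
        {"wavelength": grid, **{sid: spectra_by_species[sid].reflectance for sid in species}}
    )
    wide.to_csv(spectra_path, index=False)

    leaves_path = out_dir / "leaves.csv"
    leaves = [gen_leaf_spectrum(10_000 + i, grid=grid) for i in range(config.n_leaves)]
    lw = pd.DataFrame(
        {"wavelength": grid, **{f"leaf{i:02d}": leaf.reflectance for i, leaf in enumerate(leaves, 1)}}
    )
    lw.to_csv(leaves_path, index=False)

    tree_path = out_dir / "tree.nwk"
    tree.write(path=str(tree_path), schema="newick", suppress_rooting=True)

    comm_path = out_dir / "community.tsv"
    pol = rng.choice(["bee", "insect"], size=len(species), p=[config.bee_fraction, 1 - config.bee_fraction])
    endemic = rng.integers(0, 2, size=len(species))
    pd.DataFrame(
        {
            "species_id": species,
            "group": [group_of[s] for s in species],
            "pollinator_class": pol,
            "endemic": endemic,
        }
    ).to_csv(comm_path, sep="\t", index=False)

    return {
        "spectra": spectra_path,
        "leaves": leaves_path,
        "tree": tree_path,
        "community": comm_path,
    }


def _assign_tips(
    tree: dendropy.Tree,
    tip_labels: list[str],
    species: list[str],
    group_of: dict[str, str],
    clade_group: str | None,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Map placeholder tip labels to species ids, honoring clade_group."""
    if len(tip_labels) != len(species):
        raise ValueError(
            f"tree has {len(tip_labels)} tips but {len(species)} species configured"
        )
    if clade_group is None:
        shuffled = list(species)
        rng.shuffle(shuffled)
        return dict(zip(tip_labels, shuffled))
    members = [s for s in species if group_of[s] == clade_group]
    if not members:
        raise ValueError(f"clade_group {clade_group!r} not among configured groups")
    # smallest clade that can host the whole group
    best = None
    for node in tree.postorder_internal_node_iter():
        leaves = [l.taxon.label for l in node.leaf_iter()]
        if len(leaves) >= len(members) and (best is None or len(leaves) < len(best)):
            best = leaves
    clade = list(best)
    rng.shuffle(clade)
    mapping: dict[str, str] = {}
    clade_slots = clade[: len(members)]
    members_shuffled = list(members)
    rng.shuffle(members_shuffled)
    mapping.update(zip(clade_slots, members_shuffled))
    rest_slots = [t for t in tip_labels if t not in mapping]
    rest_species = [s for s in species if group_of[s] != clade_group]
    rng.shuffle(rest_species)
    mapping.update(zip(rest_slots, rest_species))
    return mapping
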