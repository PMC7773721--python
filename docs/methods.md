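# Methods

This note documents the models, parameter choices and numerical
conventions implemented in `beehex`, and what the synthetic-data
generator does and does not emulate.

## Spectral processing

Reflectance spectra are resampled by linear interpolation onto a common
1-nm grid over 300–700 nm (401 points) — the finest resolution common
spectrometer exports share; all spectral integrals use the trapezoidal
rule on this grid, where integration error is negligible relative to
measurement noise. A spectrum may fall short of the grid by at most
5 nm at either edge (constant margin, edge-extrapolated); sparse but
finite sampling is interpolated without complaint, while holes left by
dropped non-finite readings wider than the margin are errors.
Negative readings (instrument noise) are clipped to zero; reflectance
above 1 (specular glare) is retained with a warning so that data are
not silently altered. Replicate spectra sharing a species id are
averaged after resampling, because the analysis assigns one color
locus per species.

**Receptor sensitivities.** The trichromatic bee receptor set peaks at
350, 440 and 540 nm. Only the peak positions are constrained by the
underlying behavioral literature, so curve shapes come from the
standard A1 visual-pigment (rhodopsin) template: the α-band with its
peak-dependent steepness parameter plus the Gaussian β-band, evaluated
on the grid and peak-normalized. The β-band keeps sensitivity strictly
positive in the near-UV for the long-wavelength receptor, which
matters for UV-reflecting stimuli.

**Illuminant.** CIE standard daylight D65 (relative spectral power,
5-nm tabulation over 300–700 nm) interpolated to the grid and
multiplied pointwise by wavelength to convert energy to photon flux —
photon energy scales as 1/λ — then normalized to maximum 1. The
normalization is cosmetic: any illuminant scale cancels in von Kries
adaptation, and this invariance is asserted by tests.

**Marker points.** Wavelengths of steepest spectral transition are the
local maxima of |dR/dλ| after smoothing with a centered moving average
(default window 11 nm). Maxima below 20% of the global maximum slope
are suppressed, and — because sub-window noise superimposes spurious
local maxima on a broad transition — the slope curve is smoothed with
the same window and peaks must additionally reach that 20% level in
prominence. A constant spectrum has no marker points.

## Hexagon color space

Receptor excitation is E = q/(q+1) of the background-relative quantum
catch; the hexagon coordinates are x = (√3/2)(E_g − E_uv),
y = E_b − (E_uv + E_g)/2. Orientation: receptor vertices at B = 90°,
G = 330°, UV = 210°, blended vertices BG = 30°, UB = 150°, UG = 270°;
sectors are vertex-centered half-open 60° wedges [v−30°, v+30°), so a
hue exactly on a boundary belongs to the higher wedge. This
orientation puts the bee-preferred blue/blue-green region at 30–90°,
UV-absorbing white flowers in the BG sector and UV-reflecting yellows
in UG, matching the relative statements available (dominant hue peak
near 60°, "white arm" toward BG, "yellow arm" toward UG); absolute
angles in externally produced datasets may be rotated relative to
other software. The achromatic point (r = 0) reports θ = 0 by
convention and is excluded from angular statistics.

## Diversity

Color diversity of a species set is the area of the convex hull of its
loci (scipy Qhull; 0 for fewer than three points or collinear sets,
with collinearity detected by cross products below 1e−12 in hexagon
units). Hull area grows with sample size, so groups are also compared
by rarefaction: draw `n_sub` species without replacement (default: the
smallest group's size), compute the hull area, repeat (default 1000
replicates) and summarize with 2.5/50/97.5% quantiles. Two groups are
conventionally called separated when their central 95% intervals do
not overlap — an explicit, declared criterion.

## Assembly null models

MPD is the mean over all unordered pairs; MNTD the mean over members
of the distance to the nearest other member. The null model is
richness randomization: each replicate draws the observed number of
species uniformly without replacement from the full pooled species
list (no abundance weighting, pool never restricted — pollinator-class
subsets are tested against the same full pool so their null
distributions are comparable). The p-value is the lower-tail rank with
add-one smoothing and ties counted half:

    p = (#{null < obs} + #{null = obs}/2 + 1) / (reps + 1)

so small p indicates clustering and large p overdispersion, and p is
never exactly 0. When a group exhausts its pool the null is a point
mass and the result is reported as ses = 0, p = 1. Default 1000
replicates; every result records its seed, and identical inputs plus
seed reproduce results bit-for-bit. Phylogenetic distances are
cophenetic (tree-path) distances computed with dendropy; polytomies
are allowed, missing branch lengths are errors.

## Phylogenetic signal

Blomberg's K uses the Brownian covariance matrix V (shared
root-to-MRCA path lengths; for a subset of tips the tree is implicitly
re-rooted at the subset's MRCA, matching pruned-subtree semantics):

    â    = (1ᵀV⁻¹1)⁻¹ 1ᵀV⁻¹x
    MSE0 = (x−â)ᵀ(x−â)/(n−1)
    MSE  = (x−â)ᵀV⁻¹(x−â)/(n−1)
    K    = (MSE0/MSE) / [(tr V − n/(1ᵀV⁻¹1)) / (n−1)]

K = 1 on a star tree for any non-constant trait (asserted to 1e−10),
and K is invariant to affine trait transforms. The implementation is
cross-checked against an independent direct linear-algebra evaluation
and against R `phytools::phylosig`. Significance shuffles trait values
across tips and ranks the phylogenetically corrected error:
p = (#{permuted MSE ≤ observed} + 1)/(reps + 1), default 999
permutations. Singular V (zero-length cherries, as produced by some
supertree tools) raises an error advising the optional ridge epsilon
(1e−8 on the diagonal, off by default). Constant traits are errors.

Hue θ is treated as a linear variable in degrees, not circular — a
deliberate fidelity choice to the source analysis tradition; for
floras whose hues straddle 0°/360° this inflates apparent divergence
(known limitation).

The Mantel statistic is the Pearson correlation of lower-triangle
entries; p is one-tailed (positive association) from joint row/column
permutations of the color matrix while the phylogenetic matrix is held
fixed (permuting the non-tree matrix preserves tree structure),
add-one smoothed, default 999 permutations.

## Synthetic data generator

Archetypes are logistic-step-plus-Gaussian-bump reflectance shapes
with fixed constants (so golden tests are stable): UV-absorbing white
(plateau 0.8, step at 400 nm), yellow with/without a UV bump at 350 nm
(step at 500 nm), blue (Gaussian peak at 450 nm), purple (blue peak +
long-wavelength step), long-red, and leaf green (baseline 0.05 +
Gaussian peak at 550 nm), each with Gaussian noise (sd 0.01, leaves
0.005) clipped to [0, 1]. Under the default leaf background the
archetypes map to the sectors their real counterparts occupy (white →
BG, UV-yellow → UG, blue → B) in ≥95% of draws.

Default study conditions mirror the field design the pipeline targets:
three altitude groups of 399/186/142 species; a mixture dominated by
white (0.47) and purple (0.25) with UV-present yellow 0.13, UV-absent
yellow 0.06, blue 0.05, red 0.04 (translating the reported human-color
frequencies onto the available archetypes); a pure-birth (Yule)
phylogeny over all species (birth rate 1); and per-group assembly
structure low = random, middle = clustered, high = overdispersed.
Structured groups select their members from a 3× oversampled candidate
set drawn from the group's mixture — clustered as a focal species plus
nearest color neighbors, overdispersed by greedy max-min — so that the
imposed structure is measured against the pooled community exactly as
in the analysis. Optionally one group's species are confined to the
smallest tree clade that can host them, creating phylogenetic
clustering.

Brownian trait evolution adds independent Gaussian increments per
branch (variance σ²·length); the 2-D color mode evolves x and y
independently — a simplification (real floral color evolution is
constrained to the hexagon and correlated across axes) used only to
create phylogenetically structured fixtures.

What the generator does **not** emulate: pigment chemistry (archetype
shapes are phenomenological), measurement artifacts beyond additive
noise, abundance structure, spatial autocorrelation of communities,
and trait-dependent diversification. Passing tests therefore
demonstrate correctness of the computations and calibration of the
statistics under idealized conditions, not robustness to every
property of field data.

## Problem sizes and defaults

Unit and property tests run on trees of 4–60 tips, pools of up to 200
species and 99–10,000 randomization replicates, chosen so the whole
suite completes in a few minutes on one core. Statistical calibration
uses 199 permutation replicates per run (making P(p ≤ 0.05) exactly
10/200 under the null) across 200 seeded runs, and 50-seed power
checks. The acceptance script runs the full 727-species study at the
production defaults (1000/999 replicates).

## Known limitations

- Hue circularity ignored (above).
- The hexagon orientation is a convention; compare absolute angles
  across software with care.
- The rarefaction separation rule (non-overlapping 95% intervals) is
  conservative and not a formal test.
- Cophenetic and covariance computations are dense O(n²); adequate for
  community-scale trees (≲ a few thousand tips), not for megatrees.
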