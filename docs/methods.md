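# Methods

This note documents the models and procedures implemented in `stacktraj`,
the assumptions behind them, the tunable parameters, and the design choices
made where several reasonable definitions exist.

## Input model

A *section* is one planar capture array: a spots×genes count matrix,
spot coordinates (µm), a per-spot anatomical region label, a position
`z_um` along the cutting axis, and a time-point label from
{control, sham, d1, d3, d7} (extensible via the manifest). Sections of one
time point form a serial stack ordered by `z_um`. Counts are assumed to be
non-negative integers (UMI counts); region labels are assumed to be
supplied by an upstream annotation step (e.g. registration to a reference
atlas) and are taken at face value.

Within a time point a shared gene universe is formed, by default the
**intersection** of the member sections' gene sets (sections are subset to
the sorted shared list). The union policy is also supported; under union,
genes absent from a section are treated as *not measured* there, never as
zero. Intersection is the default because the cross-section union of
transition-gene lists (below) presumes every listed gene was measurable in
every merged section.

## Planar pseudospace-time trajectories

**Normalization and smoothing.** Counts are library-size normalized to
10^4 per spot and log1p-transformed. Each spot's expression vector is then
blended with the mean of its spatial neighbours within
`smooth_radius_um` (default 1.5× the array pitch, the pitch estimated as
the median nearest-neighbour distance):
`x_i <- (1 - α)·x_i + α·mean(x_neighbours)` with `α = 0.7`. This
coordinate-based smoothing is what makes the ordering *pseudospace*-time:
it regularizes spot-level sampling noise using the spatial structure of
the tissue, without requiring histology images. The weight 0.7 was fixed
during initial calibration as the smallest value that gave stable region
separation on the synthetic conditions and is deliberately not exposed as
a per-run tuning knob in the pipeline configuration.

**Diffusion pseudotime.** PCA (30 components) of the smoothed matrix, a
k-nearest-neighbour graph (k = 15), diffusion maps and diffusion
pseudotime (DPT), all via scanpy. The root is the medoid (in PCA space)
spot of the configured root region (default `VL`). DPT values are min–max
rescaled to [0, 1], so root spots sit at 0. Degenerate inputs (no
expression variance, or fewer than three spots reachable from the root)
return all-zero pseudotime with an explicit `degenerate` flag; spots in
k-NN components disconnected from the root receive NaN and are flagged
`unreached`, never silently zeroed.

**Region graph.** Regions are nodes; a directed edge `A -> B` requires
(a) at least `min_adjacent` (default 3) spot pairs straddling the A/B
border within `adjacency_radius_um` (default 1.5× pitch) and (b) a median
pseudotime increase `median_pt(B) − median_pt(A) ≥ min_delta` (default
0.05, i.e. 5 % of the pseudotime range). Because every edge strictly
increases median pseudotime, the graph is acyclic by construction
(pseudotime is a potential function); equal medians yield no edge. Every
simple path from the root to a sink is one planar trajectory.

## 3D reconstruction

Planar trajectories from the serial sections of one time point are merged
into 3D trajectories. Two merge modes exist because the exact
cross-section matching criterion is a genuinely open design choice:

* `exact` — chains merge only when identical;
* `subsequence` (default) — a chain also supports a longer chain when it
  is a root-preserving subsequence of it (a thin section may simply miss a
  small region that a neighbouring section captures).

The implementation retains the *maximal* chains (those not a proper
subsequence of another observed chain); each maximal chain's support is
the number of distinct sections contributing a compatible chain. This
formulation is associative and independent of input order, and it never
forces a merge: chains that are mutually incompatible (e.g. the same
regions in different orders) stay separate. Chains with support below
`min_support` (default 2) are discarded. Results are ordered by
(support desc, chain lexicographic) for determinism.

**Bundle classification.** A reconstructed chain is classified by
configurable region classes: ending in a hippocampal region
({CA1, CA3, DG}) directly → bundle I; ending hippocampal having passed an
integrator region ({TH, HY, HYL, MB}) → bundle II; ending in a cortical
region ({I…VIb, RSP, PIR, CTXsp, COA, and the compound cortical-layer
labels}) → bundle III; anything else, or any chain containing a region in
no class and not on the pass-through list ({VL, fxs, cpd}), is
`unclassified` with a warning. The class sets are user-editable — they are
an anatomical convention, not an algorithmic constant — and the default
rule set is an endpoint-based approximation that does not attempt to
reproduce every historically published assignment (e.g. chains terminating
in white-matter or integrator regions are left unclassified rather than
guessed).

## Transition genes

For a subtrajectory `(r_i, r_{i+1})` of a trajectory, every gene's
log-normalized expression is Spearman-correlated with pseudotime **over
the spots of those two regions only** (not the whole chain): the intent is
to localize each transition to the border it crosses. At least
`min_spots = 10` spots are required; zero-variance genes are excluded;
ties in ρ break by gene identifier. The top `K = 30` genes by positive ρ
are "up", the top 30 by negative ρ "down".

Per-section lists for the same subtrajectory and time point merge into the
3D set by union. A gene listed with conflicting signs by different
sections keeps the signed score of greatest absolute value (an exact
|ρ| tie between conflicting signs keeps the positive one — an arbitrary
but deterministic convention). After merging, the pool is re-truncated to
the top K per direction by |ρ|, so the 3D set is again a top-30 set; the
alternative reading (no re-truncation, lists growing with section count)
is rejected because the merged set is meant to be comparable in size to a
planar set. The union is idempotent and commutative; a brute-force
enumeration oracle in the test suite verifies it exhaustively on random
instances.

No multiple-testing control is applied to ρ: the procedure ranks genes, it
does not test them.

## Subtype profiles, similarity, matching, pathways

The subtype profile of a trajectory at a time point is the signed union of
its subtrajectories' 3D transition sets, cross-subtrajectory sign
conflicts resolved by the same greatest-|score| rule.

**Similarity.** Two profiles are compared with a sign-aware Jaccard
index: the number of genes present in both profiles *with the same sign*,
divided by the size of the union of their gene sets. This is symmetric,
lies in [0, 1], equals 1 exactly for identical profiles and 0 exactly when
no gene agrees. A sign-aware definition is essential: a gene up-regulated
at one time and down-regulated at another is evidence of difference, not
similarity.

**Cell-type matching.** Profiles are matched against a local marker table
(`cell_type → gene set`, case-insensitive symbols) by the hypergeometric
upper-tail probability of the overlap between profile genes (signs
ignored) and each type's markers, against a universe defaulting to the
database's genes plus the profile's. The top 5 types per time point are
reported and unioned across a trajectory's time points. A local table with
hypergeometric scoring replaces any remote annotation service: it is
deterministic, offline, and swappable for any marker resource the user
trusts. Ties in p-value prefer the larger overlap, then the
lexicographically smaller name.

**Pathways.** Pathway sets are inputs (the output of whatever enrichment
tool the user runs on the marker genes). The mutual set is the
intersection; similarity is the overlap coefficient
`|P_A ∩ P_B| / min(|P_A|, |P_B|)`, chosen over Jaccard for robustness to
strongly unequal set sizes, and defined as 0 when either set is empty.

## Ligand–receptor communication density

For pair `LR_n` with ligand expression `L` and receptor expression `R`
(log-normalized), the raw per-spot intensity is

    raw_i = ½ · [ L_i · mean(R over neighbours of i)
                + R_i · mean(L over neighbours of i) ]

with neighbours the spots within `neighbor_radius` (default 1.5× pitch),
self excluded; spots without neighbours use a neighbour mean of 0 (an
isolated spot cannot exhibit juxtacrine-style signalling). The
symmetrized form makes the score direction-agnostic at spot resolution,
which is appropriate because a Visium spot contains a mixture of cells.

**Permutation null.** The spot labels of `L` and `R` are permuted
*jointly* (one permutation applied to both vectors per iteration,
`n_perm ≥ 100`, default 200) and `raw` recomputed; this preserves the
within-spot L/R coupling while destroying spatial structure, so the
z-score `Zscore_i = (raw_i − mean_null_i)/sd_null_i` measures *spatially
localized* co-expression rather than overall abundance. `sd_null = 0`
yields `Zscore = 0` with a degeneracy flag. The null standard deviation
uses the population convention (ddof = 0). Permutations are vectorized
(all `n_perm` shuffles as one matrix product per pair and section) and
seeded per (time point, pair, section) from the run seed via a stable
digest, so results are independent of iteration order.

**Discretization and density.** Default `binary` mode:
`ZT_i = 1{Zscore_i ≥ z*}` with `z* = 1.96` (the two-sided 5 % normal
quantile — the minimal defensible reading of "discrete interaction
intensity"); a `binned` mode `ZT_i = trunc(Zscore_i / z*)` is kept for
sensitivity analysis. Over the N spots of a trajectory's regions,
`ZT_Total = Σ ZT_i` and `Density = ZT_Total / N`; in binary mode Density
is the fraction of significant spots and is monotone non-decreasing as
`z*` is lowered. Z-scores are computed per section (the null is spatial,
hence section-local) and pooled across the time point's serial sections
before discretization, giving one density per (trajectory, time point,
pair).

**Cross-time-point comparison.** For one trajectory, the density vectors
over LR pairs at each time point are compared with the tie-corrected
Kruskal–Wallis test (groups = time points, observations = pairs). The
asymptotic χ² p-value is the default; a permutation p-value (shuffling the
pooled observations) is available and recommended when very few pairs per
group are present. All observations identical returns the convention
H = 0, p = 1. Simulation at the bundled null conditions (8 pairs per
group, 100-spot sections) puts the empirical type-I error of both methods
at 2.5–3 % at α = 5 % — slightly conservative, as expected for rank tests
on discrete densities — and power ≈ 1 at a 2-SD group shift with 50
observations per group.

## Synthetic data generator

The generator emulates the *structure* of a multi-section, multi-day
spatial study, not its biology:

* **Geometry** — square grid (default 400 spots at 100 µm pitch per
  section, 3 sections per time point 20 µm apart), regions as contiguous
  vertical bands ordered along the planted chain `VL -> A -> B -> C`.
  True pseudotime is the normalized band-axis coordinate, so the planted
  ordering is geometrically checkable.
* **Counts** — negative binomial with per-gene baseline log-means drawn
  once from Normal(2.0, 0.5) (≈ 7 counts/gene, ≈ 4·10³ UMI per spot over
  the 500-gene panel — comparable to Visium depth over an expressed-gene
  panel) and shared dispersion 0.3.
* **Transition genes** — per subtrajectory and time point, 30 up and 30
  down genes whose log-mean follows a clipped linear ramp across the
  pair's pseudotime span (slope `effect_size`, default 1.0 natural-log
  unit) and *plateaus* outside it, so planted genes are globally monotone
  in pseudotime. Sham/control time points draw from a pool disjoint from
  the injury time points'; successive injury days share a configurable
  fraction (default 0.8) of their pool. This reproduces the qualitative
  pattern that injury-phase subtype profiles resemble each other and
  differ from sham.
* **Hotspots** — per LR pair (default 8 pairs), a spatially contiguous
  patch (nearest 15 % of a region's spots around a random seed spot)
  multiplies both genes' means by `multiplier` (default 5), scaled by a
  per-time-point effect (default sham 0, d3 1, d7 0.1): communication
  rises sharply at day 3 and largely subsides by day 7.

Everything planted is recorded in a `GroundTruth` object (per-spot true
pseudotime, signed transition genes per subtrajectory and time point,
hotspot spot sets, per-time-point marker sets) and serialized alongside
the dataset. Generation is deterministic given the config seed, to the
byte.

**What the generator does not emulate** — and what passing tests therefore
do not show: realistic transcriptome composition or dropout structure,
curved or branching anatomy (bands are straight and parallel), partial
region overlap between serial sections, cell-type mixtures within spots,
image-derived features, or any mechanistic injury biology. Recovery rates
measured here are best-case figures for data whose spatial signal matches
the model's assumptions.

## Problem sizes and reproducibility

The bundled test suite and the acceptance script run the full method at
the default conditions (9 sections of 400 spots, 500 genes; the
transition-gene recovery check at 200 spots per section; Kruskal–Wallis
calibration over 200 simulated null datasets of 3×100 spots). These sizes
were chosen so the whole battery completes in about a minute on one CPU
while keeping every statistical check at a sample size where its nominal
behaviour is measurable. All randomness flows from explicit seeds;
pipeline outputs are byte-stable for a fixed configuration and seed, and
`report.json` records per-file SHA-256 checksums so reruns can be
verified.

## Known limitations

* Pseudotime quality degrades when expression varies weakly along the
  tissue axis; the degeneracy flags report, but cannot repair, such cases.
* The region graph assumes region-level monotone progression; trajectories
  that re-enter a region are not representable (chains are simple paths).
* The subsequence merge can attribute one planar chain's support to
  several maximal chains when the planar chain is compatible with more
  than one; support values are therefore upper bounds under heavy
  branching.
* Subtype profiles are transition-gene unions; no additional
  differential-expression filter is applied.
* The Kruskal–Wallis comparison treats LR pairs as independent
  observations, which underestimates dependence between pairs sharing a
  gene.
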