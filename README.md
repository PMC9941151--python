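# stacktraj

**3D pseudospace-time trajectory analysis for serial-section spatial
transcriptomics.**

Spatially resolved transcriptomics (Visium-style arrays) measures gene
expression at thousands of tissue spots per planar section. When several
serial sections are cut through the same tissue — for example coronal brain
sections collected at successive depths after an acute injury, across
several post-injury days — the interesting questions become three
dimensional and temporal: along which chains of anatomical regions does the
transcriptional perturbation propagate, which genes change along those
chains, how do the resulting cell states evolve over days, and where is
ligand–receptor signalling concentrated?

`stacktraj` is a toolkit for exactly this setting. It is aimed at
computational biologists who have per-section spot×gene count matrices,
spot coordinates and per-spot anatomical region labels, and want
reproducible region-level trajectory and communication statistics across a
stack of sections and a panel of time points.

## What it computes

1. **Planar pseudospace-time trajectories.** Per section, counts are
   log-normalized, spatially smoothed (each spot blended with the mean of
   its neighbours within 1.5× the array pitch, weight 0.7), and diffusion
   pseudotime (DPT) is computed on a k-NN graph over the PCA of the
   smoothed matrix, rooted at the medoid spot of a root region (default
   `VL`, the lateral ventricle). Regions become nodes of a directed graph
   with an edge `A -> B` when the regions are spatially adjacent and
   median pseudotime rises by at least `min_delta`; every simple
   root-to-sink path is one planar trajectory.
2. **3D reconstruction.** Planar trajectories from the serial sections of
   one time point are merged when their region chains agree exactly, or
   when one chain is a root-preserving subsequence of the other; the
   number of distinct supporting sections is the chain's *support*, and
   chains below `min_support` are dropped. Chains are classified into
   bundles by their endpoint: hippocampal directly (I), hippocampal via a
   thalamic/hypothalamic integrator (II), or cortical (III).
3. **Transition genes.** For each subtrajectory (consecutive region pair),
   genes are ranked by Spearman correlation ρ of expression with
   pseudotime over the pair's spots; the top 30 positive and top 30
   negative are the up/down transition genes. Per-section lists are merged
   into the 3D set by union; a gene reported with conflicting signs keeps
   the signed ρ of greatest absolute value, and the merged pool is
   re-truncated to the top 30 per direction.
4. **Cell-subtype profiles.** The signed union of a trajectory's 3D
   transition sets is its subtype profile CellT<sup>trajectory</sup><sub>time</sub>.
   Profiles at different time points are compared by a sign-aware Jaccard
   similarity (agreeing signed genes / union of genes), matched against a
   local cell-type marker table by hypergeometric enrichment (top 5 types,
   then union across time points), and pathway-ID sets are compared with
   the overlap coefficient |P<sub>A</sub> ∩ P<sub>B</sub>| / min(|P<sub>A</sub>|, |P<sub>B</sub>|).
5. **Communication density.** For each ligand–receptor pair LR<sub>n</sub>,
   the per-spot intensity ½·[L<sub>i</sub>·mean(R over neighbours) +
   R<sub>i</sub>·mean(L over neighbours)] is z-scored against a spatial
   permutation null (Zscore<sup>LRn</sup><sub>i</sub>), discretized
   (ZT<sup>LRn</sup><sub>i</sub> = 1 if Zscore ≥ 1.96), and aggregated over
   the N spots of a trajectory's regions:
   **Density<sup>LRn</sup> = ZT<sub>Total</sub> / N.** Densities across
   time points are compared with the Kruskal–Wallis test.

A negative-binomial synthetic-data generator with planted region chains,
pseudotime-graded transition genes and ligand–receptor hotspots ships as a
first-class module, so every stage can be exercised — and its error
measured — against known ground truth.

## Worked example

```python
import stacktraj as st
from stacktraj.pipeline import grid_spacing

config = st.SyntheticConfig(seed=0)          # 3 time points x 3 sections x 400 spots
mds, truth = st.generate_dataset(config)

planar = {tp: [] for tp in mds.timepoints}
pts = {}
for section in mds.sections:
    res = st.compute_pseudotime(section, root_region="VL")
    pts[section.section_id] = res.values
    graph = st.build_region_graph(section, res.values, 1.5 * grid_spacing(section))
    planar[section.timepoint].extend(
        st.extract_planar_trajectories(graph, "VL", section, res.values))

section_z = {s.section_id: s.z_um for s in mds.sections}
for traj in st.reconstruct_3d(planar, section_z, min_support=2):
    print(f"{traj.timepoint:>5}  {'->'.join(traj.chain):<14} support={traj.support}")

sections = mds.sections_by_timepoint["d3"]
merged = st.union_3d([
    st.rank_transition_genes(s, ("A", "B"), pts[s.section_id]) for s in sections])
print("top 5 up-regulated A->B transition genes at d3:",
      [(g, round(merged.scores[g], 2)) for g in merged.up[:5]])

pairs = [st.LRPair(h.ligand, h.receptor) for h in config.lr_hotspots]
table, _ = st.communication.communication_table(
    mds, config.planted_chain, pairs, "VL->A->B->C", 150.0, n_perm=200, seed=0)
print(table.groupby("timepoint")["density"].mean().round(4).to_dict())
```

prints

```
   d3  VL->A->B->C    support=3
   d7  VL->A->B->C    support=3
 sham  VL->A->B->C    support=3
top 5 up-regulated A->B transition genes at d3: [('G0193', 0.52), ('G0217', 0.5), ('G0194', 0.49), ('G0196', 0.48), ('G0204', 0.48)]
{'d3': 0.0429, 'd7': 0.0189, 'sham': 0.018}
```

The planted chain `VL->A->B->C` is recovered at every time point with full
section support; the `A->B` transition list is dominated by planted genes
(IDs `G0181`–`G0240` belong to that subtrajectory's day-3 pool); and the
mean communication density over the eight planted ligand–receptor pairs
rises from sham to day 3 and falls back by day 7 — the generator's
configured rise-then-fall dynamic.

## Command line

```sh
stacktraj simulate out/dataset --seed 0          # write a synthetic dataset + ground truth
stacktraj run-all config.yaml --seed 0           # run every stage from a YAML config
```

`run-all` writes tidy TSVs (`pseudotime.tsv`, `trajectories.tsv`,
`transition_genes.tsv`, `subtype_profiles.tsv`, `subtype_similarity.tsv`,
`cell_type_matches.tsv`, `communication_density.tsv`,
`communication_spots.tsv`, `density_tests.tsv`, `pathway_similarity.tsv`) plus `report.json` with the configuration echo,
seed, per-stage record counts and per-file SHA-256 checksums. Exit codes:
0 success, 2 validation error, 3 stage failure.

## Documentation

`docs/methods.md` describes the model and procedure in detail: the
assumptions behind each stage, every tunable parameter with its default and
rationale, what the synthetic generator does and does not emulate, and the
package's known limitations.
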