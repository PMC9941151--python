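"""Planar pseudotime, region-level trajectories, and 3D reconstruction.

The analysis proceeds in three steps per time point:

1. **Planar pseudotime** per section: counts are log-normalized, each
   spot's expression is blended with the mean of its spatial neighbours
   (the coordinate-based analogue of spatially-aware normalization, which
   is what makes the ordering *pseudospace*-time rather than plain
   pseudotime), and diffusion pseudotime (DPT) is computed on a
   k-nearest-neighbour graph over the PCA of the smoothed matrix, rooted
   at the medoid spot of a chosen root region (by default ``VL``, the
   lateral ventricle), min-max rescaled to [0, 1].
2. **Planar trajectories**: regions become nodes of a directed graph with
   an edge ``A -> B`` when the two regions are spatially adjacent and B's
   median pseudotime exceeds A's by at least ``min_delta``; every simple
   root-to-sink path is one planar pseudospace-time trajectory.
3. **3D reconstruction**: planar trajectories from the serial sections of
   one time point are merged when their region chains agree exactly, or —
   in ``subsequence`` mode — when the shorter chain is a root-preserving
   subsequence of the longer.  A merged chain's *support* is the number of
   distinct sections contributing a compatible planar chain; chains below
   ``min_support`` are dropped.

Reconstructed trajectories are classified into bundles by where they end:
directly in the hippocampus (I), in the hippocampus via a
thalamic/hypothalamic integrator region (II), or in the cortex (III).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scanpy as sc
from anndata import AnnData
from scipy.sparse.csgraph import connected_components

from ._utils import grid_spacing, log_normalize, neighbor_graph, smooth_expression
from .io import SectionDataset

__all__ = [
    "BundleRules",
    "DEFAULT_BUNDLE_RULES",
    "PlanarTrajectory",
    "PseudotimeResult",
    "RegionGraph",
    "Trajectory3D",
    "build_region_graph",
    "classify_bundle",
    "compute_pseudotime",
    "extract_planar_trajectories",
    "reconstruct_3d",
]


@dataclass
class PseudotimeResult:
    """Per-spot pseudotime in [0, 1] with degeneracy bookkeeping.

    ``values`` is NaN for spots unreachable from the root on the k-NN graph
    (those are flagged in ``unreached``, never silently zeroed).
    ``degenerate`` is set when expression carries no usable ordering signal
    (e.g. all spots identical), in which case values are all zero.
    """

    values: np.ndarray
    root_spot: int
    unreached: np.ndarray
    degenerate: bool = False


def compute_pseudotime(
    section: SectionDataset,
    root_region: str = "VL",
    k_neighbors: int = 15,
    n_pcs: int = 30,
    smoothing_alpha: float = 0.7,
    smooth_radius_um: float | None = None,
) -> PseudotimeResult:
    """Diffusion pseudotime rooted at the medoid spot of ``root_region``.

    Counts are library-size normalized and log1p-transformed, spatially
    smoothed (each spot blended with the mean of its neighbours within
    ``smooth_radius_um``, default 1.5x the array pitch, with weight
    ``smoothing_alpha``), reduced to ``n_pcs`` principal components, and a
    ``k_neighbors`` nearest-neighbour graph is built; DPT distances from
    the root are min-max rescaled so the root is at 0.  Spots in connected
    components not containing the root receive NaN and are flagged.
    """
    if root_region not in section.region_labels:
        raise ValueError(f"root region {root_region!r} absent from section {section.section_id}")

    X = log_normalize(section.counts)
    if smooth_radius_um is None:
        smooth_radius_um = 1.5 * grid_spacing(section.coords)
    X = smooth_expression(X, section.coords, smooth_radius_um, smoothing_alpha)
    adata = AnnData(
        X=X.astype(np.float32),
        obs=pd.DataFrame(index=pd.Index(section.spot_ids, name="barcode")),
    )

    if np.allclose(X.var(axis=0), 0):
        return PseudotimeResult(
            values=np.zeros(section.n_spots),
            root_spot=int(np.nonzero(np.asarray(section.region_labels) == root_region)[0][0]),
            unreached=np.zeros(section.n_spots, dtype=bool),
            degenerate=True,
        )

    n_comps = int(min(n_pcs, section.n_spots - 1, section.n_genes - 1))
    sc.pp.pca(adata, n_comps=n_comps)
    k = int(min(k_neighbors, section.n_spots - 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.neighbors(adata, n_neighbors=k, n_pcs=n_comps)

    pca = adata.obsm["X_pca"]
    root_mask = np.asarray(section.region_labels) == root_region
    root_idx = np.nonzero(root_mask)[0]
    # medoid of the root region in PCA space
    d = np.linalg.norm(pca[root_idx][:, None, :] - pca[root_idx][None, :, :], axis=-1)
    root_spot = int(root_idx[np.argmin(d.sum(axis=1))])

    conn = adata.obsp["connectivities"]
    n_comp, labels = connected_components(conn, directed=False)
    reachable = labels == labels[root_spot]
    values = np.full(section.n_spots, np.nan)

    if reachable.sum() < 3:
        return PseudotimeResult(
            values=np.zeros(section.n_spots),
            root_spot=root_spot,
            unreached=~reachable,
            degenerate=True,
        )

    if n_comp > 1:
        sub = adata[reachable].copy()
        sub.uns["iroot"] = int(np.nonzero(np.nonzero(reachable)[0] == root_spot)[0][0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.pp.neighbors(sub, n_neighbors=min(k, sub.n_obs - 1), n_pcs=n_comps)
            sc.tl.diffmap(sub)
            sc.tl.dpt(sub)
        pt = sub.obs["dpt_pseudotime"].to_numpy()
        values[reachable] = pt
    else:
        adata.uns["iroot"] = root_spot
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.tl.diffmap(adata)
            sc.tl.dpt(adata)
        values = adata.obs["dpt_pseudotime"].to_numpy().astype(float)

    finite = np.isfinite(values)
    degenerate = False
    span = np.nanmax(values[finite]) - np.nanmin(values[finite]) if finite.any() else 0.0
    if not finite.any() or span == 0:
        values = np.where(finite, 0.0, np.nan)
        degenerate = True
    else:
        lo = np.nanmin(values[finite])
        values = (values - lo) / span
    return PseudotimeResult(
        values=values, root_spot=root_spot, unreached=~finite, degenerate=degenerate
    )


@dataclass
class RegionGraph:
    """Directed acyclic graph over a section's regions.

    Edge ``A -> B`` carries ``n_adjacent`` (spot pairs straddling the
    border within the adjacency radius) and ``delta`` (median pseudotime
    increase from A to B).
    """

    graph: nx.DiGraph
    section_id: str

    @property
    def regions(self) -> list[str]:
        return list(self.graph.nodes)


def build_region_graph(
    section: SectionDataset,
    pseudotime: np.ndarray,
    adjacency_radius_um: float,
    min_delta: float = 0.05,
    min_adjacent: int = 3,
) -> RegionGraph:
    """Build the directed region graph from spatial adjacency and pseudotime.

    An edge ``A -> B`` requires at least ``min_adjacent`` spot pairs within
    ``adjacency_radius_um`` across the A/B border and a median-pseudotime
    increase of at least ``min_delta``.  Equal medians never produce an
    edge, so the graph is acyclic by construction (pseudotime acts as a
    potential function); this is still verified.
    """
    regions = np.asarray(section.region_labels)
    adj = neighbor_graph(section.coords, adjacency_radius_um).tocoo()
    pair_counts: dict[tuple[str, str], int] = {}
    for i, j in zip(adj.row, adj.col):
        if i < j and regions[i] != regions[j]:
            key = tuple(sorted((str(regions[i]), str(regions[j]))))
            pair_counts[key] = pair_counts.get(key, 0) + 1

    medians = {
        r: float(np.nanmedian(pseudotime[regions == r]))
        for r in dict.fromkeys(section.region_labels)
    }
    g = nx.DiGraph()
    g.add_nodes_from(dict.fromkeys(section.region_labels))
    for (a, b), n_adj in sorted(pair_counts.items()):
        if n_adj < min_adjacent:
            continue
        delta = medians[b] - medians[a]
        if delta >= min_delta:
            g.add_edge(a, b, n_adjacent=n_adj, delta=delta)
        elif -delta >= min_delta:
            g.add_edge(b, a, n_adjacent=n_adj, delta=-delta)

    while not nx.is_directed_acyclic_graph(g):  # pragma: no cover - unreachable by construction
        cycle = nx.find_cycle(g)
        weakest = min(cycle, key=lambda e: g.edges[e]["delta"])
        g.remove_edge(*weakest[:2])
    return RegionGraph(graph=g, section_id=section.section_id)


@dataclass
class PlanarTrajectory:
    """An ordered region chain in one section with its spot pseudotimes."""

    section_id: str
    chain: tuple[str, ...]
    spot_pseudotime: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chain:
            raise ValueError("empty trajectory chain")
        if len(set(self.chain)) != len(self.chain):
            raise ValueError(f"repeated region in chain {self.chain}")

    @property
    def subtrajectories(self) -> list[tuple[str, str]]:
        return [(self.chain[i], self.chain[i + 1]) for i in range(len(self.chain) - 1)]


def extract_planar_trajectories(
    region_graph: RegionGraph,
    root_region: str,
    section: SectionDataset | None = None,
    pseudotime: np.ndarray | None = None,
) -> list[PlanarTrajectory]:
    """Enumerate all simple root-to-sink paths as planar trajectories.

    When ``section`` and ``pseudotime`` are given, each trajectory carries
    the pseudotime of the spots in its chain regions.
    """
    g = region_graph.graph
    if root_region not in g:
        raise ValueError(f"root region {root_region!r} not in region graph")
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("region graph contains a cycle")

    sinks = [n for n in g.nodes if g.out_degree(n) == 0]
    chains: list[tuple[str, ...]] = []
    for sink in sinks:
        if sink == root_region:
            if g.out_degree(root_region) == 0:
                chains.append((root_region,))
            continue
        for path in nx.all_simple_paths(g, root_region, sink):
            chains.append(tuple(path))

    trajectories = []
    for chain in sorted(chains):
        spot_pt: dict[str, float] = {}
        if section is not None and pseudotime is not None:
            mask = np.isin(np.asarray(section.region_labels), chain)
            for i in np.nonzero(mask)[0]:
                spot_pt[section.spot_ids[i]] = float(pseudotime[i])
        trajectories.append(
            PlanarTrajectory(section_id=region_graph.section_id, chain=chain, spot_pseudotime=spot_pt)
        )
    return trajectories


@dataclass
class Trajectory3D:
    """A region chain supported by several serial sections of one time point."""

    timepoint: str
    chain: tuple[str, ...]
    supporting_sections: list[tuple[str, float]]
    bundle: str = "unclassified"

    @property
    def support(self) -> int:
        return len(self.supporting_sections)


def _is_root_subsequence(short: Sequence[str], long: Sequence[str]) -> bool:
    """True when ``short`` is a subsequence of ``long`` sharing its root."""
    if not short or not long or short[0] != long[0]:
        return False
    it = iter(long)
    return all(r in it for r in short)


def reconstruct_3d(
    planar_by_timepoint: Mapping[str, Sequence[PlanarTrajectory]],
    section_z: Mapping[str, float],
    min_support: int = 2,
    merge_mode: str = "subsequence",
    bundle_rules: "BundleRules | None" = None,
) -> list[Trajectory3D]:
    """Merge planar trajectories across serial sections into 3D trajectories.

    Within each time point the *maximal* chains are retained: in ``exact``
    mode every distinct chain is maximal; in ``subsequence`` mode a chain is
    maximal if it is not a proper root-preserving subsequence of another
    observed chain.  A maximal chain is supported by every section that
    contributed a compatible (equal or, in subsequence mode, subsequence)
    chain, so unmergeable chains simply remain separate.  The result is
    order-independent in the input trajectories.  Chains with support below
    ``min_support`` are dropped; output is sorted by (support descending,
    chain lexicographic).
    """
    if merge_mode not in ("exact", "subsequence"):
        raise ValueError(f"unknown merge_mode {merge_mode!r}")
    rules = bundle_rules or DEFAULT_BUNDLE_RULES

    out: list[Trajectory3D] = []
    for timepoint, trajectories in planar_by_timepoint.items():
        chains = sorted(set(t.chain for t in trajectories))
        if merge_mode == "subsequence":
            maximal = [
                c
                for c in chains
                if not any(c != other and _is_root_subsequence(c, other) for other in chains)
            ]
        else:
            maximal = chains

        for chain in maximal:
            supporting: dict[str, float] = {}
            for t in trajectories:
                compatible = t.chain == chain or (
                    merge_mode == "subsequence" and _is_root_subsequence(t.chain, chain)
                )
                if compatible:
                    supporting[t.section_id] = float(section_z.get(t.section_id, np.nan))
            if len(supporting) < min_support:
                continue
            out.append(
                Trajectory3D(
                    timepoint=timepoint,
                    chain=chain,
                    supporting_sections=sorted(supporting.items()),
                    bundle=classify_bundle(chain, rules),
                )
            )
    out.sort(key=lambda t: (-t.support, t.timepoint, t.chain))
    return out


# ---------------------------------------------------------------------------
# bundle classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BundleRules:
    """Region classes deciding the bundle of a trajectory.

    A chain ending in a hippocampal region is bundle II when it passes
    through an integrator (thalamic/hypothalamic/midbrain) region, else
    bundle I; a chain ending in a cortical region is bundle III; anything
    else — including chains touching regions in no class and not on the
    pass-through list — is unclassified.
    """

    hippocampal: frozenset[str] = frozenset({"CA1", "CA3", "DG"})
    integrator: frozenset[str] = frozenset({"TH", "HY", "HYL", "MB"})
    cortical: frozenset[str] = frozenset(
        {"I", "II", "III", "IV", "V", "VIa", "VIb", "RSP", "PIR", "CTXsp", "COA",
         "(II, III, IV)", "(V, VIa, VIb)"}
    )
    passthrough: frozenset[str] = frozenset({"VL", "fxs", "cpd"})

    @property
    def known(self) -> frozenset[str]:
        return self.hippocampal | self.integrator | self.cortical | self.passthrough


DEFAULT_BUNDLE_RULES = BundleRules()


def classify_bundle(chain: Sequence[str], rules: BundleRules = DEFAULT_BUNDLE_RULES) -> str:
    """Classify a region chain into bundle I, II, III or ``unclassified``."""
    unknown = [r for r in chain if r not in rules.known]
    if unknown:
        warnings.warn(
            f"chain {tuple(chain)} contains unknown regions {unknown}; leaving unclassified",
            stacklevel=2,
        )
        return "unclassified"
    last = chain[-1]
    if last in rules.hippocampal:
        if any(r in rules.integrator for r in chain):
            return "II"
        return "I"
    if last in rules.cortical:
        return "III"
    return "unclassified"
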