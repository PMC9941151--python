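"""Pseudotime, region graphs, path extraction, 3D merging and bundles."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest
from scipy.sparse.csgraph import shortest_path
from scipy.stats import spearmanr

import stacktraj as st
from stacktraj._utils import neighbor_graph
from stacktraj.trajectories import BundleRules, PlanarTrajectory, RegionGraph


class TestComputePseudotime:
    def test_orders_spots_along_1d_band(self, section_factory):
        """On a 1D band with the root at one end, pseudotime rank order
        follows geodesic hop distance from the root.

        The oracle is a breadth-first geodesic on the spatial line graph —
        independent of the expression-based k-NN graph the method uses.
        """
        rng = np.random.default_rng(17)
        n = 80
        coords = np.column_stack([np.arange(float(n)) * 100, np.zeros(n)])
        ramp = np.arange(n) / (n - 1)
        logmean = np.tile(rng.normal(2.0, 0.3, 40), (n, 1))
        logmean[:, :10] += 1.5 * ramp[:, None]  # up genes
        logmean[:, 10:20] -= 1.5 * ramp[:, None]  # down genes
        counts = rng.poisson(np.exp(logmean))
        s = section_factory(coords, ["VL"] * 20 + ["A"] * 30 + ["B"] * 30, counts)
        res = st.compute_pseudotime(s, "VL")
        assert not res.degenerate
        assert res.unreached.sum() == 0
        adj = neighbor_graph(s.coords, 110.0)
        hops = shortest_path(adj, unweighted=True, indices=res.root_spot)
        rho = spearmanr(res.values, hops).statistic
        assert rho > 0.9

    def test_no_degeneracy_on_default_sections(self, default_dataset):
        mds, _ = default_dataset
        s = mds.sections_by_timepoint["d3"][0]
        res = st.compute_pseudotime(s, "VL")
        assert not res.degenerate
        assert res.unreached.sum() == 0

    def test_root_spot_at_zero(self, default_dataset):
        mds, _ = default_dataset
        s = mds.sections_by_timepoint["sham"][0]
        res = st.compute_pseudotime(s, "VL")
        assert res.values[res.root_spot] == 0.0
        assert np.nanmin(res.values) == 0.0 and np.nanmax(res.values) == 1.0

    def test_identical_expression_flags_degenerate(self, section_factory):
        coords = np.column_stack([np.arange(30.0) * 100, np.zeros(30)])
        counts = np.full((30, 5), 7)
        s = section_factory(coords, ["VL"] * 15 + ["A"] * 15, counts)
        res = st.compute_pseudotime(s, "VL")
        assert res.degenerate
        assert np.all(res.values[~res.unreached] == 0.0)

    def test_missing_root_region_raises(self, section_factory):
        coords = np.column_stack([np.arange(12.0) * 100, np.zeros(12)])
        s = section_factory(coords, ["A"] * 12, np.ones((12, 3), dtype=int))
        with pytest.raises(ValueError, match="root region"):
            st.compute_pseudotime(s, "VL")

    def test_invariant_under_spot_relabeling(self, dataset_200):
        """Permuting spot order permutes pseudotime accordingly."""
        mds, _ = dataset_200
        s = mds.sections_by_timepoint["d3"][0]
        res = st.compute_pseudotime(s, "VL")
        perm = np.random.default_rng(4).permutation(s.n_spots)
        import scipy.sparse as sp

        shuffled = st.SectionDataset(
            section_id=s.section_id,
            timepoint=s.timepoint,
            z_um=s.z_um,
            spot_ids=[s.spot_ids[i] for i in perm],
            coords=s.coords[perm],
            counts=sp.csr_matrix(np.asarray(s.counts.todense())[perm]),
            gene_ids=s.gene_ids,
            region_labels=[s.region_labels[i] for i in perm],
        )
        res2 = st.compute_pseudotime(shuffled, "VL")
        rho = spearmanr(res.values[perm], res2.values).statistic
        assert rho > 0.99


class TestRegionGraph:
    def _band_section(self, section_factory, labels):
        n = len(labels)
        coords = np.column_stack([np.arange(float(n)) * 100, np.zeros(n)])
        return section_factory(coords, labels, np.ones((n, 3), dtype=int))

    def test_adjacent_with_delta_gets_one_edge(self, section_factory):
        s = self._band_section(section_factory, ["A"] * 5 + ["B"] * 5)
        pt = np.array([0.2] * 5 + [0.6] * 5)
        rg = st.build_region_graph(s, pt, adjacency_radius_um=150.0, min_adjacent=1)
        assert list(rg.graph.edges) == [("A", "B")]

    def test_equal_medians_no_edge(self, section_factory):
        s = self._band_section(section_factory, ["A"] * 5 + ["B"] * 5)
        pt = np.full(10, 0.5)
        rg = st.build_region_graph(s, pt, adjacency_radius_um=150.0, min_adjacent=1)
        assert not list(rg.graph.edges)

    def test_non_adjacent_regions_never_linked(self, section_factory):
        s = self._band_section(section_factory, ["A"] * 3 + ["C"] * 3 + ["B"] * 4)
        pt = np.array([0.1] * 3 + [0.5] * 3 + [0.9] * 4)
        rg = st.build_region_graph(s, pt, adjacency_radius_um=150.0, min_adjacent=1)
        assert ("A", "B") not in rg.graph.edges

    def test_min_adjacent_threshold(self, section_factory):
        s = self._band_section(section_factory, ["A"] * 5 + ["B"] * 5)
        pt = np.array([0.2] * 5 + [0.6] * 5)
        rg = st.build_region_graph(s, pt, adjacency_radius_um=150.0, min_adjacent=5)
        assert not list(rg.graph.edges)  # only one straddling pair on a 1D band


def _graph_of(edges, section_id="s0"):
    g = nx.DiGraph()
    g.add_edges_from(edges)
    return RegionGraph(graph=g, section_id=section_id)


class TestExtractPlanar:
    def test_single_path(self):
        rg = _graph_of([("VL", "A"), ("A", "B")])
        out = st.extract_planar_trajectories(rg, "VL")
        assert [t.chain for t in out] == [("VL", "A", "B")]

    def test_branching_enumerates_all_paths(self):
        rg = _graph_of([("VL", "A"), ("A", "B"), ("VL", "C")])
        out = st.extract_planar_trajectories(rg, "VL")
        assert sorted(t.chain for t in out) == [("VL", "A", "B"), ("VL", "C")]

    def test_cycle_rejected(self):
        rg = _graph_of([("VL", "A"), ("A", "B"), ("B", "VL")])
        with pytest.raises(ValueError, match="cycle"):
            st.extract_planar_trajectories(rg, "VL")

    def test_root_absent_rejected(self):
        rg = _graph_of([("A", "B")])
        with pytest.raises(ValueError, match="root region"):
            st.extract_planar_trajectories(rg, "VL")


class TestReconstruct3D:
    Z = {"s1": 0.0, "s2": 20.0, "s3": 40.0}

    def _pt(self, sid, chain):
        return PlanarTrajectory(section_id=sid, chain=tuple(chain))

    def test_exact_merge_counts_support(self):
        planar = {"d3": [self._pt("s1", ["VL", "CA1", "DG"]), self._pt("s2", ["VL", "CA1", "DG"])]}
        out = st.reconstruct_3d(planar, self.Z, min_support=2, merge_mode="exact")
        assert len(out) == 1
        assert out[0].chain == ("VL", "CA1", "DG")
        assert out[0].support == 2

    def test_below_min_support_dropped(self):
        planar = {"d3": [self._pt("s1", ["VL", "CA1", "DG"])]}
        assert st.reconstruct_3d(planar, self.Z, min_support=2) == []

    def test_subsequence_merges_to_longer_chain(self):
        planar = {
            "d3": [self._pt("s1", ["VL", "CA1", "DG"]), self._pt("s2", ["VL", "fxs", "CA1", "DG"])]
        }
        out = st.reconstruct_3d(planar, self.Z, min_support=2, merge_mode="subsequence")
        assert len(out) == 1
        assert out[0].chain == ("VL", "fxs", "CA1", "DG")
        assert out[0].support == 2

    def test_subsequence_must_preserve_root(self):
        planar = {
            "d3": [self._pt("s1", ["CA1", "DG"]), self._pt("s2", ["VL", "fxs", "CA1", "DG"])]
        }
        out = st.reconstruct_3d(planar, self.Z, min_support=1, merge_mode="subsequence")
        assert sorted(t.chain for t in out) == [("CA1", "DG"), ("VL", "fxs", "CA1", "DG")]

    def test_unmergeable_chains_stay_separate(self):
        planar = {
            "d3": [
                self._pt("s1", ["VL", "A", "B"]),
                self._pt("s2", ["VL", "B", "A"]),
            ]
        }
        out = st.reconstruct_3d(planar, self.Z, min_support=1)
        assert len(out) == 2

    def test_merge_is_input_order_invariant(self):
        """Associativity: any grouping/order of the planar pool gives one result."""
        rng = np.random.default_rng(9)
        regions = ["VL", "A", "B", "C", "D"]
        pool = []
        for i, sid in enumerate(["s1", "s2", "s3"]):
            for _ in range(3):
                k = rng.integers(1, 5)
                chain = ["VL"] + [regions[j] for j in sorted(rng.choice([1, 2, 3, 4], size=k, replace=False))]
                pool.append(self._pt(sid, chain))
        ref = st.reconstruct_3d({"d3": pool}, self.Z, min_support=1)
        for _ in range(5):
            shuffled = list(pool)
            rng.shuffle(shuffled)
            out = st.reconstruct_3d({"d3": shuffled}, self.Z, min_support=1)
            assert [(t.chain, t.support) for t in out] == [(t.chain, t.support) for t in ref]

    def test_planted_chain_recovered_on_synthetic(self, default_analysis, default_dataset):
        _, gt = default_dataset
        out = st.reconstruct_3d(
            default_analysis["planar"], default_analysis["section_z"], min_support=2
        )
        for tp in ("sham", "d3", "d7"):
            match = [t for t in out if t.timepoint == tp]
            assert len(match) == 1
            assert match[0].chain == gt.config.planted_chain
            assert match[0].support == 3


class TestBundles:
    @pytest.mark.parametrize(
        "chain,expected",
        [
            (("VL", "fxs", "CA1", "DG"), "I"),
            (("VL", "cpd", "HY", "TH", "CA1", "DG"), "II"),
            (("VL", "I", "RSP"), "III"),
        ],
    )
    def test_reference_chains(self, chain, expected):
        assert st.classify_bundle(chain) == expected

    def test_unknown_region_warns_unclassified(self):
        with pytest.warns(UserWarning, match="unknown regions"):
            assert st.classify_bundle(("VL", "XYZ", "CA1")) == "unclassified"

    def test_custom_rules(self):
        rules = BundleRules(
            hippocampal=frozenset({"C"}),
            integrator=frozenset(),
            cortical=frozenset(),
            passthrough=frozenset({"VL", "A", "B"}),
        )
        assert st.classify_bundle(("VL", "A", "B", "C"), rules) == "I"
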