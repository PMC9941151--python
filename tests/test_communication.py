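"""Ligand-receptor intensity, permutation z-scores, density, Kruskal-Wallis."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.stats

import stacktraj as st
from stacktraj.communication import GeneMissingError, communication_table

from _oracles import kruskal_wallis_reference


PAIR = st.LRPair("Lig", "Rec")


def lr_section(section_factory, L, R, spacing=100.0, regions=None):
    n = len(L)
    coords = np.column_stack([np.arange(float(n)) * spacing, np.zeros(n)])
    counts = np.column_stack([L, R]).astype(int)
    return section_factory(
        coords, regions or ["A"] * n, counts, gene_ids=["Lig", "Rec"]
    )


class TestSelectSpots:
    def test_counts_spots_on_chain(self, section_factory):
        coords = np.column_stack([np.arange(20.0) * 100, np.zeros(20)])
        labels = ["VL"] * 10 + ["CA1"] * 5 + ["DG"] * 5
        s = section_factory(coords, labels, np.ones((20, 2), dtype=int))
        idx = st.select_trajectory_spots(s, ["VL", "CA1", "DG"])
        assert idx.size == 20
        assert st.select_trajectory_spots(s, ["CA1", "DG"]).size == 10

    def test_no_chain_spots_rejected(self, section_factory):
        coords = np.column_stack([np.arange(4.0) * 100, np.zeros(4)])
        s = section_factory(coords, ["A"] * 4, np.ones((4, 2), dtype=int))
        with pytest.raises(ValueError, match="no spots"):
            st.select_trajectory_spots(s, ["VL"])


class TestRawIntensity:
    def test_uniform_expression_gives_squared_value(self, section_factory):
        s = lr_section(section_factory, np.full(10, 7), np.full(10, 7))
        raw = st.spot_intensity(s, PAIR, neighbor_radius_um=150.0)
        from stacktraj._utils import log_normalize

        v = log_normalize(s.counts)[0, 0]
        np.testing.assert_allclose(raw, v**2)

    def test_zero_ligand_and_neighbors_zero(self, section_factory):
        L = np.array([0, 0, 0, 5, 5])
        R = np.array([0, 0, 0, 5, 5])
        s = lr_section(section_factory, L, R, spacing=1000.0)  # no neighbours in radius
        raw = st.spot_intensity(s, PAIR, neighbor_radius_um=150.0)
        np.testing.assert_allclose(raw, 0.0)  # isolated spots use neighbour mean 0

    def test_missing_gene_raises(self, section_factory):
        s = lr_section(section_factory, np.ones(4), np.ones(4))
        with pytest.raises(GeneMissingError):
            st.spot_intensity(s, st.LRPair("Nope", "Rec"), 150.0)


class TestPermutationZscore:
    def test_deterministic_given_seed(self, section_factory):
        rng = np.random.default_rng(0)
        s = lr_section(section_factory, rng.integers(0, 30, 50), rng.integers(0, 30, 50))
        a = st.permutation_zscore(s, PAIR, 150.0, n_perm=100, seed=42)
        b = st.permutation_zscore(s, PAIR, 150.0, n_perm=100, seed=42)
        np.testing.assert_array_equal(a.zscores, b.zscores)

    def test_constant_expression_flagged_zero(self, section_factory):
        s = lr_section(section_factory, np.full(20, 9), np.full(20, 9))
        pz = st.permutation_zscore(s, PAIR, 150.0, n_perm=100, seed=0)
        assert pz.degenerate.all()
        np.testing.assert_array_equal(pz.zscores, 0.0)

    def test_too_few_permutations_rejected(self, section_factory):
        s = lr_section(section_factory, np.ones(10), np.ones(10))
        with pytest.raises(ValueError, match="n_perm"):
            st.permutation_zscore(s, PAIR, 150.0, n_perm=50)

    def test_planted_hotspot_scores_high(self, default_dataset):
        """Mean z-score inside a planted patch clears the 1.96 threshold."""
        mds, gt = default_dataset
        s = mds.sections_by_timepoint["d3"][0]
        pz = st.permutation_zscore(s, st.LRPair("Lg1", "Rc1"), 150.0, n_perm=200, seed=11)
        hot = set(gt.hotspots[("d3", "LG1_RC1", s.section_id)])
        mask = np.array([sid in hot for sid in s.spot_ids])
        assert pz.zscores[mask].mean() > 1.96
        assert pz.zscores[mask].mean() > pz.zscores[~mask].mean()


class TestDiscretizeAndDensity:
    def test_binary_extremes_and_arithmetic(self):
        assert st.discretize_and_density(np.full(20, 1.0)).density == 0.0
        assert st.discretize_and_density(np.full(20, 2.5)).density == 1.0
        z = np.array([2.0] * 10 + [0.0] * 10)
        r = st.discretize_and_density(z)
        assert r.density == 0.5
        assert r.zt_total == 10

    def test_total_conservation_exact(self):
        rng = np.random.default_rng(8)
        z = rng.normal(0, 2, 501)
        r = st.discretize_and_density(z)
        assert r.zt_total == r.zt.sum()
        assert r.density == r.zt_total / r.n_spots

    def test_density_monotone_in_threshold(self):
        rng = np.random.default_rng(9)
        z = rng.normal(0, 2, 300)
        densities = [
            st.discretize_and_density(z, z_threshold=t).density
            for t in np.linspace(3.0, -3.0, 25)
        ]
        assert all(b >= a for a, b in zip(densities, densities[1:]))

    def test_binned_mode_signed_integers(self):
        z = np.array([-4.2, -2.0, 0.5, 2.0, 4.2])
        r = st.discretize_and_density(z, mode="binned")
        np.testing.assert_array_equal(r.zt, [-2, -1, 0, 1, 2])

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            st.discretize_and_density(np.array([]))


class TestCompareDensities:
    def test_identical_groups_convention(self):
        cmp = st.compare_densities({"a": [0.2] * 5, "b": [0.2] * 5})
        assert cmp.h_statistic == 0.0 and cmp.p_value == 1.0

    def test_matches_textbook_formula_with_ties(self):
        groups = {"a": [0.1, 0.2, 0.2, 0.4], "b": [0.2, 0.5, 0.6], "c": [0.7, 0.7, 0.9]}
        cmp = st.compare_densities(groups)
        h_ref = kruskal_wallis_reference([list(v) for v in groups.values()])
        assert cmp.h_statistic == pytest.approx(h_ref, abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            st.compare_densities({"a": [1.0], "b": []})

    def test_permutation_p_close_to_asymptotic_at_moderate_n(self):
        rng = np.random.default_rng(12)
        groups = {"a": rng.normal(0, 1, 30), "b": rng.normal(0.8, 1, 30)}
        asy = st.compare_densities(groups, method="asymptotic")
        per = st.compare_densities(groups, method="permutation", n_perm=4999, seed=0)
        assert per.h_statistic == asy.h_statistic
        assert abs(per.p_value - asy.p_value) < 0.02

    def test_power_at_two_sd_shift(self):
        """Groups shifted by 2 SD at n=50 are detected essentially always."""
        rng = np.random.default_rng(13)
        hits = 0
        reps = 100
        for _ in range(reps):
            groups = {"a": rng.normal(0, 1, 50), "b": rng.normal(2, 1, 50)}
            hits += st.compare_densities(groups).p_value < 0.05
        assert hits / reps >= 0.95


class TestCommunicationTable:
    def test_pools_sections_and_skips_missing_genes(self, default_dataset):
        mds, gt = default_dataset
        pairs = [st.LRPair("Lg1", "Rc1"), st.LRPair("Absent", "Rc1")]
        with pytest.warns(UserWarning, match="ABSENT"):
            table, results = communication_table(
                mds, ("VL", "A", "B", "C"), pairs, "chain", 150.0, n_perm=100, seed=0
            )
        assert set(table["pair"]) == {"LG1_RC1"}
        # pooled N = 3 sections x 400 spots per timepoint
        assert set(table["n_spots"]) == {1200}

    def test_deterministic_given_seed(self, default_dataset):
        mds, _ = default_dataset
        pairs = [st.LRPair("Lg2", "Rc2")]
        t1, _ = communication_table(mds, ("B",), pairs, "c", 150.0, n_perm=100, seed=5)
        t2, _ = communication_table(mds, ("B",), pairs, "c", 150.0, n_perm=100, seed=5)
        assert t1.equals(t2)
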