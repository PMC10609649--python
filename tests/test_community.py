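import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import fraclift as fl
from fraclift.io import ConfigError

from conftest import random_table
from oracles import (
    anosim_oracle,
    bray_curtis_oracle,
    permanova_f_oracle,
)


def dm_from_points(points):
    d = squareform(pdist(np.asarray(points, dtype=float)))
    d = d / d.max()
    return fl.DistanceMatrix(tuple(range(len(points))), d)


class TestDistanceMatrix:
    def test_validation(self):
        with pytest.raises(ConfigError):
            fl.DistanceMatrix((0, 1), np.array([[0.0, 1.0], [0.5, 0.0]]))
        with pytest.raises(ConfigError):
            fl.DistanceMatrix((0, 1), np.array([[0.3, 1.0], [1.0, 0.0]]))
        with pytest.raises(ConfigError):
            fl.DistanceMatrix((0,), np.zeros((2, 2)))


class TestBrayCurtis:
    def test_identical_samples_distance_zero(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [0.0, 0.0]])
        assert fl.bray_curtis(x).data[0, 1] == 0.0

    def test_disjoint_supports_distance_one(self):
        x = np.array([[1.0, 0.0], [0.0, 2.0]])
        assert fl.bray_curtis(x).data[0, 1] == 1.0

    def test_worked_three_otu_pair(self):
        x = np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        assert fl.bray_curtis(x).data[0, 1] == pytest.approx(0.5)

    def test_matches_loop_oracle_and_scipy(self):
        rng = np.random.default_rng(0)
        x = rng.random((30, 8))
        d = fl.bray_curtis(x).data
        ref = squareform(pdist(x.T, metric="braycurtis"))
        np.testing.assert_allclose(d, ref, atol=1e-12)
        assert d[2, 5] == pytest.approx(bray_curtis_oracle(x[:, 2], x[:, 5]))

    def test_zero_sample_pair_rejected(self):
        x = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 2.0]])
        with pytest.raises(ConfigError, match="all-zero"):
            fl.bray_curtis(x)

    def test_depth_invariance_after_normalization(self):
        table = random_table(np.random.default_rng(1), 30, 6)
        deeper = fl.OtuTable(table.counts * 13)
        d1 = fl.bray_curtis(fl.relative_abundance(table)).data
        d2 = fl.bray_curtis(fl.relative_abundance(deeper)).data
        np.testing.assert_allclose(d1, d2, atol=1e-12)

    def test_dataframe_columns_become_ids(self, sim_default):
        table, _, _, _ = sim_default
        d = fl.bray_curtis(fl.hellinger_transform(table))
        assert list(d.ids) == table.sample_ids
        assert (d.data <= 1.0 + 1e-12).all()


class TestNmds:
    def test_planar_configuration_recovered_with_near_zero_stress(self):
        rng = np.random.default_rng(0)
        points = rng.normal(size=(9, 2))
        res = fl.nmds(dm_from_points(points), seed=1)
        assert res.stress < 0.01
        assert res.converged
        assert res.reliable
        np.testing.assert_allclose(
            res.coordinates.mean(axis=0), 0.0, atol=1e-8
        )

    def test_seeded_runs_are_identical(self):
        rng = np.random.default_rng(2)
        points = rng.normal(size=(10, 4))
        d = dm_from_points(points)
        r1 = fl.nmds(d, seed=7)
        r2 = fl.nmds(d, seed=7)
        assert r1.stress == r2.stress
        pd.testing.assert_frame_equal(r1.coordinates, r2.coordinates)

    def test_stress_invariant_to_input_rotation(self):
        """Rotating/reflecting the generating configuration leaves the
        dissimilarities, hence the stress, unchanged."""
        rng = np.random.default_rng(3)
        points = rng.normal(size=(8, 2))
        theta = 1.1
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        r1 = fl.nmds(dm_from_points(points), seed=5)
        r2 = fl.nmds(dm_from_points(points @ rot.T), seed=5)
        assert r1.stress == pytest.approx(r2.stress, abs=1e-9)

    def test_matches_reference_implementation_on_random_matrices(self):
        """Best stress within 0.02 of scikit-learn's nonmetric SMACOF."""
        from oracles import nmds_stress_reference

        rng = np.random.default_rng(4)
        for trial in range(3):
            x = rng.random((15, 15))
            d = (x + x.T) / 2
            np.fill_diagonal(d, 0.0)
            dm = fl.DistanceMatrix(tuple(range(15)), d)
            ours = fl.nmds(dm, n_restarts=8, seed=trial).stress
            ref = nmds_stress_reference(d, seed=trial)
            assert abs(ours - ref) < 0.02

    def test_cluster_structure_preserved(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 0.15, size=(6, 12))
        b = rng.normal(2, 0.15, size=(6, 12))
        x = np.abs(np.vstack([a, b]))
        d = fl.bray_curtis(x.T)
        res = fl.nmds(d, seed=9)
        coords = res.coordinates.to_numpy()
        within = pdist(coords[:6]).tolist() + pdist(coords[6:]).tolist()
        between = [
            np.linalg.norm(coords[i] - coords[j])
            for i in range(6)
            for j in range(6, 12)
        ]
        frac = np.mean([w < min(between) for w in within])
        assert frac >= 0.9

    def test_high_stress_warns(self):
        rng = np.random.default_rng(6)
        x = rng.random((40, 40))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0.0)
        dm = fl.DistanceMatrix(tuple(range(40)), d)
        with pytest.warns(UserWarning, match="stress"):
            res = fl.nmds(dm, n_restarts=2, max_iter=50, seed=0)
        assert not res.reliable

    def test_two_cluster_collapse_warns_of_degeneracy(self):
        """Two tight clusters admit a near-zero-stress collapse onto two
        points; the classic degenerate NMDS solution is flagged."""
        rng = np.random.default_rng(7)
        a = np.abs(rng.normal(1.0, 0.01, size=(6, 10)))
        b = np.abs(rng.normal(1.0, 0.01, size=(6, 10)) + np.array([3.0] * 10))
        d = fl.bray_curtis(np.vstack([a, b]).T)
        with pytest.warns(UserWarning, match="degenerate"):
            res = fl.nmds(d, seed=2)
        assert res.stress < 1e-3

    def test_too_few_samples_rejected(self):
        dm = fl.DistanceMatrix((0, 1, 2), 1 - np.eye(3))
        with pytest.raises(ConfigError):
            fl.nmds(dm, seed=0)


class TestPermanova:
    def test_statistic_matches_gower_trace_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.random((12, 20))
        d = fl.bray_curtis(x.T)
        groups = np.repeat(["a", "b", "c"], 4)
        res = fl.permanova(d, groups, n_permutations=99, seed=1)
        assert res.statistic == pytest.approx(
            permanova_f_oracle(d.data, groups), abs=1e-10
        )

    def test_statistic_matches_skbio(self):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(1)
        x = rng.random((10, 15))
        d = fl.bray_curtis(x.T)
        groups = ["a"] * 5 + ["b"] * 5
        res = fl.permanova(d, groups, n_permutations=99, seed=1)
        sk = skbio_dist.permanova(
            skbio_dist.DistanceMatrix(d.data, [str(i) for i in d.ids]),
            grouping=groups,
            permutations=99,
        )
        assert res.statistic == pytest.approx(float(sk["test statistic"]), abs=1e-10)

    def test_r2_equals_univariate_anova_ss_ratio(self):
        """On Euclidean distances of one variable, R^2 is the classical
        SS_between / SS_total."""
        rng = np.random.default_rng(2)
        values = np.r_[rng.normal(0, 1, 6), rng.normal(2, 1, 6)]
        groups = np.repeat(["a", "b"], 6)
        d = squareform(pdist(values[:, None]))
        res = fl.permanova(
            fl.DistanceMatrix(tuple(range(12)), d), groups, 99, seed=3
        )
        grand = values.mean()
        ss_total = ((values - grand) ** 2).sum()
        ss_between = sum(
            6 * (values[groups == g].mean() - grand) ** 2 for g in "ab"
        )
        assert res.effect == pytest.approx(ss_between / ss_total, abs=1e-10)

    def test_maximal_separation_floors_p(self):
        # two groups of identical duplicated samples: within-group
        # variation is zero, so only a permutation recreating the exact
        # partition (2 in C(16,8) chance) could match the observed
        # extreme ordering, and p attains its floor 1/(n_perm + 1)
        x = np.vstack([np.tile([1.0, 0.0], (8, 1)), np.tile([0.0, 1.0], (8, 1))])
        d = fl.bray_curtis(x.T)
        groups = ["a"] * 8 + ["b"] * 8
        with pytest.warns(UserWarning, match="singular"):
            res = fl.permanova(d, groups, n_permutations=199, seed=4)
        assert res.p == pytest.approx(1 / 200)

    def test_seeded_p_values_reproduce_bit_exactly(self):
        rng = np.random.default_rng(5)
        x = rng.random((10, 12))
        d = fl.bray_curtis(x.T)
        groups = ["a"] * 5 + ["b"] * 5
        r1 = fl.permanova(d, groups, n_permutations=499, seed=6)
        r2 = fl.permanova(d, groups, n_permutations=499, seed=6)
        assert r1 == r2

    def test_power_increases_with_effect_size(self):
        """Rejection frequency grows along a 3-point effect grid."""
        rng = np.random.default_rng(7)
        power = []
        for shift in (0.0, 0.6, 1.5):
            hits = 0
            for _ in range(60):
                a = np.abs(rng.normal(1.0, 0.4, size=(6, 10)))
                b = np.abs(rng.normal(1.0 + shift, 0.4, size=(6, 10)))
                d = fl.bray_curtis(np.vstack([a, b]).T)
                res = fl.permanova(
                    d, ["a"] * 6 + ["b"] * 6, n_permutations=99,
                    seed=int(rng.integers(2**31)),
                )
                hits += res.p <= 0.05
            power.append(hits / 60)
        assert power[0] < power[2]
        assert power[1] <= power[2]
        assert power[2] > 0.9

    def test_single_sample_group_warns(self):
        d = fl.DistanceMatrix(tuple(range(4)), 1 - np.eye(4))
        with pytest.warns(UserWarning, match="single sample"):
            fl.permanova(d, ["a", "a", "a", "b"], n_permutations=9, seed=0)


class TestAnosim:
    def test_matches_loop_oracle_with_ties(self):
        # duplicate coordinates create tied dissimilarities
        x = np.array([[1, 0], [1, 0], [0, 1], [0, 1], [1, 1], [2, 1]], dtype=float)
        d = fl.bray_curtis(x.T)
        groups = ["a", "a", "b", "b", "a", "b"]
        res = fl.anosim(d, groups, n_permutations=99, seed=1)
        assert res.statistic == pytest.approx(
            anosim_oracle(d.data.tolist(), groups), abs=1e-12
        )

    def test_matches_skbio(self):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(2)
        x = rng.random((10, 15))
        d = fl.bray_curtis(x.T)
        groups = ["a"] * 5 + ["b"] * 5
        res = fl.anosim(d, groups, n_permutations=99, seed=3)
        sk = skbio_dist.anosim(
            skbio_dist.DistanceMatrix(d.data, [str(i) for i in d.ids]),
            grouping=groups,
            permutations=99,
        )
        assert res.statistic == pytest.approx(float(sk["test statistic"]), abs=1e-10)

    def test_perfect_separation_gives_r_one(self):
        a = np.tile([1.0, 0.0, 0.0], (4, 1)) + np.arange(4)[:, None] * 1e-3
        b = np.tile([0.0, 1.0, 5.0], (4, 1)) + np.arange(4)[:, None] * 1e-3
        d = fl.bray_curtis(np.vstack([a, b]).T)
        res = fl.anosim(d, ["a"] * 4 + ["b"] * 4, n_permutations=99, seed=4)
        assert res.statistic == pytest.approx(1.0)

    def test_random_labels_give_r_near_zero(self):
        rng = np.random.default_rng(5)
        rs = []
        for _ in range(30):
            x = rng.random((12, 20))
            d = fl.bray_curtis(x.T)
            groups = rng.permutation(["a"] * 6 + ["b"] * 6)
            rs.append(fl.anosim(d, groups, n_permutations=9, seed=0).statistic)
        assert abs(np.mean(rs)) < 0.1
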