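"""Feature space, similarity statistics, convergence and geometry."""
import numpy as np
import pandas as pd
import pytest

import barrelnet as bn
from barrelnet.netspace import AdjacencyMatrix, ElectrodeGeometry


def _adj(bits, whisker="D4", m=0, session="control", subject=0):
    A = np.asarray(bits, dtype=np.uint8)
    np.fill_diagonal(A, 0)
    return AdjacencyMatrix(matrix=A, whisker=whisker, dataset_index=m,
                           session=session, subject=subject)


def _random_adjs(rng, n=5, count=8, whiskers=("D4", "D5")):
    out = []
    for m in range(count):
        for w in whiskers:
            A = (rng.random((n, n)) < 0.3).astype(np.uint8)
            np.fill_diagonal(A, 0)
            out.append(_adj(A, whisker=w, m=m))
    return out


class TestBuildFeatureSpace:
    def test_identical_networks_are_degenerate(self):
        A = [[0, 1], [0, 0]]
        space = bn.build_feature_space([_adj(A, m=k) for k in range(4)], p=2)
        assert space.degenerate
        assert np.allclose(space.projections, 0.0)

    def test_projection_contraction(self, rng):
        adjs = _random_adjs(rng, n=6, count=10)
        space = bn.build_feature_space(adjs, p=2)
        full = space.vectors
        for a in range(0, len(adjs), 7):
            for b in range(a + 1, len(adjs), 5):
                d_p = np.linalg.norm(space.projections[a] - space.projections[b])
                d_full = np.linalg.norm(full[a] - full[b])
                assert d_p <= d_full + 1e-9

    def test_matches_brute_force_eigendecomposition(self):
        mats = [  # chosen so the two covariance eigenvalues are distinct
            [[0, 0], [0, 0]],
            [[0, 1], [0, 0]],
            [[0, 1], [1, 0]],
            [[0, 1], [0, 0]],
        ]
        adjs = [_adj(m, m=k) for k, m in enumerate(mats)]
        space = bn.build_feature_space(adjs, p=2)
        # independent oracle: eigendecomposition of the covariance of the
        # centred off-diagonal vectorisations
        V = np.stack([np.asarray(m, float)[~np.eye(2, dtype=bool)] for m in mats])
        C = V - V.mean(0)
        w, vecs = np.linalg.eigh(C.T @ C / (len(V) - 1))
        order = np.argsort(w)[::-1]
        proj = C @ vecs[:, order[:2]]
        for k in range(2):  # PCA axes defined up to sign
            got = space.projections[:, k]
            assert np.allclose(got, proj[:, k]) or np.allclose(got, -proj[:, k])

    def test_too_few_networks_rejected(self):
        with pytest.raises(ValueError):
            bn.build_feature_space([_adj([[0, 1], [0, 0]])], p=2)

    def test_identical_adjacencies_project_identically(self, rng):
        adjs = _random_adjs(rng, n=4, count=6)
        adjs[3] = _adj(adjs[0].matrix.copy(), whisker="D5", m=99)
        space = bn.build_feature_space(adjs, p=2)
        assert np.allclose(space.projections[3], space.projections[0])


class TestDistances:
    def test_pythagorean_distance(self):
        assert bn.network_distance([0.0, 0.0], [3.0, 4.0]) == 5.0
        assert bn.network_distance([1.0, 1.0], [1.0, 1.0]) == 0.0

    def test_symmetry_and_dimension_check(self, rng):
        a, b = rng.random(2), rng.random(2)
        assert bn.network_distance(a, b) == bn.network_distance(b, a)
        with pytest.raises(ValueError, match="dimension"):
            bn.network_distance([1.0], [1.0, 2.0])

    def test_average_pair_distance_literal_factor(self):
        # all cross-pair distances equal d -> (2/M^2) * M^2 * d = 2d
        adjs = []
        for m in range(3):
            adjs.append(_adj([[0, 0], [0, 0]], whisker="D4", m=m))
            adjs.append(_adj([[0, 1], [1, 0]], whisker="D5", m=m))
        space = bn.build_feature_space(adjs, p=2)
        d = bn.network_distance(space.projections[0], space.projections[1])
        dbar = bn.average_pair_distance(space, "D4", "D5")
        assert dbar == pytest.approx(2 * d)
        strict = bn.average_pair_distance(space, "D4", "D5", strict_mean=True)
        assert strict == pytest.approx(d)

    def test_identical_clusters_zero_distance(self):
        adjs = [_adj([[0, 1], [0, 0]], whisker=w, m=m) for w in ("D4", "D5") for m in range(2)]
        adjs += [_adj([[0, 0], [1, 0]], whisker="D6", m=m) for m in range(2)]
        space = bn.build_feature_space(adjs, p=2)
        assert bn.average_pair_distance(space, "D4", "D5") == pytest.approx(0.0)

    def test_homogeneity_under_projection_scaling(self, rng):
        adjs = _random_adjs(rng, n=5, count=6)
        space = bn.build_feature_space(adjs, p=2)
        dbar = bn.average_pair_distance(space, "D4", "D5")
        space.projections = space.projections * 3.0
        assert bn.average_pair_distance(space, "D4", "D5") == pytest.approx(3 * dbar)


class TestSimilarityReport:
    def test_extremes_and_formula(self, rng):
        adjs = _random_adjs(rng, n=6, count=8, whiskers=("D4", "D5", "D6"))
        space = bn.build_feature_space(adjs, p=2)
        rep = bn.similarity_report(space)
        t = rep.table
        assert ((t["similarity"] >= 0) & (t["similarity"] <= 1)).all()
        worst = t.loc[t["mean_distance"].idxmax()]
        assert worst["similarity"] == 0.0
        expect = 1.0 - t["mean_distance"] / t["mean_distance"].max()
        assert np.allclose(t["similarity"], expect)

    def test_sample_means_reproduce_pair_similarity(self, rng):
        adjs = _random_adjs(rng, n=6, count=10, whiskers=("D4", "D5", "D6"))
        space = bn.build_feature_space(adjs, p=2)
        rep = bn.similarity_report(space)
        for _, row in rep.table.iterrows():
            samp = rep.samples[(row["session"], row["w1"], row["w2"])]
            assert np.mean(samp) == pytest.approx(row["similarity"])

    def test_degenerate_all_identical(self):
        adjs = [_adj([[0, 1], [0, 0]], whisker=w, m=m)
                for w in ("D4", "D5") for m in range(3)]
        space = bn.build_feature_space(adjs, p=2)
        rep = bn.similarity_report(space)
        assert rep.degenerate
        assert (rep.table["similarity"] == 1.0).all()


class TestConvergence:
    def test_zero_and_saturated_matrices(self):
        zero = _adj(np.zeros((4, 4), int))
        full = _adj(np.ones((4, 4), int))
        out = bn.presynaptic_convergence([zero, full])
        assert out.per_network["value"].tolist() == [0.0, 1.0]

    def test_one_parent_each_normalised(self):
        n = 11
        A = np.zeros((n, n), dtype=np.uint8)
        for j in range(n):
            A[(j + 1) % n, j] = 1  # every neuron exactly 1 parent
        out = bn.presynaptic_convergence([_adj(A)])
        assert out.per_network["value"].iloc[0] == pytest.approx(0.1)
        raw = bn.presynaptic_convergence([_adj(A)], normalize=False)
        assert raw.per_network["value"].iloc[0] == pytest.approx(1.0)


class TestConnectionProbability:
    def test_all_ones_and_all_zeros(self):
        sites = np.array([0, 1, 4, 5])
        ones = _adj(np.ones((4, 4), int))
        zeros = _adj(np.zeros((4, 4), int))
        t1 = bn.connection_probability_by_separation([ones], sites)
        assert (t1["probability"] == 1.0).all()
        t0 = bn.connection_probability_by_separation([zeros], sites)
        assert (t0["probability"] == 0.0).all()

    def test_fractional_probability_at_one_separation(self):
        sites = np.array([0, 1])  # same shank, 100 um apart vertically
        A = np.zeros((2, 2), dtype=np.uint8)
        A[0, 1] = 1
        connected = _adj(A)
        empty = _adj(np.zeros((2, 2), int))
        tab = bn.connection_probability_by_separation([connected] * 3 + [empty] * 7, sites)
        row = tab.iloc[0]
        assert (row["horizontal_um"], row["vertical_um"]) == (0.0, 100.0)
        assert row["probability"] == pytest.approx(0.3)

    def test_unmapped_unit_rejected(self):
        with pytest.raises(ValueError, match="without a site"):
            bn.connection_probability_by_separation(
                [_adj(np.zeros((3, 3), int))], np.array([0, 1])
            )

    def test_geometry_separation_pitches(self):
        g = ElectrodeGeometry()
        assert g.separation(0, 1) == (0.0, 100.0)
        assert g.separation(0, 4) == (200.0, 0.0)
        assert g.separation(2, 7) == (200.0, 100.0)


class TestCompareSessions:
    def test_identical_samples_flagged_p_one(self):
        r = bn.compare_sessions([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert (r.t, r.p, r.flagged) == (0.0, 1.0, True)

    def test_separated_samples_significant(self):
        a = np.zeros(4) + 1e-6 * np.arange(4)
        b = np.ones(4) + 1e-6 * np.arange(4)
        r = bn.compare_sessions(a, b)
        assert r.p < 0.05

    def test_swapping_samples_flips_t_keeps_p(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 10)
        r1, r2 = bn.compare_sessions(a, b), bn.compare_sessions(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_matches_closed_form_pooled_t(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 6.0])
        r = bn.compare_sessions(a, b)
        sp2 = (a.var(ddof=1) + b.var(ddof=1)) / 2
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 3))
        assert r.t == pytest.approx(t)
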