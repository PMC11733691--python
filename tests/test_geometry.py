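"""State-space analyses: PCA, participation ratio, angles, Mahalanobis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from pdpsim.geometry import (RatePatternSet, edge_angles, mahalanobis,
                             mahalanobis_subsampled, most_similar_mixtures,
                             participation_ratio, pca)


class TestParticipationRatio:
    @pytest.mark.parametrize("lam,expected", [
        ([1, 1, 1, 1, 0], 4.0),
        ([4, 0, 0], 1.0),
        ([2, 1, 1], 16 / 6),
    ])
    def test_known_spectra(self, lam, expected):
        assert participation_ratio(lam) == pytest.approx(expected)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            participation_ratio([0.0, 0.0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            participation_ratio([1.0, -0.5])


@settings(derandomize=True, max_examples=50, deadline=None)
@given(hnp.arrays(np.float64, st.integers(1, 12),
                  elements=st.floats(0.0, 1e6)))
def test_participation_ratio_bounded_by_nonzero_count(lam):
    """For any non-negative spectrum, 1 <= PR <= number of nonzero modes."""
    if lam.sum() == 0:
        return
    pr = participation_ratio(lam)
    assert 1.0 - 1e-9 <= pr <= np.count_nonzero(lam) + 1e-9


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.integers(0, 2 ** 31 - 1), st.integers(3, 30))
def test_edge_angles_within_range(seed, n):
    """Angles always fall in [0, pi] and every neighbor pair contributes."""
    rng = np.random.default_rng(seed)
    proj = rng.normal(size=(n, 4))
    ang = edge_angles(proj, 0, np.arange(1, n))
    assert np.all((ang >= 0) & (ang <= np.pi + 1e-12))


class TestPCA:
    def test_collinear_patterns_have_rank_one_spectrum(self):
        t = np.linspace(0, 1, 20)[:, None]
        x = t @ np.array([[1.0, 2.0, -1.0]])
        s = pca(x)
        assert s.eigenvalues[1] == pytest.approx(0.0, abs=1e-12)
        assert s.participation_ratio == pytest.approx(1.0)

    def test_variance_conserved(self):
        x = np.random.default_rng(0).random((30, 8))
        s = pca(x)
        total = np.var(x, axis=0, ddof=1).sum()
        assert s.eigenvalues.sum() == pytest.approx(total, rel=1e-9)

    def test_pr_matches_bruteforce_covariance_eigenvalues(self):
        x = np.random.default_rng(1).random((40, 12))
        s = pca(x)
        lam = np.linalg.eigvalsh(np.cov(x, rowvar=False))
        assert s.participation_ratio == pytest.approx(
            participation_ratio(lam), rel=1e-9)

    def test_too_few_patterns_rejected(self):
        with pytest.raises(ValueError):
            pca(np.ones((1, 5)))

    def test_component_count_validated(self):
        with pytest.raises(ValueError):
            pca(np.random.default_rng(0).random((4, 3)), n_components=10)


class TestEdgeAngles:
    def test_right_angle(self):
        proj = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        assert edge_angles(proj, 0, [1, 2])[0] == pytest.approx(np.pi / 2)

    def test_identical_neighbors_zero_angle(self):
        proj = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
        assert edge_angles(proj, 0, [1, 2])[0] == pytest.approx(0.0, abs=1e-6)

    def test_zero_length_edges_excluded(self):
        proj = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        assert len(edge_angles(proj, 0, [1, 2, 3])) == 1  # only (2,3) pair

    def test_pair_count(self):
        proj = np.random.default_rng(0).random((9, 5))
        assert len(edge_angles(proj, 0, np.arange(1, 8))) == 21  # C(7,2)


class TestMahalanobis:
    def test_distance_to_own_mean_is_zero(self):
        q = np.random.default_rng(0).multivariate_normal([1, 2], np.eye(2), 100)
        assert mahalanobis(q.mean(axis=0), q) == pytest.approx(0.0, abs=1e-9)

    def test_identity_covariance_reduces_to_euclidean(self):
        rng = np.random.default_rng(1)
        q = rng.multivariate_normal([0, 0], np.eye(2), 20000)
        d = mahalanobis(q.mean(axis=0) + np.array([3.0, 0.0]), q)
        assert d == pytest.approx(3.0, rel=0.05)

    def test_anisotropic_covariance_scales_axes(self):
        rng = np.random.default_rng(2)
        q = rng.multivariate_normal([0, 0], np.diag([9.0, 1.0]), 20000)
        d = mahalanobis(q.mean(axis=0) + np.array([3.0, 0.0]), q)
        assert d == pytest.approx(1.0, rel=0.05)

    def test_singular_covariance_raises_with_rank(self):
        q = np.ones((10, 3))
        q[:, 0] = np.arange(10)
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            mahalanobis(np.zeros(3), q)

    def test_subsampled_driver_averages_draws(self):
        rng = np.random.default_rng(3)
        q = rng.normal(0, 1, (500, 40))
        v = np.zeros(40)
        d = mahalanobis_subsampled(v, q, np.arange(40), 5, n_neurons=10,
                                   n_draws=8)
        assert d > 0


class TestSubspaceGeometry:
    def test_ob_projection_recovers_square(self, mini_subspace):
        """First two PCs of the OB patterns reproduce the subspace square:
        the four pure odors are mutually the most distant points."""
        _, sch = mini_subspace
        ob = RatePatternSet.from_schedule_ob(sch)
        s = pca(ob)
        xy = s.projections[:, :2]
        corners = {(0, 0), (0, 10), (10, 0), (10, 10)}
        c_idx = {}
        for k, ep in enumerate(sch.epochs):
            key = (ep.label["row"], ep.label["col"])
            if key in corners:
                c_idx.setdefault(key, k)  # pure odors repeat across trajectories
        c_idx = list(c_idx.values())
        # corner-to-corner separations exceed the typical pattern distance
        d = np.linalg.norm(xy[:, None] - xy[None, :], axis=2)
        corner_d = [d[i][c_idx].max() for i in c_idx]
        assert min(corner_d) > np.median(d)
        # the four vertices are mutually distinct points in PC space
        for i in c_idx:
            others = [j for j in c_idx if j != i]
            assert d[i][others].min() > 0

    def test_dimensionality_ordering_across_variants(self, mini_subspace_runs):
        pr = {}
        for variant, res in mini_subspace_runs.items():
            pats = RatePatternSet.from_simresult(res, window=1.0)
            pr[variant] = pca(pats).participation_ratio
        assert pr["rand"] > pr["TunedEI"] > pr["ScaledI"]

    def test_edge_angles_concentrate_near_one_radian(
            self, mini_subspace_runs, mini_subspace):
        """In a random balanced network, angles between the edges linking a
        pure-odor response to its most similar mixture responses cluster
        around ~1 rad (high-dimensional, nearly isotropic local geometry).

        The further contraction of these angles near learned odors in Tuned
        networks is a full-scale effect that quarter-scale fixtures cannot
        resolve above seed noise; it is not asserted here.
        """
        _, sch = mini_subspace
        res = mini_subspace_runs["rand"]
        pats = RatePatternSet.from_simresult(res, window=1.0)
        ob = RatePatternSet.from_schedule_ob(sch)
        s = pca(pats)
        n_pc = min(100, s.projections.shape[1])
        corners = {(0, 0), (0, 10), (10, 0), (10, 10)}
        angles = []
        for traj in (0, 1):
            tr_eps = [k for k, ep in enumerate(sch.epochs)
                      if ep.label["trajectory"] == traj]
            for k in tr_eps:
                if (sch.epochs[k].label["row"],
                        sch.epochs[k].label["col"]) not in corners:
                    continue
                neigh = most_similar_mixtures(
                    ob, ob.rates[k], 7,
                    exclude=[j for j in range(len(sch.epochs))
                             if j not in tr_eps or j == k])
                angles.extend(edge_angles(s.projections[:, :n_pc], k, neigh))
        angles = np.asarray(angles)
        assert len(angles) == 2 * 4 * 21  # 21 pairs x 4 odors x 2 trajectories
        assert 0.8 < angles.mean() < 1.3
        assert angles.std() < 0.35

    def test_mahalanobis_asymmetry_in_tuned_networks(
            self, mini_subspace_runs, mini_subspace, mini_net):
        """E/I assemblies increase d_M from learned-odor patterns to
        novel-odor classes more than in the reverse direction."""
        from pdpsim.assemblies import select_assembly_e
        from pdpsim.odors import pattern_correlation

        _, sch = mini_subspace
        ob = RatePatternSet.from_schedule_ob(sch)
        corners = {(0, 0): 0, (0, 10): 1, (10, 0): 2, (10, 10): 3}
        pure_eps = {}
        for k, ep in enumerate(sch.epochs):
            key = (ep.label["row"], ep.label["col"])
            if key in corners:
                pure_eps.setdefault(corners[key], k)
        cors = np.array([[pattern_correlation(ob.rates[pure_eps[c]], r)
                          for r in ob.rates] for c in range(4)])
        pures, _ = mini_subspace
        pools = [select_assembly_e(mini_net, p, n_members=25, seed=11)
                 for p in pures]
        pool = np.unique(np.concatenate(pools))

        def mean_dm(pats, vec_class, ref_class):
            vecs = np.nonzero(cors[vec_class] > 0.6)[0]
            refs = np.nonzero(cors[ref_class] > 0.5)[0]
            return np.mean([
                mahalanobis_subsampled(pats.rates[v], pats.rates[refs], pool,
                                       13, n_neurons=12, n_draws=10)
                for v in vecs[:6]])

        out = {}
        for variant in ("rand", "TunedEI"):
            pats = RatePatternSet.from_simresult(
                mini_subspace_runs[variant], window=1.0)
            out[variant] = {
                "l2n": np.mean([mean_dm(pats, a, b)
                                for a in (0, 1) for b in (2, 3)]),
                "n2n": np.mean([mean_dm(pats, 2, 3), mean_dm(pats, 3, 2)]),
                "n2l": np.mean([mean_dm(pats, a, b)
                                for a in (2, 3) for b in (0, 1)]),
            }
        t = out["TunedEI"]
        assert t["l2n"] > 1.2 * t["n2n"]
        fwd_increase = t["l2n"] - out["rand"]["l2n"]
        rev_increase = t["n2l"] - out["rand"]["n2l"]
        assert fwd_increase > rev_increase
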