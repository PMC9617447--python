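"""nu heuristics (kneedle knee, MAD), OCSVM training, scoring."""

from __future__ import annotations

import numpy as np
import pytest

from igocsvm import iggraph, spkernel, synthdata
from igocsvm.occlass import (
    OneClassModel,
    SimilarityProfile,
    fit_model,
    kneedle_knee,
    knn_profile,
    mad_nu,
    qms2_select,
    support_vector_fraction,
    train_ocsvm,
    training_outlier_fraction,
)
from igocsvm.spkernel import GramMatrix

PLANTED = [0.1, 0.12, 0.15, 0.80, 0.82, 0.84, 0.85, 0.86, 0.88, 0.90]


class TestKnnProfile:
    def test_k_is_three_percent(self):
        gm = GramMatrix(np.eye(100) + 0.1, "normalized")
        assert knn_profile(gm).K == 3

    def test_k_at_least_one(self):
        gm = GramMatrix(np.eye(10), "normalized")
        assert knn_profile(gm).K == 1

    def test_all_ones_gram(self):
        gm = GramMatrix(np.ones((20, 20)), "normalized")
        np.testing.assert_allclose(knn_profile(gm).s, 1.0)

    def test_orthogonal_instance_profile_zero(self):
        values = np.ones((10, 10))
        values[0, :] = values[:, 0] = 0.0
        values[0, 0] = 1.0
        profile = knn_profile(GramMatrix(values, "normalized"))
        assert profile.s[0] == 0.0
        assert np.all(profile.s[1:] == 1.0)

    def test_too_small_errors(self):
        with pytest.raises(ValueError):
            knn_profile(GramMatrix(np.ones((1, 1)), "normalized"))


class TestKneedle:
    def test_linear_ramp_no_knee(self):
        assert kneedle_knee(np.linspace(0.0, 1.0, 50)) is None

    def test_constant_no_knee(self):
        assert kneedle_knee([0.5] * 20) is None

    def test_two_points_no_knee(self):
        assert kneedle_knee([0.1, 0.9]) is None

    def test_planted_outliers_found(self):
        knee = kneedle_knee(PLANTED)
        assert knee == 3  # the three low-similarity points fall below it

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            kneedle_knee([0.3, 0.1, 0.2])


class TestQms2:
    def test_planted_outliers_removed(self):
        profile = SimilarityProfile(np.array(PLANTED), K=1, N=10)
        sel = qms2_select(profile)
        assert sel.nu == 0.01
        assert sorted(sel.retained_indices) == list(range(3, 10))

    def test_no_knee_retains_all(self):
        profile = SimilarityProfile(np.linspace(0.1, 0.9, 20), K=1, N=20)
        sel = qms2_select(profile)
        assert len(sel.retained_indices) == 20
        assert sel.nu == 0.01

    def test_permutation_invariant(self):
        rng = np.random.default_rng(4)
        perm = rng.permutation(10)
        shuffled = np.array(PLANTED)[perm]
        sel = qms2_select(SimilarityProfile(shuffled, K=1, N=10))
        retained_values = sorted(shuffled[sel.retained_indices])
        assert retained_values == sorted(PLANTED[3:])

    def test_seeded_decoy_mixture_removed(self, template):
        rng = np.random.default_rng(12)
        config = synthdata.SimConfig(n_frames=190, jitter_sigma=0.3,
                                     spurious_rate=0.3, seed=21)
        frames = synthdata.simulate_trajectory(template, config)
        decoys = synthdata.make_decoys(template, 10, "type_swap",
                                       synthdata.SimConfig(1, 0.3, 0.3, 22))
        fps = [spkernel.fingerprint(iggraph.build_graph(f))
               for f in frames + decoys]
        profile = knn_profile(spkernel.gram(fps, "normalized"))
        sel = qms2_select(profile)
        discarded = set(range(200)) - set(sel.retained_indices.tolist())
        assert set(range(190, 200)) <= discarded


class TestMadNu:
    def test_zero_mad_degenerate(self):
        s = np.array([0.9] * 97 + [0.1] * 3)
        sel = mad_nu(SimilarityProfile(s, K=3, N=100))
        assert sel.nu == pytest.approx(0.03)
        assert len(sel.retained_indices) == 100

    def test_all_equal_clamped(self):
        sel = mad_nu(SimilarityProfile(np.full(50, 0.7), K=1, N=50))
        assert sel.nu == pytest.approx(1.0 / 50)

    def test_hand_example(self):
        s = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 100.0])
        sel = mad_nu(SimilarityProfile(s, K=1, N=6))
        assert sel.nu == pytest.approx(1.0 / 6.0)

    def test_brute_force_oracle_1000_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            s = rng.normal(size=n)
            nu = mad_nu(SimilarityProfile(s, K=1, N=n)).nu
            # oracle: explicit sorted-copy median and MAD
            srt = np.sort(s.copy())
            med = (srt[(n - 1) // 2] + srt[n // 2]) / 2.0
            dev = np.sort(np.abs(s - med))
            mad = (dev[(n - 1) // 2] + dev[n // 2]) / 2.0
            frac = sum(1 for x in s if abs(x - med) > 3 * mad) / n
            assert nu == pytest.approx(min(1.0, max(frac, 1.0 / n)))


class TestTrainOcsvm:
    def make_gram(self, n, seed):
        rng = np.random.default_rng(seed)
        x = np.abs(rng.normal(1.0, 0.25, size=(n, 25)))
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        return x @ x.T

    def test_alpha_constraints(self):
        K = self.make_gram(80, 0)
        alpha, rho = train_ocsvm(K, nu=0.1)
        assert alpha.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(alpha >= -1e-12)
        assert np.all(alpha <= 1.0 / (0.1 * 80) + 1e-9)

    def test_nu_property_sweep(self):
        for seed in range(20):
            K = self.make_gram(100, seed)
            for nu in (0.01, 0.05, 0.2):
                alpha, rho = train_ocsvm(K, nu)
                scores = K @ alpha - rho
                outlier_frac = np.mean(scores < -1e-7)
                sv_frac = np.mean(alpha > 0)
                assert outlier_frac <= nu + 1e-3
                assert sv_frac >= nu - 1e-3

    def test_identical_graphs_all_inliers(self):
        K = np.ones((8, 8))
        alpha, rho = train_ocsvm(K, nu=0.01)
        scores = K @ alpha - rho
        assert np.all(scores >= -1e-9)

    def test_invalid_nu(self):
        with pytest.raises(ValueError):
            train_ocsvm(np.eye(5), nu=0.0)
        with pytest.raises(ValueError):
            train_ocsvm(np.eye(5), nu=1.5)

    def test_non_psd_rejected(self):
        K = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError, match="jitter"):
            train_ocsvm(K, nu=0.5)

    def test_deterministic(self):
        K = self.make_gram(60, 3)
        a1, r1 = train_ocsvm(K, 0.05)
        a2, r2 = train_ocsvm(K, 0.05)
        np.testing.assert_array_equal(a1, a2)
        assert r1 == r2


class TestModel:
    def test_fit_and_nu_property(self, small_fps):
        for method in ("qms2", "mad", "nn"):
            model = fit_model(small_fps, method=method)
            assert training_outlier_fraction(model) <= model.nu + 1e-3
            assert support_vector_fraction(model) >= model.nu - 1e-3
            assert model.kernel_mode == ("nn" if method == "nn" else "normalized")

    def test_interior_inlier_and_empty_outlier(self, template, small_fps):
        model = fit_model(small_fps, method="mad")
        # a jittered template pose scores inlier; empty graph scores -rho < 0
        scores = [model.score_fingerprint(fp) for fp in small_fps]
        assert np.mean(np.array(scores) >= 0) > 0.5
        empty_score = model.score_fingerprint(spkernel.PathFingerprint())
        assert empty_score == pytest.approx(-model.rho)
        assert empty_score < 0

    def test_inlier_vs_type_swap_decoy(self, template, small_fps):
        model = fit_model(small_fps, method="qms2")
        inlier = synthdata.simulate_trajectory(
            template, synthdata.SimConfig(1, 0.3, 0.0, 555))[0]
        decoy = synthdata.make_decoys(template, 1, "type_swap",
                                      synthdata.SimConfig(1, 0.3, 0.0, 556))[0]
        s_in = model.score_fingerprint(spkernel.fingerprint(iggraph.build_graph(inlier)))
        s_out = model.score_fingerprint(spkernel.fingerprint(iggraph.build_graph(decoy)))
        assert s_in >= 0 > s_out

    def test_json_round_trip(self, small_fps):
        model = fit_model(small_fps[:30], method="mad")
        back = OneClassModel.from_json(model.to_json())
        for fp in small_fps[30:40]:
            assert back.score_fingerprint(fp) == \
                pytest.approx(model.score_fingerprint(fp), abs=1e-12)

    def test_deterministic_across_runs(self, small_fps):
        m1 = fit_model(small_fps, method="qms2")
        m2 = fit_model(small_fps, method="qms2")
        np.testing.assert_array_equal(m1.alpha, m2.alpha)
        assert m1.rho == m2.rho
        scores1 = [m1.score_fingerprint(fp) for fp in small_fps]
        scores2 = [m2.score_fingerprint(fp) for fp in small_fps]
        assert scores1 == scores2
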