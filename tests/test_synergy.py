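"""NMF synergy extraction: VAF, model selection, activation vectors."""

import numpy as np
import pytest

from myosynergy.recording import TrialWindow
from myosynergy.synergy import (compute_vaf, extract_synergies, nmf_decompose, pad_to_dim,
                                select_synergy_count, synergy_activation_vector)
from myosynergy.synthetic import generate_discrete_trials, matched_mean_cosine


def _rank_k_matrix(rng, n_ch=4, n_t=400, k=2):
    W = rng.uniform(0.1, 1.0, (n_ch, k))
    C = rng.uniform(0.0, 1.0, (k, n_t))
    return W, C, W @ C


class TestVaf:
    def test_exact_reconstruction_gives_one(self, rng):
        W, C, M = _rank_k_matrix(rng)
        assert compute_vaf(M, W, C) == pytest.approx(1.0, abs=1e-12)

    def test_zero_coefficients_give_zero(self, rng):
        W, C, M = _rank_k_matrix(rng)
        assert compute_vaf(M, W, np.zeros_like(C)) == 0.0

    def test_two_by_two_arithmetic(self):
        # M = I2, reconstruction keeps only the first diagonal entry:
        # residual SS = 1, total SS = 2 -> VAF = 0.5
        M = np.eye(2)
        W = np.array([[1.0], [0.0]])
        C = np.array([[1.0, 0.0]])
        assert compute_vaf(M, W, C) == pytest.approx(0.5)

    def test_rejects_all_zero_input(self):
        with pytest.raises(ValueError):
            compute_vaf(np.zeros((2, 3)), np.zeros((2, 1)), np.zeros((1, 3)))


class TestNmf:
    def test_exact_rank2_reaches_vaf(self, rng):
        _, _, M = _rank_k_matrix(rng, k=2)
        model = nmf_decompose(M, 2, seed=0, restarts=5)
        assert model.vaf >= 0.999

    def test_vaf_monotone_in_synergy_count(self, rng):
        M = rng.uniform(0.0, 1.0, (4, 300))
        vafs = [nmf_decompose(M, n, seed=3, restarts=4).vaf for n in (1, 2, 3, 4)]
        assert all(b >= a - 1e-9 for a, b in zip(vafs, vafs[1:]))

    def test_seeded_determinism(self, rng):
        _, _, M = _rank_k_matrix(rng, k=3)
        m1 = nmf_decompose(M, 2, seed=11, restarts=3)
        m2 = nmf_decompose(M, 2, seed=11, restarts=3)
        assert np.array_equal(m1.W, m2.W) and np.array_equal(m1.C, m2.C)

    def test_unit_norm_columns_with_scale_in_coefficients(self, rng):
        _, _, M = _rank_k_matrix(rng, k=2)
        model = nmf_decompose(M, 2, seed=0, restarts=3)
        assert np.allclose(np.linalg.norm(model.W, axis=0), 1.0)
        assert compute_vaf(M, model.W, model.C) == pytest.approx(model.vaf)

    def test_rejects_negative_input(self):
        with pytest.raises(ValueError):
            nmf_decompose(-np.ones((4, 10)), 2, seed=0)

    def test_matches_sklearn_reconstruction_quality(self, rng):
        """Independent cross-check: best-of-restarts multiplicative updates
        reach the reconstruction quality of sklearn's NMF solver."""
        sklearn = pytest.importorskip("sklearn.decomposition")
        _, _, M = _rank_k_matrix(rng, k=3, n_t=300)
        model = nmf_decompose(M, 3, seed=0, restarts=8, tol=1e-9, max_iter=3000)
        sk = sklearn.NMF(n_components=3, init="random", solver="mu", max_iter=2000,
                         random_state=0, tol=1e-9).fit(M.T)
        sk_err = np.linalg.norm(M.T - sk.transform(M.T) @ sk.components_)
        our_err = np.linalg.norm(M - model.reconstruction())
        assert our_err <= sk_err * 1.05 + 1e-9


class TestSelection:
    def test_exact_rank1_selects_one(self, rng):
        w = rng.uniform(0.1, 1, 4)[:, None]
        c = rng.uniform(0, 1, (1, 200))
        assert select_synergy_count(w @ c, seed=0, restarts=3) == 1

    def test_noiseless_three_synergy_limb_selects_three(self, noiseless_limbs, fast_pipeline_config):
        limb = noiseless_limbs[0]
        rec = generate_discrete_trials(limb, seed=1)
        M = np.concatenate([rec.window_signal(w)[:, ::2] for w in rec.windows], axis=1)
        assert select_synergy_count(M, seed=1, restarts=4) == 3

    def test_iid_noise_needs_all_channels(self, rng):
        M = rng.uniform(0.0, 1.0, (4, 600))
        vaf3 = nmf_decompose(M, 3, seed=2, restarts=4).vaf
        assert vaf3 <= 0.95  # boundary behaviour verified directly
        assert select_synergy_count(M, seed=2, restarts=4) == 4


class TestActivationVector:
    def test_constant_single_synergy(self):
        C = np.zeros((3, 100))
        C[0] = 1.0
        sav = synergy_activation_vector(C, 100.0, TrialWindow("PF", 0.0, 1.0))
        assert np.allclose(sav.u, [1.0, 0.0, 0.0])

    def test_equal_constant_pair_normalizes(self):
        C = np.zeros((3, 100))
        C[0] = C[1] = 0.4
        sav = synergy_activation_vector(C, 100.0, TrialWindow("DF", 0.0, 1.0))
        assert np.allclose(sav.u, [1 / np.sqrt(2), 1 / np.sqrt(2), 0.0])

    def test_ramp_against_trapezoid_oracle(self):
        # c1 ramps 0 -> 1, c2 constant 0.5: time averages (0.5, 0.5)
        n = 101
        C = np.vstack([np.linspace(0, 1, n), np.full(n, 0.5)])
        sav = synergy_activation_vector(C, 100.0, TrialWindow("IN", 0.0, 1.01))
        oracle = np.array([np.trapezoid(C[0], dx=0.01), np.trapezoid(C[1], dx=0.01)])
        oracle = oracle / np.linalg.norm(oracle)
        assert np.allclose(sav.u[:2], oracle, atol=1e-9)
        assert sav.u[2] == 0.0

    def test_all_zero_average_flags_degenerate(self):
        sav = synergy_activation_vector(np.zeros((2, 50)), 50.0, TrialWindow("EV", 0.0, 1.0))
        assert sav.degenerate


class TestPadding:
    def test_pads_missing_axes_with_zeros(self):
        out = pad_to_dim(np.array([[0.6, 0.8]]), 3)
        assert np.allclose(out, [[0.6, 0.8, 0.0]])

    def test_identity_when_already_three(self):
        v = np.array([[0.2, 0.3, 0.5]])
        assert np.array_equal(pad_to_dim(v, 3), v)

    def test_rejects_oversized_input(self):
        with pytest.raises(ValueError):
            pad_to_dim(np.ones((1, 4)), 3)


def test_noiseless_recovery_of_true_synergies(noiseless_limbs, fast_pipeline_config):
    """Extraction on noiseless discrete trials recovers each limb's operative
    synergy columns with matched cosine >= 0.99."""
    for limb in noiseless_limbs[:3]:
        rec = generate_discrete_trials(limb, seed=5)
        M = np.concatenate([rec.window_signal(w)[:, ::2] for w in rec.windows], axis=1)
        model = extract_synergies(M, seed=5, restarts=5)
        assert model.n_synergies == 3
        assert matched_mean_cosine(limb.W_true, model.W) >= 0.99
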