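"""Synthetic cohort generator: protocols, degradation model, determinism."""

import numpy as np
import pytest

from myosynergy.decoding import DirectionBasis
from myosynergy.pipeline import circle_controllability, extract_from_recording
from myosynergy.recording import MOVEMENTS
from myosynergy.synthetic import (CohortConfig, generate_circle_task, generate_discrete_trials,
                                  generate_ground_truth, generate_perception_trials,
                                  generate_speed_accuracy_trials, matched_mean_cosine,
                                  modulate_raw, response_curve)


class TestGroundTruth:
    def test_same_seed_reproduces_cohort_exactly(self, small_cohort_config):
        a = generate_ground_truth(small_cohort_config, 3)
        b = generate_ground_truth(small_cohort_config, 3)
        for la, lb in zip(a, b):
            assert la.limb_id == lb.limb_id
            assert np.array_equal(la.W_true, lb.W_true)
            assert all(np.array_equal(la.coeff_templates[m], lb.coeff_templates[m])
                       for m in MOVEMENTS)

    def test_full_strain_limb_is_uncorrupted(self, small_cohort_config):
        cfg = CohortConfig(n_ami=1, n_ctl=0, ami_ams=(1.0,), w_jitter=0.0)
        limb = generate_ground_truth(cfg, 0)[0]
        assert limb.fusion_level == pytest.approx(0.0)
        assert limb.mix_weight == pytest.approx(0.0)

    def test_zero_strain_limb_has_fused_synergies(self):
        """At AMS = 0 the corrupted synergy columns coactivate: every pairwise
        cosine exceeds the fusion target (verified by direct computation)."""
        cfg = CohortConfig(n_ami=1, n_ctl=0, ami_ams=(0.0,), w_jitter=0.0)
        limb = generate_ground_truth(cfg, 0)[0]
        assert limb.fusion_level == pytest.approx(1.0)
        W = limb.W_true
        for i in range(3):
            for j in range(i + 1, 3):
                assert W[:, i] @ W[:, j] > 0.9

    def test_fusion_level_monotone_in_ams(self):
        cfg = CohortConfig(n_ami=5, n_ctl=0, ami_ams=(0.1, 0.3, 0.5, 0.7, 0.9),
                           include_bio=False, w_jitter=0.0)
        limbs = generate_ground_truth(cfg, 0)
        fusion = [l.fusion_level for l in limbs]
        assert all(b < a for a, b in zip(fusion, fusion[1:]))

    def test_basis_similarity_calibrated_to_response_curve(self, noiseless_limbs):
        """Corrupted-basis similarity to the natural basis sits on the
        configured motor response curve."""
        from myosynergy.synthetic import _W_CANONICAL

        for limb in noiseless_limbs:
            if limb.group == "BIO":
                continue
            target = float(response_curve(limb.ams_true, limb.config.motor_amsc))
            got = matched_mean_cosine(_W_CANONICAL, limb.W_true)
            assert got == pytest.approx(target, abs=5e-3)

    def test_invalid_ams_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(ami_ams=(1.2,))


class TestDiscreteTrials:
    def test_protocol_window_counts(self, noiseless_limbs):
        limb = noiseless_limbs[0]
        rec = generate_discrete_trials(limb, 0)
        reps = limb.config.discrete_reps
        assert len(rec.windows) == 4 * reps
        for m in MOVEMENTS:
            assert sum(w.movement == m for w in rec.windows) == reps

    def test_movement_order_is_fixed_pf_in_df_ev(self, noiseless_limbs):
        rec = generate_discrete_trials(noiseless_limbs[0], 0)
        first_four = [w.movement for w in rec.windows[:4]]
        assert first_four == ["PF", "IN", "DF", "EV"]

    def test_seeds_change_noise_not_layout(self, small_cohort_config):
        limb = generate_ground_truth(small_cohort_config, 1)[0]
        r1 = generate_discrete_trials(limb, 1)
        r2 = generate_discrete_trials(limb, 2)
        assert [w.movement for w in r1.windows] == [w.movement for w in r2.windows]
        assert not np.array_equal(r1.signal, r2.signal)

    def test_envelopes_nonnegative_and_windows_in_bounds(self, noiseless_limbs):
        rec = generate_discrete_trials(noiseless_limbs[2], 0)
        assert np.all(rec.signal >= 0)
        ends = [w.t_end for w in rec.windows]
        starts = [w.t_start for w in rec.windows]
        assert max(ends) <= rec.duration + 1e-9
        assert all(b >= a for a, b in zip(ends, starts[1:]))  # disjoint


class TestCircleTask:
    def test_ideal_limb_reaches_high_controllability(self, noiseless_limbs, fast_pipeline_config):
        bio = next(l for l in noiseless_limbs if l.group == "BIO")
        rec = generate_discrete_trials(bio, 4)
        model, vec, _ = extract_from_recording(rec, fast_pipeline_config, 4, "b", "BIO")
        basis = DirectionBasis(u=vec.u)
        circ = generate_circle_task(bio, 4)
        assert circle_controllability(circ, model.W, basis) >= 0.95

    def test_single_dof_mode_scores_near_zero(self, noiseless_limbs, fast_pipeline_config):
        bio = next(l for l in noiseless_limbs if l.group == "BIO")
        rec = generate_discrete_trials(bio, 4)
        model, vec, _ = extract_from_recording(rec, fast_pipeline_config, 4, "b", "BIO")
        basis = DirectionBasis(u=vec.u)
        circ = generate_circle_task(bio, 4, single_dof=True)
        assert circle_controllability(circ, model.W, basis) <= 0.05

    def test_seeded_determinism(self, noiseless_limbs):
        limb = noiseless_limbs[1]
        assert np.array_equal(generate_circle_task(limb, 9).signal,
                              generate_circle_task(limb, 9).signal)


class TestSpeedAccuracy:
    def test_block_structure(self, noiseless_limbs):
        limb = noiseless_limbs[0]
        rec = generate_speed_accuracy_trials(limb, 0)
        cfg = limb.config
        assert len(rec.windows) == len(cfg.time_constraints) * 4 * cfg.speed_reps
        for tc in cfg.time_constraints:
            block = [w for w in rec.windows if w.time_constraint == tc]
            assert len(block) == 4 * cfg.speed_reps

    def test_within_block_order_randomized_by_seed(self, small_cohort_config):
        limb = generate_ground_truth(small_cohort_config, 1)[0]
        o1 = [w.movement for w in generate_speed_accuracy_trials(limb, 1).windows]
        o2 = [w.movement for w in generate_speed_accuracy_trials(limb, 2).windows]
        assert o1 != o2


class TestPerceptionTrials:
    def test_trial_counts_and_rom_levels(self, noiseless_limbs):
        limb = next(l for l in noiseless_limbs if l.group != "BIO")
        rec, gon = generate_perception_trials(limb, 0)
        pfdf = [w for w in rec.windows if w.movement in ("PF", "DF")]
        inev = [w for w in rec.windows if w.movement in ("IN", "EV")]
        assert len(pfdf) == limb.config.perception_pfdf_trials
        assert len(inev) == limb.config.perception_inev_trials
        assert set(w.rom_fraction for w in pfdf) == {0.25, 0.5, 0.75, 1.0}
        assert set(w.rom_fraction for w in inev) == {0.5, 1.0}

    def test_noiseless_full_gain_perception_is_identity(self):
        cfg = CohortConfig(n_ami=1, n_ctl=0, ami_ams=(1.0,)).noiseless()
        limb = generate_ground_truth(cfg, 0)[0]
        rec, gon = generate_perception_trials(limb, 0)
        for w in rec.windows:
            rom_deg = cfg.ankle_rom_deg if w.movement in ("PF", "DF") else cfg.subtalar_rom_deg
            col = "ankle_deg" if w.movement in ("PF", "DF") else "subtalar_deg"
            mask = (gon.time_s >= w.t_start) & (gon.time_s < w.t_end)
            perceived = gon.loc[mask, col].mean() / rom_deg
            sign = -1.0 if w.movement in ("PF", "IN") else 1.0
            assert perceived == pytest.approx(sign * w.rom_fraction, abs=1e-9)

    def test_zero_sensation_mode_is_uncorrelated(self):
        cfg = CohortConfig(n_ami=1, n_ctl=0, ami_ams=(0.9,),
                           zero_sensation_limbs=("AMI-1",))
        limb = generate_ground_truth(cfg, 0)[0]
        rec, gon = generate_perception_trials(limb, 0)
        commanded, perceived = [], []
        for w in rec.windows:
            if w.movement not in ("PF", "DF"):
                continue
            sign = -1.0 if w.movement == "PF" else 1.0
            commanded.append(sign * w.rom_fraction)
            mask = (gon.time_s >= w.t_start) & (gon.time_s < w.t_end)
            perceived.append(gon.loc[mask, "ankle_deg"].mean())
        r = np.corrcoef(commanded, perceived)[0, 1]
        assert abs(r) < 0.4


def test_raw_mode_round_trips_through_emg_chain(noiseless_limbs):
    """Carrier-modulated raw output, processed through the EMG chain,
    correlates strongly with the original envelope."""
    from myosynergy.emg import process_raw
    from myosynergy.recording import MUSCLES

    limb = noiseless_limbs[0]
    env = generate_discrete_trials(limb, 0)
    raw = modulate_raw(env, 0)
    assert raw.domain == "raw"
    maxima = {m: 1.0 for m in MUSCLES}
    rec = process_raw(raw, maxima)
    t_env = env.time
    up = np.interp(np.arange(rec.n_samples) / rec.sample_rate, t_env, env.signal[2])
    mask = up > 0.05
    corr = np.corrcoef(rec.signal[2][mask], up[mask])[0, 1]
    assert corr > 0.9
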