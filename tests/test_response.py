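"""AMS degree, Kendall tau, exponential response fits, jackknife, group tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myosynergy.response import (LN20, cohens_d, compute_ams, fit_response_curve,
                                 fit_with_jackknife, group_tests, jackknife_amsc,
                                 kendall_tau)


def _brute_force_tau_b(x, y):
    """Exhaustive tie-corrected pair counting (independent oracle)."""
    n = len(x)
    concordant = discordant = 0
    tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = np.sign(x[j] - x[i]), np.sign(y[j] - y[i])
        if dx == 0 and dy == 0:
            continue
        if dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx == dy:
            concordant += 1
        else:
            discordant += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))
    return (concordant - discordant) / denom


def _tie_term(v):
    _, counts = np.unique(v, return_counts=True)
    return sum(c * (c - 1) / 2 for c in counts)


class TestComputeAms:
    def test_full_strain_gives_one(self):
        assert compute_ams({"PFDF": 0.15, "INEV": 0.1}, {"PFDF": 0.15, "INEV": 0.1}) == 1.0

    def test_zero_strain_gives_zero(self):
        assert compute_ams({"PFDF": 0.0, "INEV": 0.0}, {"PFDF": 0.15, "INEV": 0.1}) == 0.0

    def test_mean_of_dof_ratios(self):
        assert compute_ams({"PFDF": 0.4, "INEV": 0.2}, {"PFDF": 1.0, "INEV": 1.0}) == pytest.approx(0.3)

    def test_ratios_clipped_at_one(self):
        assert compute_ams({"PFDF": 2.0, "INEV": 0.5}, {"PFDF": 1.0, "INEV": 1.0}) == pytest.approx(0.75)

    def test_missing_dof_rejected(self):
        with pytest.raises(ValueError):
            compute_ams({"PFDF": 0.1}, {"PFDF": 1.0, "INEV": 1.0})


class TestKendallTau:
    def test_strictly_increasing_is_one(self):
        tau, p = kendall_tau([1, 2, 3, 4, 5], [2, 4, 5, 7, 9])
        assert tau == pytest.approx(1.0)
        assert p < 0.05

    def test_strictly_decreasing_is_minus_one(self):
        tau, _ = kendall_tau([1, 2, 3, 4, 5], [9, 7, 5, 4, 2])
        assert tau == pytest.approx(-1.0)

    def test_known_five_point_example(self):
        # y = (2,1,4,3,5): 8 concordant, 2 discordant of 10 pairs -> 0.6
        tau, _ = kendall_tau([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert tau == pytest.approx(0.6)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=6), min_size=4, max_size=8),
           st.integers(min_value=0, max_value=10 ** 6))
    def test_matches_exhaustive_pair_counting(self, ys, seed):
        y = np.asarray(ys, float)
        x = np.arange(len(y), dtype=float)
        rng = np.random.default_rng(seed)
        x = rng.permutation(x)
        if np.ptp(y) == 0:
            return
        tau, _ = kendall_tau(x, y)
        assert tau == pytest.approx(_brute_force_tau_b(x, y), abs=1e-12)

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            kendall_tau([1, 1, 1, 1], [1, 2, 3, 4])


class TestResponseCurve:
    def _model(self, ams, y_inf=1.0, ams_c=0.21):
        lam = LN20 / ams_c
        return y_inf * (1 - np.exp(-lam * np.asarray(ams)))

    def test_recovers_known_amsc(self):
        ams = np.linspace(0.05, 1.0, 14)
        fit = fit_response_curve(ams, self._model(ams))
        assert fit.saturating
        assert fit.ams_c == pytest.approx(0.21, abs=1e-3)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_amsc_invariant_to_response_scaling(self):
        ams = np.linspace(0.05, 1.0, 14)
        y = self._model(ams)
        f1 = fit_response_curve(ams, y)
        f2 = fit_response_curve(ams, 7.3 * y)
        assert f1.ams_c == pytest.approx(f2.ams_c, rel=1e-6)

    def test_flat_responses_flagged_non_saturating(self):
        ams = np.linspace(0.1, 1.0, 10)
        fit = fit_response_curve(ams, np.full(10, 0.5) - 0.3 * ams)
        assert not fit.saturating
        assert np.isnan(fit.ams_c)

    def test_optional_intercept_recovers_offset_curve(self):
        ams = np.linspace(0.05, 1.0, 14)
        y = 0.4 + 0.6 * (1 - np.exp(-(LN20 / 0.3) * ams))
        fit = fit_response_curve(ams, y, with_intercept=True)
        assert fit.ams_c == pytest.approx(0.3, abs=1e-3)


class TestJackknife:
    def test_noiseless_data_has_vanishing_sd(self):
        ams = np.linspace(0.05, 1.0, 14)
        lam = LN20 / 0.21
        mean, sd = jackknife_amsc(ams, 1 - np.exp(-lam * ams))
        assert mean == pytest.approx(0.21, abs=1e-3)
        assert sd < 1e-6

    def test_matches_direct_enumeration_for_n6(self, rng):
        ams = np.array([0.1, 0.25, 0.4, 0.55, 0.7, 0.95])
        y = 1 - np.exp(-(LN20 / 0.3) * ams) + rng.normal(0, 0.02, 6)
        mean, sd = jackknife_amsc(ams, y)
        loo = [fit_response_curve(np.delete(ams, k), np.delete(y, k)).ams_c for k in range(6)]
        assert mean == pytest.approx(np.mean(loo), abs=1e-9)
        assert sd == pytest.approx(np.std(loo, ddof=1), abs=1e-9)

    def test_duplicated_dataset_is_stable(self, rng):
        ams = np.linspace(0.1, 1.0, 7)
        y = 1 - np.exp(-(LN20 / 0.25) * ams) + rng.normal(0, 0.01, 7)
        full = fit_response_curve(np.tile(ams, 2), np.tile(y, 2)).ams_c
        mean, _ = jackknife_amsc(np.tile(ams, 2), np.tile(y, 2))
        assert mean == pytest.approx(full, abs=5e-3)

    def test_fit_with_jackknife_populates_fields(self):
        ams = np.linspace(0.05, 1.0, 14)
        fit = fit_with_jackknife(ams, 1 - np.exp(-(LN20 / 0.21) * ams))
        assert fit.jackknife_mean is not None and fit.jackknife_sd is not None


def _paired_table(ami, ctl, bio_a, bio_c):
    rows = []
    for g, vals in (("AMI", ami), ("CTL", ctl), ("BIO-A", bio_a), ("BIO-C", bio_c)):
        side = "A" if g.endswith("A") or g == "AMI" else "C"
        for i, v in enumerate(vals):
            rows.append({"limb_id": f"{g}-{i}", "group": g,
                         "subject": f"{side}{i}", "value": v})
    return pd.DataFrame(rows)


class TestGroupTests:
    def test_identical_paired_groups_give_t_zero_p_half(self, rng):
        vals = rng.uniform(0.5, 1.0, 6)
        other = rng.uniform(0.5, 1.0, 6)
        table = _paired_table(vals, other, vals, other + rng.normal(0, 0.1, 6))
        out = group_tests(table, "value")
        assert out["t_ami_bioa"] == pytest.approx(0.0, abs=1e-12)
        assert out["p_ami_bioa"] == pytest.approx(0.5)

    def test_cohens_d_of_unit_separation(self):
        # mean difference equal to the pooled s.d. gives d = 1
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x - np.std(x, ddof=1)
        assert cohens_d(x, y) == pytest.approx(1.0)

    def test_interaction_f_matches_hand_decomposition(self):
        """Balanced 2x2 design: F for the interaction from the textbook
        sums-of-squares decomposition."""
        ami = np.array([0.9, 1.0, 1.1, 1.0])
        ctl = np.array([0.5, 0.6, 0.4, 0.5])
        bio_a = np.array([1.0, 1.1, 0.9, 1.0])
        bio_c = np.array([1.0, 0.9, 1.1, 1.0])
        table = _paired_table(ami, ctl, bio_a, bio_c)
        out = group_tests(table, "value")
        cells = [ami, bio_a, ctl, bio_c]
        grand = np.mean(np.concatenate(cells))
        m = np.array([[ami.mean(), bio_a.mean()], [ctl.mean(), bio_c.mean()]])
        row_m = m.mean(axis=1)
        col_m = m.mean(axis=0)
        n = 4
        ss_inter = n * sum((m[i, j] - row_m[i] - col_m[j] + grand) ** 2
                           for i in range(2) for j in range(2))
        ss_err = sum(((c - c.mean()) ** 2).sum() for c in cells)
        f_oracle = (ss_inter / 1) / (ss_err / (16 - 4))
        assert out["anova_f_interaction"] == pytest.approx(f_oracle, rel=1e-9)

    def test_unmatched_pairs_rejected(self, rng):
        table = _paired_table(rng.uniform(size=4), rng.uniform(size=4),
                              rng.uniform(size=4), rng.uniform(size=4))
        table.loc[table.group == "BIO-A", "subject"] = ["A9", "A8", "A7", "A6"]
        with pytest.raises(ValueError):
            group_tests(table, "value")
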