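"""Split-plot mixed ANOVA: identities, sphericity, cross-checks, post-hocs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.linalg import fractional_matrix_power

from pergss.stats import emm_posthoc, mixed_anova
from pergss.synthetic import CohortDesign, generate_cohort_table
from pergss.stats import average_eyes


def _long(groups_data, factor="check_size_deg"):
    """groups_data: {group: (n_subjects x n_levels) matrix} -> long DataFrame."""
    rows = []
    for group, mat in groups_data.items():
        for s, row in enumerate(np.atleast_2d(mat)):
            for lvl, val in enumerate(row):
                rows.append((f"{group}{s:02d}", group, float(lvl), val))
    return pd.DataFrame(rows, columns=["subject", "group", factor, "dv"])


def test_all_equal_degenerate():
    records, _ = generate_cohort_table(CohortDesign(seed=0))
    records["amplitude_uV"] = 1.0
    res = mixed_anova(average_eyes(records), "amplitude_uV")
    assert np.allclose(res.effects["ss"], 0.0)
    assert np.allclose(res.effects["F"], 0.0)
    assert np.allclose(res.effects["p_uncorrected"], 1.0)
    assert np.allclose(res.effects["p_corrected"], 1.0)


def test_split_plot_f_equals_squared_t_on_two_level_design():
    """Classical identities: group F = t² on subject means; interaction F = t²
    on within-subject differences."""
    rng = np.random.default_rng(8)
    a = rng.normal(0.0, 1.0, size=(9, 2))
    b = rng.normal(0.5, 1.2, size=(9, 2))
    res = mixed_anova(_long({"ga": a, "gb": b}), "dv",
                      within=("check_size_deg",))
    t_means = sps.ttest_ind(a.mean(axis=1), b.mean(axis=1))
    t_diffs = sps.ttest_ind(a[:, 1] - a[:, 0], b[:, 1] - b[:, 0])
    assert res.effects.loc["group", "F"] == pytest.approx(
        t_means.statistic**2, rel=1e-9)
    assert res.effects.loc["group", "p_uncorrected"] == pytest.approx(
        t_means.pvalue, rel=1e-9)
    assert res.effects.loc["check_size_deg:group", "F"] == pytest.approx(
        t_diffs.statistic**2, rel=1e-9)


def test_ss_additivity(eye_averaged):
    res = mixed_anova(eye_averaged, "amplitude_uV")
    assert res.ss_additivity_gap() < 1e-8
    assert (res.effects["ss"] >= 0).all()
    assert (res.errors["ss"] >= 0).all()


def test_gg_epsilon_one_under_constructed_compound_symmetry():
    """Data transformed to an exactly spherical within-group covariance."""
    rng = np.random.default_rng(15)
    groups = {}
    for g in ("ga", "gb"):
        x = rng.normal(size=(12, 4))
        xc = x - x.mean(axis=0)
        cov = xc.T @ xc / 11
        whitened = xc @ np.real(fractional_matrix_power(cov, -0.5))
        groups[g] = whitened + np.array([1.0, 2.0, 1.5, 0.5])
    res = mixed_anova(_long(groups), "dv", within=("check_size_deg",))
    assert res.effects.loc["check_size_deg", "gg_epsilon"] == pytest.approx(
        1.0, abs=1e-9)


def test_two_level_within_effects_have_epsilon_one(eye_averaged):
    res = mixed_anova(eye_averaged, "amplitude_uV")
    assert res.effects.loc["reversal_rate_rps", "gg_epsilon"] == 1.0
    eps4 = res.effects.loc["check_size_deg", "gg_epsilon"]
    assert 1.0 / 3.0 <= eps4 <= 1.0


def test_f_invariant_under_constant_shift_and_relabeling(eye_averaged):
    res = mixed_anova(eye_averaged, "amplitude_uV")
    shifted = eye_averaged.assign(amplitude_uV=eye_averaged["amplitude_uV"] + 5.0)
    res_shift = mixed_anova(shifted, "amplitude_uV")
    np.testing.assert_allclose(res_shift.effects["F"], res.effects["F"],
                               rtol=1e-9)
    # relabel check sizes identically for all subjects: group F unchanged
    relabel = {0.8: 16.0, 1.6: 3.2, 3.2: 1.6, 16.0: 0.8}
    perm = eye_averaged.assign(
        check_size_deg=eye_averaged["check_size_deg"].map(relabel))
    res_perm = mixed_anova(perm, "amplitude_uV")
    assert res_perm.effects.loc["group", "F"] == pytest.approx(
        res.effects.loc["group", "F"], rel=1e-9)


def test_unbalanced_and_incomplete_designs_rejected(eye_averaged):
    with pytest.raises(ValueError, match="unbalanced|incomplete"):
        mixed_anova(eye_averaged.iloc[:-1], "amplitude_uV")
    dropped = eye_averaged[eye_averaged["subject"] != "con01"]
    with pytest.raises(ValueError, match="unequal group sizes"):
        mixed_anova(dropped, "amplitude_uV")


def test_matches_pingouin_single_within_factor(eye_averaged):
    import pingouin as pg

    one = eye_averaged[eye_averaged["reversal_rate_rps"] == 12.5]
    mine = mixed_anova(one, "amplitude_uV", within=("check_size_deg",))
    ref = pg.mixed_anova(data=one, dv="amplitude_uV", within="check_size_deg",
                         subject="subject", between="group", correction=True)
    ref = ref.set_index("Source")
    assert mine.effects.loc["group", "F"] == pytest.approx(
        ref.loc["group", "F"], rel=1e-9)
    assert mine.effects.loc["check_size_deg", "F"] == pytest.approx(
        ref.loc["check_size_deg", "F"], rel=1e-9)
    assert mine.effects.loc["check_size_deg:group", "F"] == pytest.approx(
        ref.loc["Interaction", "F"], rel=1e-9)
    assert mine.effects.loc["check_size_deg", "p_uncorrected"] == pytest.approx(
        ref.loc["check_size_deg", "p_unc"], rel=1e-9)
    # epsilon estimators differ only in the centering convention
    assert mine.effects.loc["check_size_deg", "gg_epsilon"] == pytest.approx(
        ref.loc["check_size_deg", "eps"], abs=0.05)


def test_frozen_split_plot_regression():
    """Fixed-seed cohort against values validated once with an independent
    split-plot implementation (sum-to-zero Type III with GG correction)."""
    records, _ = generate_cohort_table(CohortDesign(seed=3))
    res = mixed_anova(average_eyes(records), "amplitude_uV")
    eff = res.effects
    assert eff.loc["group", "F"] == pytest.approx(21.9524, abs=2e-4)
    assert eff.loc["check_size_deg", "F"] == pytest.approx(14.7594, abs=2e-4)
    assert eff.loc["reversal_rate_rps", "F"] == pytest.approx(10.1115, abs=2e-4)
    assert eff.loc["check_size_deg", "gg_epsilon"] == pytest.approx(
        0.91542, abs=1e-5)
    assert eff.loc["check_size_deg:reversal_rate_rps", "gg_epsilon"] == (
        pytest.approx(0.91298, abs=1e-5))
    assert eff.loc["group", "p_uncorrected"] == pytest.approx(1.132e-4, rel=1e-3)


class TestEmmPosthoc:
    def test_difference_equals_raw_group_means(self, eye_averaged):
        ph = emm_posthoc(eye_averaged, "amplitude_uV")
        cells = eye_averaged.groupby(
            ["check_size_deg", "reversal_rate_rps", "group"])["amplitude_uV"].mean()
        for _, row in ph.iterrows():
            key = (row["check_size_deg"], row["reversal_rate_rps"])
            expected = cells[(*key, "control")] - cells[(*key, "patient")]
            assert row["emm_difference"] == pytest.approx(expected, abs=1e-10)

    def test_identical_groups_give_null_contrasts(self, eye_averaged):
        controls = eye_averaged[eye_averaged["group"] == "control"]
        mirrored = controls.assign(
            group="patient", subject=controls["subject"].str.replace("con", "pat"))
        both = pd.concat([controls, mirrored], ignore_index=True)
        ph = emm_posthoc(both, "amplitude_uV")
        assert np.allclose(ph["emm_difference"], 0.0, atol=1e-12)
        assert np.allclose(ph["p_uncorrected"], 1.0)

    def test_pooled_se_constant_across_conditions(self, eye_averaged):
        ph = emm_posthoc(eye_averaged, "amplitude_uV")
        assert ph["se"].nunique() == 1
        assert (ph["se"] > 0).all()
        # frozen value validated once against a marginal-means reference
        assert ph["se"].iloc[0] == pytest.approx(0.198, abs=5e-4)

    def test_hedges_sign_convention(self, eye_averaged):
        """Positive g where controls exceed patients (the default cohort)."""
        ph = emm_posthoc(eye_averaged, "amplitude_uV")
        assert (ph["hedges_g"] > 0).all()
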