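"""Group-level inference for steady-state PERG cohorts.

Implements the analysis layer for a two-group, fully-crossed repeated
measures design: eye averaging, Wilcoxon tests, a split-plot (mixed)
ANOVA with Greenhouse–Geisser sphericity correction computed from first
principles, per-condition group contrasts of estimated marginal means with
a pooled standard error, Hedges-corrected Cohen's d effect sizes,
Bonferroni–Holm multiple-comparison control, check-size amplitude ratios
and relative-reduction profiles.

The ANOVA is built directly from its sums-of-squares decomposition and
orthonormal-contrast covariances rather than delegated to a stats package,
so every degree of freedom and epsilon is inspectable; established
implementations serve as cross-checks in the test suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "average_eyes",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "mixed_anova",
    "AnovaResult",
    "emm_posthoc",
    "hedges_g",
    "holm_adjust",
    "perg_ratio",
    "ratio_table",
    "relative_reduction",
    "effect_size_profile",
]


# ---------------------------------------------------------------------------
# eye averaging

def average_eyes(records: pd.DataFrame, dv_columns: Sequence[str] | None = None
                 ) -> pd.DataFrame:
    """Average the dependent measures across available eyes per subject x condition.

    Rows with NaN in a measure are treated as missing for that measure; a
    subject x condition cell with a single usable eye passes through
    unchanged (as when one eye's recording is excluded for electrode
    displacement).  A cell with no usable amplitude at all raises.  The
    result has one row per subject x condition with an ``n_eyes`` column.
    """
    if dv_columns is None:
        dv_columns = [c for c in ("amplitude_uV", "response_time_ms", "noise_uV",
                                  "snr") if c in records.columns]
    keys = ["subject", "group", "check_size_deg", "reversal_rate_rps"]
    grouped = records.groupby(keys, sort=True)
    out = grouped[list(dv_columns)].mean().reset_index()
    out["n_eyes"] = grouped["amplitude_uV"].count().to_numpy()
    if (out["n_eyes"] == 0).any():
        bad = out.loc[out["n_eyes"] == 0, keys].to_dict("records")
        raise ValueError(f"no usable eye for cells: {bad}")
    return out


# ---------------------------------------------------------------------------
# Wilcoxon wrappers

class TestResult(NamedTuple):
    statistic: float
    p_value: float
    method: str


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon rank-sum (Mann–Whitney) test.

    Exact null distribution when both samples have <= 25 observations and
    the pooled data is tie-free; otherwise the normal approximation with
    tie correction.  ``alternative`` refers to ``x`` relative to ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 25 and len(y) <= 25 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return TestResult(float(res.statistic), float(res.pvalue), method)


def wilcoxon_signed_rank(diffs, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon's rule); if every difference is
    zero the test is uninformative and returns p = 1 with a warning.
    """
    diffs = np.asarray(diffs, dtype=float)
    if len(diffs) == 0:
        raise ValueError("empty sample")
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        warnings.warn("all paired differences are zero; the signed-rank test is "
                      "uninformative", stacklevel=2)
        return TestResult(0.0, 1.0, "degenerate")
    ties = len(np.unique(np.abs(nonzero))) < len(nonzero)
    method = "exact" if (len(nonzero) <= 25 and not ties) else "approx"
    res = sps.wilcoxon(nonzero, alternative=alternative, method=method)
    return TestResult(float(res.statistic), float(res.pvalue), method)


# ---------------------------------------------------------------------------
# split-plot mixed ANOVA

@dataclass
class AnovaResult:
    """Split-plot ANOVA: per-effect table plus the error strata.

    ``effects`` is indexed by effect name (e.g. ``group``,
    ``check_size_deg``, ``check_size_deg:group``) with columns ss, df_num,
    df_den, F, p_uncorrected, gg_epsilon, df_num_corrected,
    df_den_corrected, p_corrected.  ``errors`` holds each error stratum's
    ss and df.  Effect and error sums of squares add up to the total.
    """

    effects: pd.DataFrame
    errors: pd.DataFrame
    ss_total: float
    design: dict = field(default_factory=dict)

    def ss_additivity_gap(self) -> float:
        """Relative gap between total SS and the sum of all components."""
        parts = self.effects["ss"].sum() + self.errors["ss"].sum()
        denom = max(self.ss_total, 1e-300)
        return abs(parts - self.ss_total) / denom


def _orthonormal_contrasts(n_levels: int) -> np.ndarray:
    """(n−1) x n orthonormal rows, each orthogonal to the constant vector."""
    h = np.zeros((n_levels - 1, n_levels))
    for i in range(1, n_levels):
        h[i - 1, :i] = 1.0
        h[i - 1, i] = -float(i)
        h[i - 1] /= np.linalg.norm(h[i - 1])
    return h


def _gg_epsilon(cell_matrix: np.ndarray, groups: np.ndarray,
                contrast: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from the pooled within-group covariance
    of the orthonormal-contrast scores."""
    r = contrast.shape[0]
    if r <= 1:
        return 1.0
    scores = cell_matrix @ contrast.T
    centered = np.empty_like(scores)
    n_groups = 0
    for g in np.unique(groups):
        sel = groups == g
        centered[sel] = scores[sel] - scores[sel].mean(axis=0)
        n_groups += 1
    dof = cell_matrix.shape[0] - n_groups
    if dof < 1:
        return 1.0
    sigma = centered.T @ centered / dof
    trace = np.trace(sigma)
    denom = r * float((sigma**2).sum())
    if denom <= 0 or trace <= 0:
        return 1.0  # degenerate (zero variability): sphericity holds trivially
    eps = trace**2 / denom
    return float(min(1.0, max(1.0 / r, eps)))


def _f_test(ss_eff: float, df_eff: float, ss_err: float, df_err: float
            ) -> tuple[float, float]:
    if df_err <= 0:
        return math.nan, math.nan
    ms_err = ss_err / df_err
    if ms_err == 0.0:
        return (0.0, 1.0) if ss_eff == 0.0 else (math.inf, 0.0)
    f = (ss_eff / df_eff) / ms_err
    return f, float(sps.f.sf(f, df_eff, df_err))


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str = "subject",
    between: str = "group",
    within: Sequence[str] = ("check_size_deg", "reversal_rate_rps"),
) -> AnovaResult:
    """Split-plot (mixed) repeated-measures ANOVA on a balanced design.

    One between-subject factor and one or two within-subject factors.  The
    between effect is tested against subjects-within-groups; each within
    effect (and its interaction with the between factor) against the
    corresponding effect x subject-within-group stratum.  For within
    effects with more than two levels the Greenhouse–Geisser epsilon is
    estimated from the pooled within-group covariance of orthonormal
    contrasts and applied multiplicatively to both degrees of freedom;
    2-level effects have epsilon 1 by construction.

    Requires a complete balanced design (every subject measured once in
    every within cell, equal group sizes); missing cells raise.
    """
    within = tuple(within)
    if not 1 <= len(within) <= 2:
        raise ValueError("one or two within factors supported")
    df = data[[subject, between, *within, dv]].copy()
    if df[dv].isna().any():
        raise ValueError(f"missing {dv} values; the design must be complete")

    # design validation: nesting, completeness, balance
    subj_groups = df.groupby(subject)[between].nunique()
    if (subj_groups != 1).any():
        raise ValueError("each subject must belong to exactly one group")
    cell_counts = df.groupby([subject, *within], sort=False).size()
    levels = [np.sort(df[w].unique()) for w in within]
    n_cells = int(np.prod([len(lv) for lv in levels]))
    per_subject = df.groupby(subject).size()
    if (cell_counts != 1).any() or (per_subject != n_cells).any():
        raise ValueError("unbalanced or incomplete design: every subject needs "
                         "exactly one observation per within cell")
    group_sizes = df.groupby(between)[subject].nunique()
    if len(group_sizes) < 2 or (group_sizes < 2).any():
        raise ValueError("need >= 2 groups with >= 2 subjects each")
    if group_sizes.nunique() != 1:
        raise ValueError("unequal group sizes are not supported")

    n_subjects = int(per_subject.size)
    p = len(group_sizes)
    n = int(group_sizes.iloc[0])

    y = df[dv].to_numpy(dtype=float)
    m = y.mean()

    def cmean(cols: Sequence[str]) -> np.ndarray:
        return df.groupby(list(cols), sort=False)[dv].transform("mean").to_numpy()

    G, S = between, subject
    mg, ms_ = cmean([G]), cmean([S])
    ss_total = float(((y - m) ** 2).sum())

    effects: dict[str, dict] = {}
    errors: dict[str, dict] = {}

    effects[between] = {"ss": float(((mg - m) ** 2).sum()), "df": p - 1,
                        "stratum": "subjects"}
    errors["subjects"] = {"ss": float(((ms_ - mg) ** 2).sum()), "df": p * (n - 1)}

    w_levels = dict(zip(within, levels))

    def n_lv(w):
        return len(w_levels[w])

    # per within factor: main effect, x group, x subject-within-group error
    per_factor = {}
    for w in within:
        mw, mgw, msw = cmean([w]), cmean([G, w]), cmean([S, w])
        a = n_lv(w)
        stratum = f"{w} x subjects"
        effects[w] = {"ss": float(((mw - m) ** 2).sum()), "df": a - 1,
                      "stratum": stratum}
        effects[f"{w}:{between}"] = {
            "ss": float(((mgw - mg - mw + m) ** 2).sum()),
            "df": (p - 1) * (a - 1), "stratum": stratum}
        errors[stratum] = {"ss": float(((msw - ms_ - mgw + mg) ** 2).sum()),
                           "df": p * (n - 1) * (a - 1)}
        per_factor[w] = (mw, mgw, msw)

    if len(within) == 2:
        w1, w2 = within
        a, b = n_lv(w1), n_lv(w2)
        m1, mg1, ms1 = per_factor[w1]
        m2, mg2, ms2 = per_factor[w2]
        m12 = cmean([w1, w2])
        mg12 = cmean([G, w1, w2])
        stratum = f"{w1}:{w2} x subjects"
        effects[f"{w1}:{w2}"] = {
            "ss": float(((m12 - m1 - m2 + m) ** 2).sum()),
            "df": (a - 1) * (b - 1), "stratum": stratum}
        effects[f"{w1}:{w2}:{between}"] = {
            "ss": float(((mg12 - mg1 - mg2 - m12 + m1 + m2 + mg - m) ** 2).sum()),
            "df": (p - 1) * (a - 1) * (b - 1), "stratum": stratum}
        errors[stratum] = {
            "ss": float(((y - ms1 - ms2 - mg12 + ms_ + mg1 + mg2 - mg) ** 2).sum()),
            "df": p * (n - 1) * (a - 1) * (b - 1)}

    # Greenhouse–Geisser epsilons from subject x within-cell score matrices
    subj_index = df[subject].unique()
    group_of = df.groupby(subject)[between].first().reindex(subj_index).to_numpy()
    contrasts = {w: _orthonormal_contrasts(n_lv(w)) for w in within}
    epsilons: dict[str, float] = {}
    for w in within:
        pivot = df.pivot_table(index=subject, columns=w, values=dv, aggfunc="mean")
        pivot = pivot.reindex(index=subj_index, columns=w_levels[w])
        epsilons[w] = _gg_epsilon(pivot.to_numpy(), group_of, contrasts[w])
    if len(within) == 2:
        w1, w2 = within
        pivot = df.pivot_table(index=subject, columns=[w1, w2], values=dv,
                               aggfunc="mean")
        cols = pd.MultiIndex.from_product([w_levels[w1], w_levels[w2]])
        pivot = pivot.reindex(index=subj_index, columns=cols)
        epsilons[f"{w1}:{w2}"] = _gg_epsilon(
            pivot.to_numpy(), group_of, np.kron(contrasts[w1], contrasts[w2]))

    rows = []
    for name, eff in effects.items():
        err = errors[eff["stratum"]]
        f_val, p_unc = _f_test(eff["ss"], eff["df"], err["ss"], err["df"])
        base = name.replace(f":{between}", "") if name != between else between
        eps = epsilons.get(base, 1.0) if name != between else 1.0
        df1c, df2c = eps * eff["df"], eps * err["df"]
        if math.isnan(f_val):
            p_corr = math.nan
        elif math.isinf(f_val):
            p_corr = 0.0
        elif f_val == 0.0 and err["ss"] == 0.0:
            p_corr = 1.0
        else:
            p_corr = float(sps.f.sf(f_val, df1c, df2c))
        rows.append((name, eff["ss"], eff["df"], err["df"], f_val, p_unc,
                     eps, df1c, df2c, p_corr))
    effects_df = pd.DataFrame(
        rows, columns=["effect", "ss", "df_num", "df_den", "F", "p_uncorrected",
                       "gg_epsilon", "df_num_corrected", "df_den_corrected",
                       "p_corrected"]).set_index("effect")
    errors_df = pd.DataFrame(
        [(k, v["ss"], v["df"]) for k, v in errors.items()],
        columns=["stratum", "ss", "df"]).set_index("stratum")

    return AnovaResult(effects=effects_df, errors=errors_df, ss_total=ss_total,
                       design={"n_per_group": n, "n_groups": p,
                               "n_subjects": n_subjects,
                               "within_levels": {w: list(map(float, lv))
                                                 if np.issubdtype(lv.dtype, np.number)
                                                 else list(lv)
                                                 for w, lv in w_levels.items()}})


# ---------------------------------------------------------------------------
# estimated-marginal-mean post-hoc contrasts

def emm_posthoc(
    data: pd.DataFrame,
    dv: str,
    subject: str = "subject",
    between: str = "group",
    within: Sequence[str] = ("check_size_deg", "reversal_rate_rps"),
    reference_group: str = "control",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-condition group contrast of estimated marginal means.

    In this balanced design the EMM difference equals the difference of raw
    group means in each within cell.  The standard error pools every
    within-subject error stratum with the between-subject stratum into a
    single condition-independent SE — one number for the whole table, as a
    mixed-model marginal contrast yields — with the pooled degrees of
    freedom; two-sided p-values come from the t distribution on those df.
    Holm flags control the familywise error across the table's conditions,
    and Hedges g (positive when the reference group is larger) quantifies
    each contrast.
    """
    anova = mixed_anova(data, dv, subject=subject, between=between, within=within)
    n = anova.design["n_per_group"]
    if anova.design["n_groups"] != 2:
        raise ValueError("post-hoc group contrasts require exactly 2 groups")
    groups = data[between].unique()
    other = [g for g in groups if g != reference_group]
    if reference_group not in groups or len(other) != 1:
        raise ValueError(f"reference group {reference_group!r} not found or more "
                         f"than two groups present")
    other = other[0]

    pooled_ss = float(anova.errors["ss"].sum())
    pooled_df = float(anova.errors["df"].sum())
    ms = pooled_ss / pooled_df
    se = math.sqrt(2.0 * ms / n)

    within = tuple(within)
    cells = (data.groupby([*within, between])[dv]
             .agg(["mean", "std", "count"]).reset_index())
    rows = []
    for keys, cell in cells.groupby(list(within), sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        ref = cell[cell[between] == reference_group].iloc[0]
        oth = cell[cell[between] == other].iloc[0]
        diff = ref["mean"] - oth["mean"]
        if se > 0:
            t = diff / se
            p = 2.0 * float(sps.t.sf(abs(t), pooled_df))
        else:
            t, p = 0.0, 1.0
        g = hedges_g(diff, ref["std"], int(ref["count"]), oth["std"],
                     int(oth["count"]))
        rows.append((*keys, ref["mean"], ref["std"], oth["mean"], oth["std"],
                     diff, se, pooled_df, t, p, g))
    out = pd.DataFrame(rows, columns=[
        *within, f"mean_{reference_group}", f"sd_{reference_group}",
        f"mean_{other}", f"sd_{other}", "emm_difference", "se", "df",
        "t", "p_uncorrected", "hedges_g"])
    significant, adjusted = holm_adjust(out["p_uncorrected"].to_numpy(), alpha)
    out["p_holm"] = adjusted
    out["holm_significant"] = significant
    return out


# ---------------------------------------------------------------------------
# effect sizes and multiplicity

def hedges_g(mean_diff: float, sd1: float, n1: int, sd2: float, n2: int) -> float:
    """Hedges-corrected Cohen's d for two independent samples.

    ``d = mean_diff / s_pooled`` with the pooled SD
    ``sqrt(((n1−1)sd1² + (n2−1)sd2²)/(n1+n2−2))``, multiplied by the
    small-sample correction ``J = 1 − 3/(4(n1+n2) − 9)``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be >= 0")
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if pooled_var == 0.0:
        if mean_diff == 0.0:
            return 0.0
        raise ValueError("zero pooled SD with nonzero mean difference")
    d = mean_diff / math.sqrt(pooled_var)
    j = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return d * j


def holm_adjust(p_values, familywise_alpha: float = 0.05
                ) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni–Holm step-down procedure.

    Returns ``(significant, adjusted)``: the rejection flags at the
    familywise alpha and the Holm-adjusted p-values (running maximum of
    ``(m−i+1)·p_(i)``, capped at 1).  Flags are exactly
    ``adjusted <= alpha``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = (m - np.arange(m)) * p[order]
    adjusted_sorted = np.minimum(np.maximum.accumulate(stepped), 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    significant = adjusted <= familywise_alpha
    return significant, adjusted


# ---------------------------------------------------------------------------
# check-size ratios and reduction profiles

class RatioResult(NamedTuple):
    ratio: float
    floored: bool


def perg_ratio(amplitude_small_uV: float, amplitude_large_uV: float,
               floor_uV: float = 0.05) -> RatioResult:
    """Check-size amplitude ratio (finest / coarsest check).

    A near-zero denominator is floored at ``floor_uV`` and flagged, keeping
    the ratio finite for extinguished responses.
    """
    if amplitude_small_uV < 0 or amplitude_large_uV < 0:
        raise ValueError("amplitudes must be >= 0")
    floored = amplitude_large_uV < floor_uV
    return RatioResult(amplitude_small_uV / max(amplitude_large_uV, floor_uV),
                       floored)


def ratio_table(records: pd.DataFrame, check_small_deg: float = 0.8,
                check_large_deg: float = 16.0, floor_uV: float = 0.05
                ) -> pd.DataFrame:
    """Per subject x frequency amplitude ratios from an eye-averaged table."""
    rows = []
    for (subj, group, rate), cell in records.groupby(
            ["subject", "group", "reversal_rate_rps"], sort=True):
        amp = cell.set_index("check_size_deg")["amplitude_uV"]
        if check_small_deg not in amp.index or check_large_deg not in amp.index:
            raise ValueError(
                f"subject {subj} at {rate} rps lacks the {check_small_deg} or "
                f"{check_large_deg} degree condition")
        r = perg_ratio(float(amp[check_small_deg]), float(amp[check_large_deg]),
                       floor_uV)
        rows.append((subj, group, rate, r.ratio, r.floored))
    return pd.DataFrame(rows, columns=["subject", "group", "reversal_rate_rps",
                                       "ratio", "floored"])


def relative_reduction(mean_control: float, mean_patient: float) -> float:
    """Percent reduction of the patient mean relative to the control mean."""
    if mean_control <= 0:
        raise ValueError("mean_control must be > 0")
    return 100.0 * (mean_control - mean_patient) / mean_control


def effect_size_profile(posthoc: pd.DataFrame, reference_group: str = "control"
                        ) -> pd.DataFrame:
    """Effect size and relative reduction per condition (reduction-profile plot data)."""
    other = [c.removeprefix("mean_") for c in posthoc.columns
             if c.startswith("mean_") and c != f"mean_{reference_group}"][0]
    out = posthoc[["check_size_deg", "reversal_rate_rps", "hedges_g"]].copy()
    out["relative_reduction_pct"] = [
        relative_reduction(r[f"mean_{reference_group}"], r[f"mean_{other}"])
        for _, r in posthoc.iterrows()]
    return out
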