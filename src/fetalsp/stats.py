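"""Group-level inference: trimester growth, hemispheric asymmetry, ANCOVA.

Implements the statistical layer of the regional subplate analysis:

* trimester grouping (late 2nd: 22-27 wGA vs early 3rd: >27-32 wGA) and
  percent change of group means with delta-method standard errors,
* homotopic growth Z-tests from pooled percent-change standard errors,
* the normalized asymmetry index AI = (R - L) * 100 / (0.5 * (R + L))
  (positive = rightward), one-sample and paired lateralization t-tests,
  AI-change Z-tests between trimester groups,
* Benjamini-Hochberg FDR correction, applied across regions within metric,
* ANCOVA with type-III sums of squares, effect coding, and partial eta
  squared; repeated-measures designs use univariate subject stratification
  (between-subject effects tested against subject-level error, within-
  subject effects against the residual).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "assign_trimester_group",
    "percent_change",
    "homotopic_growth_ztest",
    "asymmetry_index",
    "lateralization_test",
    "paired_homotopic_test",
    "ai_change_ztest",
    "bh_fdr",
    "ancova",
    "PercentChange",
    "AsymmetryResult",
    "AncovaResult",
]

Z95 = 1.96  # critical Z for 95% confidence intervals


# --------------------------------------------------------------------------
# trimester grouping and percent change

def assign_trimester_group(ga) -> np.ndarray:
    """Map GA (weeks) to 'late2' (22-27 wGA) or 'early3' (>27-32 wGA).

    The boundary scan at exactly 27.0 weeks belongs to the late-2nd group.
    """
    ga = np.asarray(ga, dtype=float)
    if np.any(ga < 22.0) or np.any(ga > 32.0):
        raise ValueError("GA outside the 22-32 week study window")
    out = np.where(ga <= 27.0, "late2", "early3")
    return out if out.ndim else str(out)


@dataclass
class PercentChange:
    region: str
    hemisphere: str
    metric: str
    pc: float
    se: float
    ci95: tuple[float, float]
    group_ns: tuple[int, int]
    defined: bool = True


def percent_change(values_late2, values_early3,
                   region: str = "", hemisphere: str = "",
                   metric: str = "") -> PercentChange:
    """Percent change of group means, with a delta-method standard error.

    pc = 100 * (m2 - m1) / m1 for group means m1 (late 2nd) and m2 (early
    3rd). The SE propagates both group-mean standard errors through the
    ratio:  se_pc^2 = (100/m1)^2 * (se2^2 + se1^2 * (m2/m1)^2).
    The 95% CI is pc +/- 1.96 * se_pc.
    """
    v1 = np.asarray(values_late2, dtype=float)
    v2 = np.asarray(values_early3, dtype=float)
    if v1.size < 3 or v2.size < 3:
        raise ValueError("each group needs at least 3 observations")
    m1, m2 = v1.mean(), v2.mean()
    if m1 <= 0:
        return PercentChange(region, hemisphere, metric, np.nan, np.nan,
                             (np.nan, np.nan), (v1.size, v2.size), defined=False)
    se1 = v1.std(ddof=1) / np.sqrt(v1.size)
    se2 = v2.std(ddof=1) / np.sqrt(v2.size)
    pc = 100.0 * (m2 - m1) / m1
    se = np.sqrt((100.0 / m1) ** 2 * (se2**2 + se1**2 * (m2 / m1) ** 2))
    return PercentChange(region, hemisphere, metric, float(pc), float(se),
                         (float(pc - Z95 * se), float(pc + Z95 * se)),
                         (v1.size, v2.size))


def homotopic_growth_ztest(pc_left: PercentChange,
                           pc_right: PercentChange) -> tuple[float, float]:
    """Z-test of right-vs-left percent-change difference, pooled SEs."""
    if (pc_left.region, pc_left.metric) != (pc_right.region, pc_right.metric):
        raise ValueError("left/right percent changes must match region and metric")
    pooled = np.hypot(pc_left.se, pc_right.se)
    if pooled == 0 or not np.isfinite(pooled):
        raise ValueError("pooled standard error is zero or undefined")
    z = (pc_right.pc - pc_left.pc) / pooled
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


# --------------------------------------------------------------------------
# asymmetry

def asymmetry_index(left, right):
    """AI = (right - left) * 100 / (0.5 * (right + left)); positive = rightward.

    Bounded in [-200, 200] for nonnegative inputs; NaN where R + L <= 0.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    denom = 0.5 * (right + left)
    with np.errstate(divide="ignore", invalid="ignore"):
        ai = np.where(denom > 0, (right - left) * 100.0 / denom, np.nan)
    return ai if ai.ndim else float(ai)


@dataclass
class AsymmetryResult:
    region: str
    metric: str
    group: str | None
    mean_ai: float
    t_stat: float
    p: float
    q: float          # FDR-adjusted across regions within metric
    cohens_d: float
    direction: str    # 'left' | 'right' | 'none'
    degenerate: bool = False


def _one_sample(values: np.ndarray) -> tuple[float, float, float, bool]:
    """t, p, Cohen's d vs zero with a degenerate zero-variance contract."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1)
    mean = values.mean()
    if sd == 0.0:
        # all values identical: evidence is absolute, not statistical
        return (np.inf if mean > 0 else (-np.inf if mean < 0 else 0.0),
                0.0 if mean != 0 else 1.0,
                np.inf if mean > 0 else (-np.inf if mean < 0 else 0.0),
                True)
    t, p = sps.ttest_1samp(values, 0.0)
    return float(t), float(p), float(mean / sd), False


def lateralization_test(ais, region: str = "", metric: str = "",
                        group: str | None = None,
                        alpha: float = 0.05) -> AsymmetryResult:
    """One-sample t-test of per-subject asymmetry indices against zero.

    The q-value is filled in later by :func:`bh_fdr` across the regions of
    one metric (family boundary of the analysis); until then q = p and the
    direction is assessed at the raw p.
    """
    ais = np.asarray(ais, dtype=float)
    ais = ais[np.isfinite(ais)]
    if ais.size < 3:
        raise ValueError("need at least 3 finite AI values")
    t, p, d, degen = _one_sample(ais)
    mean_ai = float(ais.mean())
    direction = "none"
    if p < alpha and mean_ai != 0:
        direction = "right" if mean_ai > 0 else "left"
    return AsymmetryResult(region, metric, group, mean_ai, t, p, p, d,
                           direction, degenerate=degen)


def paired_homotopic_test(left_values, right_values
                          ) -> tuple[float, float, float]:
    """Paired t-test of right-vs-left values; returns (t, p, Cohen's d).

    Cohen's d = mean(R - L) / sd(R - L); identical to a one-sample t-test on
    the paired differences.
    """
    left = np.asarray(left_values, dtype=float)
    right = np.asarray(right_values, dtype=float)
    if left.size != right.size:
        raise ValueError("paired samples must have equal length")
    if left.size < 3:
        raise ValueError("need at least 3 pairs")
    t, p, d, _ = _one_sample(right - left)
    return t, p, d


def ai_change_ztest(ais_late2, ais_early3
                    ) -> tuple[float, float, float]:
    """Z-test on the difference in mean AI between trimester groups.

    delta = mean(early3) - mean(late2); z = delta / sqrt(se1^2 + se2^2) with
    group-mean standard errors pooled in quadrature.
    """
    a1 = np.asarray(ais_late2, dtype=float)
    a2 = np.asarray(ais_early3, dtype=float)
    a1, a2 = a1[np.isfinite(a1)], a2[np.isfinite(a2)]
    if a1.size < 3 or a2.size < 3:
        raise ValueError("each group needs at least 3 finite AI values")
    se1 = a1.std(ddof=1) / np.sqrt(a1.size)
    se2 = a2.std(ddof=1) / np.sqrt(a2.size)
    pooled = np.hypot(se1, se2)
    delta = float(a2.mean() - a1.mean())
    if pooled == 0.0:
        z = np.inf if delta > 0 else (-np.inf if delta < 0 else 0.0)
        p = 0.0 if delta != 0 else 1.0
        return delta, float(z), p
    z = delta / pooled
    return delta, float(z), float(2.0 * sps.norm.sf(abs(z)))


def bh_fdr(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (monotone q-values, rejections at alpha)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, rejected


# --------------------------------------------------------------------------
# ANCOVA

@dataclass
class AncovaResult:
    """Per-effect F, p, and partial eta squared (SS_eff/(SS_eff+SS_err))."""

    table: pd.DataFrame  # index: effect; columns: sum_sq, df, F, p, partial_eta_sq
    stratum: dict[str, str] | None = None  # effect -> 'between'|'within'

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]


def _effect_coded_formula(response: str, covariates, factors, interactions):
    def term(name):
        return f"C({name}, Sum)" if name in factors else name
    parts = [term(c) for c in covariates] + [term(f) for f in factors]
    for inter in interactions:
        parts.append(":".join(term(t) for t in inter))
    return f"{response} ~ " + " + ".join(parts) if parts else f"{response} ~ 1"


def _anova_typ3(formula: str, data: pd.DataFrame) -> pd.DataFrame:
    model = ols(formula, data=data).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("rank-deficient design; aliased effects present")
    aov = anova_lm(model, typ=3)
    aov = aov.drop(index=[i for i in ("Intercept",) if i in aov.index])
    return aov


def _clean_effect_name(name: str) -> str:
    return name.replace("C(", "").replace(", Sum)", "")


def ancova(table: pd.DataFrame, response: str, covariates=(), factors=(),
           interactions=(), subject: str | None = None,
           within=()) -> AncovaResult:
    """General linear model ANCOVA with type-III SS and partial eta squared.

    Between-subject designs (``subject=None``) fit one OLS with effect-coded
    factors; every effect is tested against the residual error.

    Repeated-measures designs name the ``subject`` column and the ``within``
    factors/covariates (e.g. region, hemisphere, depth). Between-subject
    effects (constant within subject) are then tested at the subject level:
    the response is aggregated to subject means and tested against the
    subject-level residual. Within-subject effects are tested in the full
    model with a subject main effect absorbing between-subject variance,
    against the within-subject residual. Rows with missing values in any
    named column are dropped (e.g. unknown sex).
    """
    within = list(within)
    covariates = list(covariates)
    factors = list(factors)
    interactions = [tuple(i) for i in interactions]
    used = set([response] + covariates + factors +
               [t for i in interactions for t in i])
    if subject is not None:
        used.add(subject)
    data = table[list(used)].replace({None: np.nan}).dropna().copy()

    if subject is None:
        formula = _effect_coded_formula(response, covariates, factors, interactions)
        aov = _anova_typ3(formula, data)
        ss_err = float(aov.loc["Residual", "sum_sq"])
        rows = {}
        for name in aov.index:
            if name == "Residual":
                continue
            ss = float(aov.loc[name, "sum_sq"])
            rows[_clean_effect_name(name)] = {
                "sum_sq": ss,
                "df": float(aov.loc[name, "df"]),
                "F": float(aov.loc[name, "F"]),
                "p": float(aov.loc[name, "PR(>F)"]),
                "partial_eta_sq": ss / (ss + ss_err),
            }
        return AncovaResult(pd.DataFrame(rows).T)

    # -------- repeated measures: univariate subject stratification --------
    between_cov = [c for c in covariates if c not in within]
    between_fac = [f for f in factors if f not in within]
    stratum: dict[str, str] = {}
    rows = {}

    # between-subject stratum: aggregate to subject level
    if between_cov or between_fac:
        agg_cols = {response: "mean", **{c: "first" for c in between_cov},
                    **{f: "first" for f in between_fac}}
        subj_df = data.groupby(subject).agg(agg_cols).reset_index()
        b_inter = [i for i in interactions
                   if all(t not in within for t in i)]
        formula = _effect_coded_formula(response, between_cov, between_fac, b_inter)
        aov = _anova_typ3(formula, subj_df)
        ss_err_b = float(aov.loc["Residual", "sum_sq"])
        for name in aov.index:
            if name == "Residual":
                continue
            ss = float(aov.loc[name, "sum_sq"])
            eff = _clean_effect_name(name)
            rows[eff] = {
                "sum_sq": ss, "df": float(aov.loc[name, "df"]),
                "F": float(aov.loc[name, "F"]),
                "p": float(aov.loc[name, "PR(>F)"]),
                "partial_eta_sq": ss / (ss + ss_err_b),
            }
            stratum[eff] = "between"

    # within-subject stratum: full model with a subject main effect.
    # Between-subject covariate mains are included in the formula so patsy
    # gives interactions their reduced (Sum) coding, then dropped from the
    # design (they are aliased with the subject dummies); each within effect
    # is then tested by a type-III column-group refit.
    import patsy

    w_inter = [i for i in interactions if any(t in within for t in i)]
    w_factors = [f for f in factors if f in within]
    w_covs = [c for c in covariates if c in within]
    if w_factors or w_covs or w_inter:
        def term(name):
            return f"C({name}, Sum)" if name in factors else name
        parts = ([term(c) for c in covariates] + [term(f) for f in w_factors]
                 + [":".join(term(t) for t in i) for i in w_inter]
                 + [f"C({subject}, Sum)"])
        formula = f"{response} ~ " + " + ".join(parts)
        yv, X = patsy.dmatrices(formula, data, return_type="dataframe")
        yv = yv.to_numpy().ravel()
        info = X.design_info
        aliased = {term(c) for c in covariates if c not in within}
        keep_terms = [t for t in info.term_names
                      if t != "Intercept" and t not in aliased]
        cols: dict[str, list[int]] = {
            t: list(range(*info.term_name_slices[t].indices(X.shape[1])))
            for t in info.term_names}
        keep_idx = cols["Intercept"] + sum((cols[t] for t in keep_terms), [])
        Xf = X.to_numpy()[:, keep_idx]
        if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
            raise ValueError("rank-deficient within-subject design")

        def rss(mat):
            beta, res, *_ = np.linalg.lstsq(mat, yv, rcond=None)
            fitted = mat @ beta
            return float(np.sum((yv - fitted) ** 2))

        rss_full = rss(Xf)
        df_err = Xf.shape[0] - Xf.shape[1]
        ms_err = rss_full / df_err
        # positions of each kept term inside Xf
        pos = {}
        cursor = len(cols["Intercept"])
        for t in keep_terms:
            pos[t] = list(range(cursor, cursor + len(cols[t])))
            cursor += len(cols[t])
        for t in keep_terms:
            eff = _clean_effect_name(t)
            if eff == subject:
                continue
            reduced = np.delete(Xf, pos[t], axis=1)
            ss = rss(reduced) - rss_full
            df = len(pos[t])
            F = (ss / df) / ms_err
            p = float(sps.f.sf(F, df, df_err))
            rows[eff] = {
                "sum_sq": ss, "df": float(df), "F": float(F), "p": p,
                "partial_eta_sq": ss / (ss + rss_full),
            }
            stratum[eff] = "within"
    return AncovaResult(pd.DataFrame(rows).T, stratum=stratum)
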