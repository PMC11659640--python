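"""Descriptive, reliability and comparison statistics for twin cohorts.

Covers the non-genetic half of a twin analysis: per-stage descriptive tables
with percent change from the primary dentition, intraclass correlation for
within-pair resemblance (and test-retest reliability), duplicate-measurement
error (Dahlberg and mean-corrected method-of-moments estimators), two-sample
comparisons with Bonferroni adjustment, and a family random-intercept linear
mixed model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import TRAIT_NAMES

logger = logging.getLogger(__name__)


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# descriptives


def descriptive_table(cohort: pd.DataFrame, traits: Sequence[str] = TRAIT_NAMES) -> pd.DataFrame:
    """Per-stage, per-trait means and SDs for Overall / M / F / MZ / DZ groups.

    SD uses the n-1 denominator.  Cells with fewer than two values are
    omitted with a log entry.
    """
    rows = []
    for stage, sub in cohort.groupby("stage"):
        groups = {
            "Overall": sub,
            "M": sub[sub["sex"] == "M"],
            "F": sub[sub["sex"] == "F"],
            "MZ": sub[sub["zygosity"] == "MZ"],
            "DZ": sub[sub["zygosity"] == "DZ"],
        }
        for trait in traits:
            if trait not in sub.columns:
                continue
            for gname, g in groups.items():
                vals = g[trait].dropna()
                if len(vals) < 2:
                    logger.warning(
                        "omitting cell (%s, %s, %s): %d value(s)",
                        stage, trait, gname, len(vals),
                    )
                    continue
                rows.append({
                    "stage": stage, "trait": trait, "group": gname,
                    "mean": float(vals.mean()), "sd": float(vals.std(ddof=1)),
                    "n": int(len(vals)),
                })
    return pd.DataFrame(rows)


def percent_change(mean_stage: float, mean_primary: float) -> float:
    """Percent change of a later-stage mean from the primary-dentition mean."""
    if mean_primary <= 0:
        raise StatsError("baseline mean must be positive")
    return round(100.0 * (mean_stage - mean_primary) / mean_primary, 1)


# ---------------------------------------------------------------------------
# intraclass correlation


@dataclass(frozen=True)
class IccResult:
    icc: float
    n_pairs: int
    ms_between: float
    ms_within: float


def icc_oneway(pairs: np.ndarray) -> IccResult:
    """One-way random-effects intraclass correlation for pairs of size two.

    ICC = (MS_between - MS_within) / (MS_between + MS_within); twin labels
    are exchangeable, so the estimate is invariant under within-pair swaps.
    """
    p = np.asarray(pairs, float)
    if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 2:
        raise StatsError("icc_oneway needs an (n>=2, 2) array of pairs")
    n = p.shape[0]
    grand = p.mean()
    pair_means = p.mean(axis=1)
    ms_between = 2.0 * ((pair_means - grand) ** 2).sum() / (n - 1)
    ms_within = ((p[:, 0] - p[:, 1]) ** 2 / 2.0).sum() / n
    total = ms_between + ms_within
    if total <= 0:
        raise StatsError("zero total variance: ICC undefined")
    return IccResult(
        icc=float((ms_between - ms_within) / total),
        n_pairs=n,
        ms_between=float(ms_between),
        ms_within=float(ms_within),
    )


def zygosity_icc(cohort: pd.DataFrame, trait: str, stage: str) -> dict[str, IccResult]:
    """ICC of a trait within MZ and DZ pairs at one stage."""
    out = {}
    sub = cohort[cohort["stage"] == stage]
    for zyg in ("MZ", "DZ"):
        pairs = pairs_from_cohort(sub[sub["zygosity"] == zyg], trait)
        out[zyg] = icc_oneway(pairs)
    return out


def pairs_from_cohort(sub: pd.DataFrame, trait: str) -> np.ndarray:
    """(n_pairs, 2) trait values, one row per family (order arbitrary)."""
    rows = []
    for _, g in sub.groupby("family_id"):
        vals = g[trait].dropna().to_numpy()
        if len(vals) == 2:
            rows.append(vals)
    if not rows:
        return np.empty((0, 2))
    return np.array(rows)


# ---------------------------------------------------------------------------
# duplicate-measurement error


@dataclass(frozen=True)
class MethodErrorResult:
    dahlberg: float
    mme: float
    n_replicated: int
    d_i: np.ndarray


def method_error(session1: np.ndarray, session2: np.ndarray) -> MethodErrorResult:
    """Random error of duplicate measurements.

    With per-item differences d_i = session1_i - session2_i:

    * Dahlberg = sqrt(sum d_i^2 / (2 n))  — includes any systematic offset;
    * MME      = sqrt(sum (d_i - dbar)^2 / (2 (n - 1)))  — mean-corrected
      method-of-moments estimator, excluding the systematic component.

    The two satisfy Dahlberg^2 = MME^2 (n-1)/n + dbar^2 / 2.
    """
    s1 = np.asarray(session1, float)
    s2 = np.asarray(session2, float)
    if s1.shape != s2.shape or s1.ndim != 1:
        raise StatsError("sessions must be equal-length 1-D arrays")
    n = len(s1)
    if n < 2:
        raise StatsError("need at least two replicated measurements")
    d = s1 - s2
    dahlberg = float(np.sqrt((d**2).sum() / (2.0 * n)))
    mme = float(np.sqrt(((d - d.mean()) ** 2).sum() / (2.0 * (n - 1))))
    return MethodErrorResult(dahlberg=dahlberg, mme=mme, n_replicated=n, d_i=d)


# ---------------------------------------------------------------------------
# group comparisons


def two_sample_t(
    x: np.ndarray, y: np.ndarray, welch: bool = True
) -> tuple[float, float]:
    """Two-sample t statistic and two-sided p (Welch by default)."""
    res = stats.ttest_ind(np.asarray(x, float), np.asarray(y, float),
                          equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def group_comparisons(
    cohort: pd.DataFrame,
    comparisons: Mapping[str, tuple[pd.Series, pd.Series]] | None = None,
    traits: Sequence[str] = TRAIT_NAMES,
    alpha: float = 0.05,
    m_tests: int = len(TRAIT_NAMES),
    welch: bool = True,
) -> pd.DataFrame:
    """Two-sample comparisons per stage and trait with Bonferroni decisions.

    Default comparisons: MZ vs DZ and M vs F within each stage.  The adjusted
    threshold is alpha / m_tests.  Twin pairs are clustered by family, which
    these unadjusted t-tests ignore; rows carry a ``clustered`` caveat flag.
    """
    rows = []
    for stage, sub in cohort.groupby("stage"):
        groupings = comparisons or {
            "MZ_vs_DZ": (sub["zygosity"] == "MZ", sub["zygosity"] == "DZ"),
            "M_vs_F": (sub["sex"] == "M", sub["sex"] == "F"),
        }
        for label, (m1, m2) in groupings.items():
            for trait in traits:
                if trait not in sub.columns:
                    continue
                x = sub.loc[m1, trait].dropna()
                y = sub.loc[m2, trait].dropna()
                if len(x) < 2 or len(y) < 2:
                    logger.warning(
                        "skipping degenerate comparison %s (%s, %s)",
                        label, stage, trait,
                    )
                    continue
                t, p = two_sample_t(x, y, welch=welch)
                rows.append({
                    "stage": stage, "trait": trait, "comparison": label,
                    "t": t, "p_raw": p,
                    "alpha_adjusted": alpha / m_tests,
                    "significant_raw": p < alpha,
                    "significant_bonferroni": p < alpha / m_tests,
                    "clustered": True,
                })
    return pd.DataFrame(rows)


def attrition_check(
    cohort: pd.DataFrame,
    earlier_stage: str,
    later_stage: str,
    traits: Sequence[str] = TRAIT_NAMES,
    alpha: float = 0.05,
    m_tests: int = len(TRAIT_NAMES),
    welch: bool = True,
) -> pd.DataFrame:
    """Compare earlier-stage traits of pairs lost to follow-up vs retained."""
    early = cohort[cohort["stage"] == earlier_stage]
    later_fams = set(cohort.loc[cohort["stage"] == later_stage, "family_id"])
    retained = early["family_id"].isin(later_fams)
    comparisons = {"attrited_vs_retained": (~retained, retained)}
    return group_comparisons(
        early, comparisons=comparisons, traits=traits,
        alpha=alpha, m_tests=m_tests, welch=welch,
    )


# ---------------------------------------------------------------------------
# random-intercept mixed model


@dataclass(frozen=True)
class LmmResult:
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    family_variance: float
    residual_variance: float
    converged: bool


def lmm_random_intercept(
    cohort: pd.DataFrame,
    trait: str,
    fixed: Sequence[str] = ("zygosity", "sex", "stage"),
) -> LmmResult:
    """Family random-intercept linear model fitted by maximum likelihood.

    Fixed effects are entered as treatment-coded categoricals; the family ID
    random intercept absorbs the within-pair (and within-family across-stage)
    correlation.
    """
    import statsmodels.formula.api as smf

    data = cohort.dropna(subset=[trait]).copy()
    if data["family_id"].nunique() < 2:
        raise StatsError("need at least two families")
    formula = f"{trait} ~ " + " + ".join(f"C({f})" for f in fixed)
    model = smf.mixedlm(formula, data, groups=data["family_id"])
    fit = None
    errors = []
    # gradient-based fit first; fall back to derivative-free when the family
    # variance sits on the zero boundary and the information matrix degenerates
    for method in ("lbfgs", "powell", "nm"):
        try:
            fit = model.fit(reml=False, method=method)
        except Exception as exc:  # noqa: BLE001
            errors.append(f"{method}: {exc}")
            continue
        if fit.converged:
            break
    if fit is None or not fit.converged:
        raise StatsError(
            "mixed model failed to converge: " + "; ".join(errors or ["no fit"])
        )
    coeffs = {k: float(v) for k, v in fit.fe_params.items()}
    ses = {k: float(fit.bse_fe[k]) for k in fit.fe_params.index}
    return LmmResult(
        coefficients=coeffs,
        std_errors=ses,
        family_variance=float(fit.cov_re.iloc[0, 0]),
        residual_variance=float(fit.scale),
        converged=bool(fit.converged),
    )
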