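"""Pre/post/follow-up statistics for participants x {T0, T1, T2} outcomes.

For each outcome the pipeline follows the classical gated plan:

1. **Normality gate** -- Shapiro-Wilk on each time point; all p > alpha
   routes the outcome to the parametric branch.
2. **Omnibus** -- one-way repeated-measures ANOVA (parametric) or Friedman
   chi-square with mid-rank ties (nonparametric), with eta-squared or
   epsilon-squared effect sizes.
3. **Post hoc** -- paired t tests with Bonferroni adjustment and paired
   Cohen d (Hedges small-sample corrected), or Tukey/Nemenyi-style q tests
   on Friedman mean ranks with Cohen r = |z| / sqrt(n) from the Wilcoxon
   signed-rank normal approximation.

Conventions that are not universal are pinned here and echoed in the
output: epsilon-squared is ``chi2 / (n * (k - 1))`` (the Kendall-W
equivalent); the "adjusted" Cohen d is the Hedges-corrected paired d.
Missing data are handled by listwise deletion per outcome, with the number
of complete cases recorded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import IntegrityError, ParameterError

TIME_POINTS = ("T0", "T1", "T2")
CONTRASTS = (("T0", "T1"), ("T0", "T2"), ("T1", "T2"))


@dataclass
class TestResult:
    """Omnibus test summary."""

    test_name: str  # rm_anova | friedman
    statistic: float
    df: Tuple[float, ...]
    p_value: float
    effect_size_name: str  # eta2 | epsilon2
    effect_size_value: float
    n: int
    note: str = ""


@dataclass
class PairwiseResult:
    """One post-hoc contrast."""

    contrast: str  # e.g. "T0vT1"
    statistic: float
    p_value: float
    adjusted_p: float
    effect_size_name: str  # cohen_d_adjusted | cohen_r
    effect_size_value: float
    effect_size_unadjusted: Optional[float] = None


def _pivot(table: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Complete-case wide matrix (participants x T0/T1/T2) for one outcome."""
    sub = table[table["outcome_name"] == outcome]
    if sub.empty:
        raise IntegrityError(f"no records for outcome {outcome!r}")
    wide = sub.pivot(index="participant_id", columns="time_point", values="value")
    missing_tp = [tp for tp in TIME_POINTS if tp not in wide.columns]
    if missing_tp:
        raise IntegrityError(f"outcome {outcome!r} lacks time points {missing_tp}")
    return wide[list(TIME_POINTS)].dropna()


# --- normality gate --------------------------------------------------------

def normality_gate(wide: pd.DataFrame, alpha: float = 0.05) -> Tuple[str, dict]:
    """Shapiro-Wilk on every time point; parametric iff all p > alpha.

    Degenerate (all-identical) columns route to the nonparametric branch
    with a warning, since the Shapiro statistic is undefined there.
    """
    if len(wide) < 3:
        raise IntegrityError("normality test needs at least 3 complete cases")
    detail: Dict[str, float] = {}
    parametric = True
    for tp in TIME_POINTS:
        col = wide[tp].to_numpy(dtype=float)
        if np.ptp(col) == 0.0:
            warnings.warn(
                f"time point {tp} is constant; routing to nonparametric tests",
                UserWarning,
                stacklevel=2,
            )
            detail[tp] = float("nan")
            parametric = False
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(sps.shapiro(col).pvalue)
        detail[tp] = p
        if p <= alpha:
            parametric = False
    return ("parametric" if parametric else "nonparametric"), {"shapiro_p": detail}


# --- omnibus tests ---------------------------------------------------------

def rm_anova(table: pd.DataFrame, outcome: str) -> TestResult:
    """One-way repeated-measures ANOVA with eta-squared effect size.

    Complete cases only; F has df (k-1, (n-1)(k-1)); eta2 is
    SS_effect / (SS_effect + SS_error).
    """
    import pingouin as pg

    wide = _pivot(table, outcome)
    n, k = wide.shape
    if n < 3:
        raise IntegrityError("repeated-measures ANOVA needs at least 3 complete cases")
    if float(np.ptp(wide.to_numpy(float), axis=1).max()) == 0.0:
        # no within-participant variation at all: F is identically zero
        return TestResult(
            test_name="rm_anova",
            statistic=0.0,
            df=(float(k - 1), float((n - 1) * (k - 1))),
            p_value=1.0,
            effect_size_name="eta2",
            effect_size_value=0.0,
            n=n,
        )
    long = (
        wide.reset_index()
        .melt(id_vars="participant_id", var_name="time_point", value_name="value")
    )
    aov = pg.rm_anova(
        data=long,
        dv="value",
        within="time_point",
        subject="participant_id",
        detailed=True,
    )
    ss_effect = float(aov.loc[0, "SS"])
    ss_error = float(aov.loc[1, "SS"])
    denom = ss_effect + ss_error
    eta2 = ss_effect / denom if denom > 0 else 0.0
    f_stat = float(aov.loc[0, "F"])
    if not np.isfinite(f_stat):  # identical columns: SS_error == SS_effect == 0
        f_stat, p = 0.0, 1.0
    else:
        p = float(aov.loc[0, "p_unc"])
    return TestResult(
        test_name="rm_anova",
        statistic=f_stat,
        df=(float(aov.loc[0, "DF"]), float(aov.loc[1, "DF"])),
        p_value=p,
        effect_size_name="eta2",
        effect_size_value=eta2,
        n=n,
    )


def friedman(table: pd.DataFrame, outcome: str) -> TestResult:
    """Friedman chi-square (mid-rank ties) with epsilon-squared effect size.

    epsilon2 = chi2 / (n * (k - 1)), the Kendall-W-equivalent convention;
    the choice is recorded in the result note.
    """
    wide = _pivot(table, outcome)
    n, k = wide.shape
    if n < 3:
        raise IntegrityError("Friedman test needs at least 3 complete cases")
    cols = [wide[tp].to_numpy(dtype=float) for tp in TIME_POINTS]
    if float(np.ptp(np.vstack(cols), axis=0).max()) == 0.0:
        chi2, p = 0.0, 1.0  # every participant fully tied across time points
    else:
        try:
            res = sps.friedmanchisquare(*cols)
            chi2, p = float(res.statistic), float(res.pvalue)
        except ValueError:  # fully tied data
            chi2, p = 0.0, 1.0
    if not np.isfinite(chi2):
        chi2, p = 0.0, 1.0
    eps2 = chi2 / (n * (k - 1))
    return TestResult(
        test_name="friedman",
        statistic=chi2,
        df=(float(k - 1),),
        p_value=p,
        effect_size_name="epsilon2",
        effect_size_value=eps2,
        n=n,
        note="epsilon2 = chi2 / (n * (k - 1)) (Kendall-W equivalent)",
    )


# --- post hoc --------------------------------------------------------------

def paired_cohen_d(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Paired Cohen d (mean diff / SD of diffs) and its Hedges correction."""
    diff = np.asarray(x, float) - np.asarray(y, float)
    n = diff.size
    sd = diff.std(ddof=1)
    if sd == 0.0:
        return 0.0, 0.0
    d = diff.mean() / sd
    j = 1.0 - 3.0 / (4.0 * (n - 1) - 1.0)
    return d, j * d


def _wilcoxon_z(x: np.ndarray, y: np.ndarray) -> float:
    """Signed z from the Wilcoxon signed-rank normal approximation."""
    diff = np.asarray(x, float) - np.asarray(y, float)
    if np.all(diff == 0):
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.wilcoxon(diff, method="approx", correction=False)
    z = abs(float(sps.norm.isf(res.pvalue / 2.0)))
    return math.copysign(z, np.median(diff) if np.median(diff) != 0 else diff.mean())


def posthoc(
    table: pd.DataFrame, outcome: str, route: str, alpha: float = 0.05
) -> List[PairwiseResult]:
    """All pairwise T0/T1/T2 comparisons for one outcome.

    Parametric route: paired t per contrast, Bonferroni-adjusted p
    (min(1, 3p)) and Hedges-corrected paired Cohen d.  Nonparametric route:
    Nemenyi/Tukey-style q on Friedman mean ranks with the studentized-range
    adjusted p, and Cohen r = |z| / sqrt(n) from the Wilcoxon signed-rank z.
    """
    if route not in ("parametric", "nonparametric"):
        raise ParameterError(f"unknown route {route!r}")
    wide = _pivot(table, outcome)
    n, k = wide.shape
    if n < 3:
        raise IntegrityError("post-hoc tests need at least 3 complete cases")
    results: List[PairwiseResult] = []
    if route == "parametric":
        m = len(CONTRASTS)
        for a, b in CONTRASTS:
            x, y = wide[b].to_numpy(float), wide[a].to_numpy(float)
            diff = x - y
            if diff.std(ddof=1) == 0.0:
                t_stat, p = 0.0, 1.0
            else:
                res = sps.ttest_rel(x, y)
                t_stat, p = float(res.statistic), float(res.pvalue)
            d, g = paired_cohen_d(x, y)
            results.append(
                PairwiseResult(
                    contrast=f"{a}v{b}",
                    statistic=t_stat,
                    p_value=p,
                    adjusted_p=min(1.0, m * p),
                    effect_size_name="cohen_d_adjusted",
                    effect_size_value=g,
                    effect_size_unadjusted=d,
                )
            )
        return results
    # nonparametric: Friedman mean ranks, q against the studentized range
    ranks = wide.rank(axis=1, method="average")
    mean_ranks = ranks.mean(axis=0)
    se = math.sqrt(k * (k + 1) / (6.0 * n))
    for a, b in CONTRASTS:
        q = abs(float(mean_ranks[b] - mean_ranks[a])) / se
        p_adj = float(sps.studentized_range.sf(q * math.sqrt(2.0), k, np.inf))
        p_adj = float(np.clip(p_adj, 0.0, 1.0))
        z = _wilcoxon_z(wide[b].to_numpy(float), wide[a].to_numpy(float))
        results.append(
            PairwiseResult(
                contrast=f"{a}v{b}",
                statistic=q,
                p_value=p_adj,
                adjusted_p=p_adj,
                effect_size_name="cohen_r",
                effect_size_value=abs(z) / math.sqrt(n),
            )
        )
    return results


# --- full study pipeline ----------------------------------------------------

def run_study_analysis(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Gate -> omnibus -> post hoc for every outcome in a long table.

    Returns a machine-readable report keyed by outcome; a failure in one
    outcome is recorded as its ``error`` entry and does not abort the rest.
    """
    if table is None or len(table) == 0:
        raise IntegrityError("empty outcome table")
    required = {"participant_id", "time_point", "outcome_name", "value"}
    if not required.issubset(table.columns):
        raise IntegrityError(f"outcome table needs columns {sorted(required)}")
    report: Dict[str, dict] = {}
    for outcome in sorted(table["outcome_name"].unique()):
        try:
            wide = _pivot(table, outcome)
            n_total = table[table["outcome_name"] == outcome][
                "participant_id"
            ].nunique()
            route, gate_detail = normality_gate(wide, alpha=alpha)
            omni = (
                rm_anova(table, outcome)
                if route == "parametric"
                else friedman(table, outcome)
            )
            significant = omni.p_value < alpha
            pairs = posthoc(table, outcome, route, alpha=alpha) if significant else []
            report[outcome] = {
                "route": route,
                "gate": gate_detail,
                "n_complete": int(len(wide)),
                "n_dropped": int(n_total - len(wide)),
                "omnibus": {
                    "test": omni.test_name,
                    "statistic": omni.statistic,
                    "df": list(omni.df),
                    "p_value": omni.p_value,
                    "effect_size_name": omni.effect_size_name,
                    "effect_size_value": omni.effect_size_value,
                    "note": omni.note,
                },
                "significant": bool(significant),
                "posthoc": [
                    {
                        "contrast": pr.contrast,
                        "statistic": pr.statistic,
                        "p_value": pr.p_value,
                        "adjusted_p": pr.adjusted_p,
                        "effect_size_name": pr.effect_size_name,
                        "effect_size_value": pr.effect_size_value,
                        "effect_size_unadjusted": pr.effect_size_unadjusted,
                    }
                    for pr in pairs
                ],
            }
        except Exception as exc:  # per-outcome isolation
            report[outcome] = {"error": f"{type(exc).__name__}: {exc}"}
    report["alpha"] = alpha
    return report
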