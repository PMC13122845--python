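"""Cohort assembly and statistics.

Per subject the physiological compliance is ``C_physio = dV_ART / dP_CC`` and
the infusion-derived parameter is ``C_INF = dV_INF / dP_INF``.  Cohort means
of these ratios are always means of per-subject ratios, never ratios of
cohort means.

Paired outcomes (duration, volume change, pressure change, compliance) are
compared with a normality-gated test — Shapiro–Wilk on the paired
differences decides between the paired t-test and the Wilcoxon signed-rank
test — and the family of comparisons run together is Holm-adjusted.
Associations are summarized with tie-corrected Spearman rank correlations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


def c_physio(delta_v_art_ml: float, delta_p_cc_mmHg: float) -> float:
    """Arterial-related physiological compliance, mL/mmHg."""
    if delta_p_cc_mmHg <= 0:
        raise ValueError("delta_p_cc must be positive")
    if delta_v_art_ml < 0:
        raise ValueError("delta_v_art must be non-negative")
    return delta_v_art_ml / delta_p_cc_mmHg


def cv_percent(values) -> float:
    """Coefficient of variation: 100 * SD / mean (SD with n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    mean = np.mean(x)
    if mean == 0:
        raise ValueError("CV%% undefined for zero mean")
    sd = np.std(x, ddof=1) if len(x) > 1 else 0.0
    return float(100.0 * sd / mean)


@dataclass
class StatResult:
    label: str
    test_used: str            # {"paired-t", "wilcoxon"}
    statistic: float
    p_raw: float
    normality_p: float        # Shapiro-Wilk on the differences (nan if degenerate)
    n: int
    p_holm: float = field(default=np.nan)


def paired_compare(x, y, alpha: float = 0.05, label: str = "") -> StatResult:
    """Normality-gated paired comparison (two-sided).

    Shapiro–Wilk on the differences: p >= alpha -> paired t-test, otherwise
    Wilcoxon signed-rank (zero differences dropped; normal approximation with
    continuity correction beyond n = 25; all-zero differences -> p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"paired samples differ in length ({len(x)} vs {len(y)})")
    if len(x) < 5:
        raise ValueError("need at least 5 pairs")
    d = x - y
    if np.all(d == 0):
        return StatResult(label, "wilcoxon", 0.0, 1.0, np.nan, len(x))
    if np.ptp(d) == 0:
        # constant nonzero differences: normality test undefined, all signs equal
        normality_p = np.nan
        use_t = False
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normality_p = float(stats.shapiro(d).pvalue)
        use_t = normality_p >= alpha
    if use_t:
        res = stats.ttest_rel(x, y)
        return StatResult(label, "paired-t", float(res.statistic), float(res.pvalue),
                          normality_p, len(x))
    nonzero = np.count_nonzero(d)
    method = "approx" if nonzero > 25 else "exact"
    res = stats.wilcoxon(d[d != 0], zero_method="wilcox", correction=(method == "approx"),
                         method=method, alternative="two-sided")
    return StatResult(label, "wilcoxon", float(res.statistic), float(res.pvalue),
                      normality_p, len(x))


def holm_adjust(p_values) -> np.ndarray:
    """Step-down Holm adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="holm")[1]


@dataclass
class CorrelationMatrix:
    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    flagged: pd.DataFrame     # True where R is undefined (constant input / too few pairs)


CORRELATION_VARIABLES = [
    "c_physio_ml_per_mmHg", "c_inf_ml_per_mmHg", "delta_v_art_ml",
    "rout_mmHg_per_ml_per_min", "icp_b_mmHg", "icp_p_mmHg",
    "hr_mri_bpm", "hr_inf_bpm",
]


def spearman_matrix(table: pd.DataFrame, variables: list[str] | None = None,
                    min_pairs: int = 5) -> CorrelationMatrix:
    """Pairwise-complete, tie-corrected Spearman correlation matrix."""
    variables = variables or [v for v in CORRELATION_VARIABLES if v in table.columns]
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    flagged = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            xi = table[variables[i]].to_numpy(dtype=float)
            xj = table[variables[j]].to_numpy(dtype=float)
            mask = np.isfinite(xi) & np.isfinite(xj)
            if mask.sum() < min_pairs or np.ptp(xi[mask]) == 0 or np.ptp(xj[mask]) == 0:
                log.warning("Spearman undefined for (%s, %s); flagged", variables[i], variables[j])
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                flagged[i, j] = flagged[j, i] = True
                continue
            res = stats.spearmanr(xi[mask], xj[mask])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    as_df = lambda a: pd.DataFrame(a, index=variables, columns=variables)  # noqa: E731
    return CorrelationMatrix(variables, as_df(r), as_df(p), as_df(flagged))


def cohort_summary(table: pd.DataFrame, variables: list[str] | None = None) -> pd.DataFrame:
    """Per-variable mean, SD, Q1, Q3 (linear-interpolation quantiles) and CV%."""
    if len(table) == 0:
        raise ValueError("empty cohort table")
    variables = variables or [c for c in table.columns
                              if np.issubdtype(table[c].dtype, np.number)]
    rows = []
    for v in variables:
        x = table[v].dropna().to_numpy(dtype=float)
        if len(x) == 1:
            log.warning("variable %s has a single value; SD reported as 0", v)
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        mean = float(np.mean(x))
        rows.append({
            "variable": v, "n": len(x), "mean": mean, "sd": sd,
            "q1": float(np.quantile(x, 0.25)), "q3": float(np.quantile(x, 0.75)),
            "cv_percent": 100.0 * sd / mean if mean != 0 else np.nan,
        })
    return pd.DataFrame(rows)


# The paired outcome family compared in one cohort run (Holm family):
# measurement duration, volume change, pressure change, compliance —
# infusion condition vs. single-cardiac-cycle condition.  Values are compared
# on their native reporting scales (minutes vs. seconds for duration).
OUTCOME_FAMILY = [
    ("duration (infusion min vs cardiac s)", "delta_t_inf_min", "cardiac_period_s"),
    ("volume change (dV_INF vs dV_ART)", "delta_v_inf_ml", "delta_v_art_ml"),
    ("pressure change (dP_INF vs dP_CC)", "delta_p_inf_mmHg", "delta_p_cc_mmHg"),
    ("compliance (C_INF vs C_physio)", "c_inf_ml_per_mmHg", "c_physio_ml_per_mmHg"),
]


def run_outcome_comparisons(table: pd.DataFrame, alpha: float = 0.05) -> list[StatResult]:
    """Run the paired outcome family and Holm-adjust it as one family."""
    work = table.copy()
    work["delta_t_inf_min"] = work["delta_t_inf_s"] / 60.0
    results = [paired_compare(work[a], work[b], alpha=alpha, label=label)
               for label, a, b in OUTCOME_FAMILY]
    log.info("Holm family: %s", [r.label for r in results])
    adjusted = holm_adjust([r.p_raw for r in results])
    for res, ph in zip(results, adjusted):
        res.p_holm = float(ph)
    return results


def compare_heart_rates(table: pd.DataFrame, alpha: float = 0.05) -> StatResult:
    """Paired comparison of MRI vs infusion heart rates (reported separately)."""
    res = paired_compare(table["hr_mri_bpm"], table["hr_inf_bpm"], alpha=alpha,
                         label="heart rate (MRI vs infusion)")
    res.p_holm = res.p_raw
    return res


def stats_to_frame(results: list[StatResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "comparison": r.label, "test": r.test_used, "statistic": r.statistic,
        "p_raw": r.p_raw, "p_holm": r.p_holm, "normality_p": r.normality_p, "n": r.n,
    } for r in results])
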