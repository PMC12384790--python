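"""Group statistics for repeated-measures metric tables.

The layer that turns per-subject metric values under several conditions
into group results: normality / homogeneity checks (Lilliefors-corrected
Kolmogorov-Smirnov, Levene), classical one-way repeated-measures ANOVA,
Benjamini-Hochberg FDR correction across metrics, Scheffe post hoc
contrasts on the repeated-measures error term, Cohen's d effect sizes
with conventional bands, Pearson correlation with behaviour, and a
noncentral-F power computation for the minimum subject count of a
within-subjects design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SubjectConditionTable",
    "AnovaResult",
    "PowerSpec",
    "check_assumptions",
    "rm_anova_oneway",
    "fdr_bh",
    "scheffe_posthoc",
    "cohens_d",
    "effect_band",
    "correlate_behavior",
    "correlation_band",
    "rm_anova_sample_size",
]


@dataclass
class SubjectConditionTable:
    """One metric's values for every subject under every condition."""

    values: np.ndarray  # (n_subjects, n_conditions)
    condition_names: list[str]
    subject_ids: list | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        s, c = self.values.shape
        if c < 2:
            raise ValueError("need at least 2 conditions")
        if s < 2:
            raise ValueError("repeated-measures analysis needs at least 2 subjects")
        if len(self.condition_names) != c:
            raise ValueError("condition name count mismatch")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("table has missing or non-finite cells")
        if self.subject_ids is None:
            self.subject_ids = list(range(s))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]


@dataclass
class AnovaResult:
    F: float
    df: tuple[float, float]
    p: float
    ms_error: float

    # filled by the pipeline when several metrics are corrected together
    p_fdr: float | None = None


def check_assumptions(table: SubjectConditionTable, alpha: float = 0.05) -> dict:
    """Normality (Lilliefors KS) per condition and Levene across conditions.

    Advisory only: failures are reported, not raised, since the ANOVA is
    run regardless and the caller decides how to react.
    """
    report: dict = {"normality": {}, "alpha": alpha}
    for j, name in enumerate(table.condition_names):
        stat, p = lilliefors(table.values[:, j], dist="norm")
        report["normality"][name] = {"ks_stat": float(stat), "p": float(p), "normal": p > alpha}
    w, p = sstats.levene(*[table.values[:, j] for j in range(table.n_conditions)])
    report["homogeneity"] = {"levene_stat": float(w), "p": float(p), "homogeneous": p > alpha}
    if not all(v["normal"] for v in report["normality"].values()):
        warnings.warn("normality check failed for at least one condition (advisory)")
    if not report["homogeneity"]["homogeneous"]:
        warnings.warn("variance homogeneity check failed (advisory)")
    return report


def rm_anova_oneway(table: SubjectConditionTable) -> AnovaResult:
    """Classical one-way within-subjects ANOVA.

    F = MS_condition / MS_(condition x subject), df = (c-1, (c-1)(s-1)).
    """
    y = table.values
    s, c = y.shape
    grand = y.mean()
    subj_means = y.mean(axis=1)
    cond_means = y.mean(axis=0)
    ss_cond = s * np.sum((cond_means - grand) ** 2)
    ss_subj = c * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1 = c - 1
    df2 = (c - 1) * (s - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err <= 0:
        # degenerate (perfectly additive) data: no residual variance
        F = np.inf if ms_cond > 0 else 0.0
        p = 0.0 if ms_cond > 0 else 1.0
    else:
        F = ms_cond / ms_err
        p = float(sstats.f.sf(F, df1, df2))
    return AnovaResult(F=float(F), df=(df1, df2), p=p, ms_error=float(ms_err))


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("expected a non-empty 1-D array of p-values")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def scheffe_posthoc(
    table: SubjectConditionTable,
    ms_error: float | None = None,
    df_error: float | None = None,
    alpha: float = 0.05,
) -> list[dict]:
    """Scheffe contrasts for every condition pair.

    Uses the repeated-measures error mean square (condition x subject
    interaction) from the omnibus ANOVA.  The pair statistic
    F = (mean_a - mean_b)^2 / (2 MS_err / s) is referred to
    (c-1) F_{c-1, df_err}, which protects all linear contrasts.
    A direction string "A > B" is attached when the pair is significant.
    """
    if ms_error is None or df_error is None:
        res = rm_anova_oneway(table)
        ms_error, df_error = res.ms_error, res.df[1]
    s, c = table.values.shape
    means = table.values.mean(axis=0)
    out = []
    for a in range(c):
        for b in range(a + 1, c):
            diff = means[a] - means[b]
            if ms_error <= 0:
                p = 1.0 if diff == 0 else 0.0
            else:
                F_pair = diff**2 / (2 * ms_error / s)
                p = float(sstats.f.sf(F_pair / (c - 1), c - 1, df_error))
            name_a, name_b = table.condition_names[a], table.condition_names[b]
            direction = None
            if p < alpha and diff != 0:
                hi, lo = (name_a, name_b) if diff > 0 else (name_b, name_a)
                direction = f"{hi} > {lo}"
            out.append({"pair": (name_a, name_b), "p": p, "diff": float(diff),
                        "direction": direction})
    return out


def cohens_d(x, y) -> float:
    """Cohen's d with the pooled (n-1 weighted) standard deviation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per sample")
    nx, ny = x.size, y.size
    pooled = np.sqrt(
        ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    )
    if pooled == 0:
        raise ValueError("pooled standard deviation is zero; d undefined")
    return float((x.mean() - y.mean()) / pooled)


def effect_band(d: float) -> str:
    """Conventional |d| bands: <0.2 small, 0.2-0.8 moderate, >0.8 large."""
    a = abs(d)
    if a < 0.2:
        return "small"
    if a < 0.8:
        return "moderate"
    return "large"


def correlation_band(r: float) -> str:
    """Conventional |r| bands: <0.3 low, 0.3-0.6 moderate, >0.6 strong."""
    a = abs(r)
    if a < 0.3:
        return "low"
    if a < 0.6:
        return "moderate"
    return "strong"


def correlate_behavior(metric_values, behavior_values) -> dict:
    """Pearson correlation between a metric and a behavioural score."""
    x = np.asarray(metric_values, dtype=float)
    y = np.asarray(behavior_values, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = sstats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "band": correlation_band(r)}


@dataclass
class PowerSpec:
    """Inputs of the within-subjects F-test power computation."""

    effect_size_f: float = 0.25
    alpha: float = 0.05
    target_power: float = 0.8
    n_groups: int = 1
    n_measurements: int = 3
    corr_rep: float = 0.5
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if self.effect_size_f <= 0:
            raise ValueError("effect size f must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target power must be in (0, 1)")
        if not 0 < self.epsilon <= 1:
            raise ValueError("epsilon must be in (0, 1]")
        if not -1 < self.corr_rep < 1:
            raise ValueError("corr among repeated measures must be in (-1, 1)")


def rm_anova_sample_size(spec: PowerSpec, n_cap: int = 10**6) -> int:
    """Smallest n reaching the target power of the within-subjects F test.

    Noncentrality lambda = n m f^2 / (1 - rho) with numerator df
    (m-1) eps and denominator df (n-1)(m-1) eps; power is evaluated on
    the noncentral F distribution at the central-F critical value.
    """
    f2 = spec.effect_size_f**2
    m = spec.n_measurements
    eps = spec.epsilon
    n = 2
    while n <= n_cap:
        lam = n * m * f2 / (1 - spec.corr_rep)
        df1 = (m - 1) * eps
        df2 = (n - 1) * (m - 1) * eps
        crit = sstats.f.isf(spec.alpha, df1, df2)
        power = float(sstats.ncf.sf(crit, df1, df2, lam))
        if power >= spec.target_power:
            return n
        n += 1
    raise RuntimeError(f"required sample size exceeds cap {n_cap}")


def metric_family_anova(
    tables: dict[str, SubjectConditionTable], alpha: float = 0.05
) -> pd.DataFrame:
    """Omnibus RM-ANOVA per metric with BH-FDR across the metric family.

    Returns a tidy frame with one row per metric: F, df, raw and adjusted
    p, and the per-pair Scheffe summary for significant metrics (the
    Scheffe p-values themselves are left uncorrected).
    """
    names = list(tables)
    results = {name: rm_anova_oneway(tables[name]) for name in names}
    p_adj = fdr_bh([results[n].p for n in names])
    rows = []
    for name, padj in zip(names, p_adj):
        res = results[name]
        res.p_fdr = float(padj)
        posthoc = None
        if padj < alpha:
            pairs = scheffe_posthoc(tables[name], res.ms_error, res.df[1], alpha=alpha)
            posthoc = "; ".join(p["direction"] for p in pairs if p["direction"]) or None
        rows.append(
            {"metric": name, "F": res.F, "df1": res.df[0], "df2": res.df[1],
             "p": res.p, "p_fdr": res.p_fdr, "posthoc": posthoc}
        )
    return pd.DataFrame(rows)
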