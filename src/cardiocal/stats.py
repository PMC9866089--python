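"""Group statistics matching the study's reporting conventions.

Normality-gated two-group comparison (Lilliefors-corrected KS gate, then
t-test or Mann-Whitney), two-way ANOVA for the organ-culture beating time
courses, two-sided Grubbs outlier screening, and the comparative (ΔΔCt)
qPCR fold change.  All summaries are mean ± SEM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "GroupComparison",
    "DdctResult",
    "normality_gated_test",
    "organ_culture_anova",
    "grubbs_outlier",
    "ddct_fold_change",
]


@dataclass(frozen=True)
class GroupComparison:
    """Result of a gated two-group comparison."""

    labels: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    sems: tuple[float, float]
    test: str  # "t", "paired t", or "Mann-Whitney"
    statistic: float
    p: float
    normal: tuple[bool, bool]  # per-group normality-gate outcome


@dataclass(frozen=True)
class DdctResult:
    """Comparative qPCR quantities for one target gene."""

    gene: str
    dct_control: float
    dct_treatment: float
    ddct: float
    fold_change: float

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold change must be positive")


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    """Normality gate: Lilliefors-corrected Kolmogorov-Smirnov test.

    The plain KS test with parameters estimated from the sample is
    anti-conservative; the Lilliefors correction accounts for the
    estimation.  Constant samples are trivially non-normal here.
    """
    if np.std(x) == 0:
        return False
    from statsmodels.stats.diagnostic import lilliefors

    _, p = lilliefors(x, dist="norm")
    return bool(p > alpha)


def normality_gated_test(
    group_a,
    group_b,
    *,
    labels: tuple[str, str] = ("a", "b"),
    paired: bool = False,
    alpha_normality: float = 0.05,
) -> GroupComparison:
    """Two-group comparison with a normality gate.

    Both groups normal (Lilliefors KS, alpha 0.05) → (paired) t-test;
    otherwise Mann-Whitney rank-sum (Wilcoxon signed-rank when paired).
    Means ± SEM are reported regardless of the test chosen.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs n >= 3")
    if paired and a.size != b.size:
        raise ValueError("paired groups must have equal n")
    normal = (_is_normal(a, alpha_normality), _is_normal(b, alpha_normality))
    if all(normal):
        if paired:
            stat, p = _stats.ttest_rel(a, b)
            test = "paired t"
        else:
            stat, p = _stats.ttest_ind(a, b)
            test = "t"
    else:
        if paired:
            if np.all(a == b):
                stat, p = 0.0, 1.0
            else:
                stat, p = _stats.wilcoxon(a, b)
            test = "Wilcoxon signed-rank"
        else:
            stat, p = _stats.mannwhitneyu(a, b, alternative="two-sided")
            test = "Mann-Whitney"
    return GroupComparison(
        labels=labels,
        n=(a.size, b.size),
        means=(float(a.mean()), float(b.mean())),
        sems=(_sem(a), _sem(b)),
        test=test,
        statistic=float(stat),
        p=float(p),
        normal=normal,
    )


def organ_culture_anova(table: pd.DataFrame) -> pd.DataFrame:
    """Two-way ANOVA of a beating-frequency time course.

    ``table`` needs columns ``group`` (genotype or treatment), ``time`` and
    ``bpm``.  Type-II sums of squares handle the unbalanced designs of
    explant experiments.  Returns the statsmodels ANOVA table with factor
    and interaction F and p values.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for col in ("group", "time", "bpm"):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    for factor in ("group", "time"):
        if table[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} has a single level")
    model = smf.ols("bpm ~ C(group) * C(time)", data=table).fit()
    return sm.stats.anova_lm(model, typ=2)


def grubbs_outlier(sample, *, alpha: float = 0.05) -> tuple[bool, int | None, float, float]:
    """Two-sided Grubbs test for a single outlier.

    Returns ``(is_outlier, index, G, G_critical)`` where G =
    max|x - mean| / sd.  Requires n >= 3 and non-constant data (the
    statistic is undefined at sd = 0).
    """
    x = np.asarray(sample, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample: Grubbs statistic undefined")
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = float(dev[idx] / sd)
    t = _stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    g_crit = float((n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2)))
    return g > g_crit, (idx if g > g_crit else None), g, g_crit


def ddct_fold_change(
    ct: pd.DataFrame,
    *,
    reference_gene: str,
    control_group: str,
    gene_col: str = "gene",
    group_col: str = "group",
    ct_col: str = "ct",
) -> list[DdctResult]:
    """Comparative real-time PCR fold changes, fold = 2^(−ΔΔCt).

    ``ct`` holds one Ct value per row with gene, group and ct columns.
    ΔCt = mean Ct(target) − mean Ct(reference) per group; ΔΔCt subtracts the
    control group's ΔCt; the reference gene must be present in every group.
    """
    groups = list(ct[group_col].unique())
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} absent")
    for grp in groups:
        sub = ct[ct[group_col] == grp]
        if reference_gene not in set(sub[gene_col]):
            raise ValueError(f"reference gene {reference_gene!r} missing in group {grp!r}")

    def dct(grp: str, gene: str) -> float:
        sub = ct[ct[group_col] == grp]
        return float(
            sub[sub[gene_col] == gene][ct_col].mean()
            - sub[sub[gene_col] == reference_gene][ct_col].mean()
        )

    results = []
    targets = [g for g in ct[gene_col].unique() if g != reference_gene]
    treatments = [g for g in groups if g != control_group]
    for gene in targets:
        for grp in treatments:
            d_ctl = dct(control_group, gene)
            d_trt = dct(grp, gene)
            ddct = d_trt - d_ctl
            results.append(
                DdctResult(
                    gene=gene,
                    dct_control=d_ctl,
                    dct_treatment=d_trt,
                    ddct=ddct,
                    fold_change=float(2.0 ** (-ddct)),
                )
            )
    return results
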