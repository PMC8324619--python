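"""Statistical comparison layer for repeated-measures protocol studies.

The study design is a complete block design: every VOI (block) is measured
under every reconstruction protocol (treatment).  Distributional checks use
Shapiro-Wilk (normality per group) and Levene (variance homogeneity across
groups); nonparametric dependent comparisons use the Friedman test (>= 3
treatments) or the exact Wilcoxon signed-rank test (2 treatments); and
parametric comparisons against a reference protocol use paired t contrasts
with Bonferroni-Holm step-down correction.  All tests are two-sided with
significance at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05

#: Exact signed-rank distribution is used up to this many blocks.
WILCOXON_EXACT_MAX_N = 25


@dataclass
class MetricPanel:
    """Complete block x treatment matrix of one metric."""

    values: pd.DataFrame  # index = blocks (VOIs), columns = treatments

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValueError("panel must be complete (no missing cells)")
        if self.values.shape[1] < 2:
            raise ValueError("panel needs at least two treatments")

    @classmethod
    def from_arrays(cls, blocks, treatments, matrix) -> "MetricPanel":
        return cls(pd.DataFrame(np.asarray(matrix, float), index=list(blocks), columns=list(treatments)))

    @property
    def treatments(self):
        return list(self.values.columns)

    @property
    def blocks(self):
        return list(self.values.index)


@dataclass
class GroupCheck:
    group: object
    shapiro_p: float | None
    non_normal: bool
    degenerate: bool


def distribution_checks(panel: MetricPanel, alpha: float = ALPHA):
    """Shapiro-Wilk per treatment group plus a Levene test across groups.

    Degenerate (constant) groups are flagged rather than crashed: their
    normality is undefined and they are excluded from the Levene test.
    """
    checks: list[GroupCheck] = []
    valid_groups = []
    for col in panel.treatments:
        v = panel.values[col].to_numpy(float)
        if np.ptp(v) == 0.0 or len(v) < 3:
            checks.append(GroupCheck(col, None, False, True))
            continue
        w, p = sps.shapiro(v)
        checks.append(GroupCheck(col, float(p), p < alpha, False))
        valid_groups.append(v)
    levene_p = None
    if len(valid_groups) >= 2:
        levene_p = float(sps.levene(*valid_groups).pvalue)
    return {"groups": checks, "levene_p": levene_p}


@dataclass
class DependentTestResult:
    test: str
    statistic: float
    pvalue: float


def compare_dependent(panel: MetricPanel) -> DependentTestResult:
    """Omnibus dependent-samples comparison across treatments.

    Friedman chi-square for three or more treatments; exact two-sided
    Wilcoxon signed-rank for exactly two.
    """
    cols = [panel.values[c].to_numpy(float) for c in panel.treatments]
    if len(cols) == 2:
        d = cols[0] - cols[1]
        if np.all(d == 0):
            return DependentTestResult("wilcoxon", 0.0, 1.0)
        method = "exact" if len(d) <= WILCOXON_EXACT_MAX_N else "approx"
        res = sps.wilcoxon(cols[0], cols[1], alternative="two-sided", method=method)
        return DependentTestResult("wilcoxon", float(res.statistic), float(res.pvalue))
    if np.ptp(np.vstack(cols), axis=0).max() == 0:
        # no within-block rank variation: statistic 0 by definition
        return DependentTestResult("friedman", 0.0, 1.0)
    res = sps.friedmanchisquare(*cols)
    return DependentTestResult("friedman", float(res.statistic), float(res.pvalue))


def holm_adjust(pvalues) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values (order-preserving)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def anova_posthoc(panel: MetricPanel, reference, alpha: float = ALPHA) -> pd.DataFrame:
    """Paired contrasts of every treatment against a reference protocol.

    Within the repeated-measures frame, each non-reference treatment is
    compared with the reference by a two-sided paired t test across blocks;
    p-values are Holm-adjusted over the contrast family.  Returns a table
    with the mean delta, raw and adjusted p and a significance flag.
    """
    if reference not in panel.values.columns:
        raise KeyError(f"reference treatment {reference!r} not in panel")
    ref = panel.values[reference].to_numpy(float)
    rows = []
    raw_ps = []
    for col in panel.treatments:
        v = panel.values[col].to_numpy(float)
        d = v - ref
        if np.all(d == 0):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = sps.ttest_rel(v, ref)
            t_stat, p = float(t_stat), float(p)
        rows.append({"treatment": col, "delta": float(d.mean()), "t": t_stat, "p_raw": p})
        raw_ps.append(p)
    # Holm over the non-reference contrasts only; the self-contrast stays 1.
    mask = [r["treatment"] != reference for r in rows]
    adj = np.ones(len(rows))
    if any(mask):
        adj[np.array(mask)] = holm_adjust([p for p, m in zip(raw_ps, mask) if m])
    table = pd.DataFrame(rows)
    table["p_holm"] = adj
    table["significant"] = table["p_holm"] < alpha
    return table.set_index("treatment")
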