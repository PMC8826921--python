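"""Per-analyte group comparison: Wilcoxon rank-sum, BH-FDR, log2 fold change
of medians, Cliff's delta with Romano magnitude labels.

The profile routine runs all four statistics for every analyte of a
concentration table within one sex stratum, adjusting p-values across the
full analyte family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import ConcentrationTable

#: Romano thresholds on |delta|
CLIFFS_NEGLIGIBLE = 0.147
CLIFFS_SMALL = 0.33
CLIFFS_MEDIUM = 0.474


class FoldChangeError(ValueError):
    pass


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum p-value.

    Exact enumeration when the combined sample is small (n_a + n_b <= 20)
    and tie-free; otherwise the normal approximation with tie and continuity
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= 20 and tie_free) else "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True).pvalue
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_fold_change(case, control) -> float:
    """log2(median(case) / median(control)); case is the patient group, so a
    negative value means the analyte is higher in controls."""
    mc = float(np.median(np.asarray(case, dtype=float)))
    mk = float(np.median(np.asarray(control, dtype=float)))
    if mc <= 0 or mk <= 0:
        raise FoldChangeError(f"medians must be positive (case={mc}, control={mk})")
    return float(np.log2(mc / mk))


def _magnitude(delta: float) -> str:
    d = abs(delta)
    if d < CLIFFS_NEGLIGIBLE:
        return "negligible"
    if d < CLIFFS_SMALL:
        return "small"
    if d < CLIFFS_MEDIUM:
        return "medium"
    return "large"


def cliffs_delta(a, b) -> tuple[float, str]:
    """Cliff's delta: P(a > b) - P(a < b) over all cross pairs; ties count
    zero. Returns (delta, Romano magnitude label)."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    # for each b, count a-values strictly greater / strictly less
    greater = a.size - np.searchsorted(a, b, side="right")
    less = np.searchsorted(a, b, side="left")
    delta = float((greater.sum() - less.sum()) / (a.size * b.size))
    return delta, _magnitude(delta)


@dataclass
class UnivariateResult:
    """Per-analyte statistics for one case-vs-control stratum."""

    table: pd.DataFrame
    case_group: str
    control_group: str
    sex_filter: str | None
    alpha: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def univariate_profile(
    table: ConcentrationTable,
    case_group: str,
    control_group: str,
    sex_filter: str | None = None,
    alpha: float = 0.05,
) -> UnivariateResult:
    """Wilcoxon p, BH fdr (across all analytes jointly), log2FC of medians and
    Cliff's delta for every analyte, case vs control within one sex stratum.

    ``sex_filter`` of "M"/"F" restricts to that sex; None pools both.
    """
    groups = np.array([m.group for m in table.meta])
    sexes = np.array([m.sex for m in table.meta])
    in_stratum = np.ones(len(table.meta), dtype=bool)
    if sex_filter is not None:
        in_stratum &= sexes == sex_filter
    case_mask = in_stratum & (groups == case_group)
    ctrl_mask = in_stratum & (groups == control_group)
    if case_mask.sum() == 0 or ctrl_mask.sum() == 0:
        raise ValueError(
            f"empty stratum: case n={int(case_mask.sum())}, control n={int(ctrl_mask.sum())}"
        )
    rows = []
    for j, name in enumerate(table.analyte_names):
        a = table.values[case_mask, j]
        b = table.values[ctrl_mask, j]
        p = wilcoxon_rank_sum(a, b)
        fc = log2_fold_change(a, b)
        delta, mag = cliffs_delta(a, b)
        rows.append(
            {
                "analyte": name,
                "p_value": p,
                "log2fc": fc,
                "cliffs_delta": delta,
                "magnitude": mag,
                "median_case": float(np.median(a)),
                "median_control": float(np.median(b)),
            }
        )
    df = pd.DataFrame(rows)
    df["fdr"] = bh_adjust(df["p_value"].to_numpy())
    df["significant"] = df["fdr"] < alpha
    df = df[
        [
            "analyte",
            "p_value",
            "fdr",
            "log2fc",
            "cliffs_delta",
            "magnitude",
            "median_case",
            "median_control",
            "significant",
        ]
    ]
    return UnivariateResult(
        table=df, case_group=case_group, control_group=control_group,
        sex_filter=sex_filter, alpha=alpha,
    )
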