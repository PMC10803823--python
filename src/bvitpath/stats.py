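"""Group comparisons of species prevalence.

Two-group prevalence comparisons use the classical test of equal
proportions: Pearson's chi-square on the 2x2 presence/absence table, with
the Yates continuity correction on by default (matching the convention of
R's ``prop.test``).  Three or more groups are compared by one-way ANOVA on
per-sample 0/1 presence indicators (prevalence per group is a single
number, so the ANOVA needs sample-level replication), followed by Tukey's
HSD on significant results.  Families of p-values are adjusted with the
Benjamini–Hochberg step-up procedure and called significant at adjusted
p <= 0.05 (inclusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PrevalenceContingency",
    "TestResult",
    "two_group_prevalence_test",
    "multi_group_prevalence_anova",
    "tukey_hsd",
    "bh_adjust",
    "significant",
]


@dataclass(frozen=True)
class PrevalenceContingency:
    """Presence counts per group: label -> (n_present, n_total)."""

    groups: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for label, (k, n) in self.groups.items():
            if n < 1:
                raise ValueError(f"group {label!r}: n_total must be >= 1")
            if not (0 <= k <= n):
                raise ValueError(f"group {label!r}: need 0 <= n_present <= n_total")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    p_adjusted: float | None = None
    comparison: str = ""


def two_group_prevalence_test(
    c: PrevalenceContingency, continuity_correction: bool = True
) -> TestResult:
    """Test of equal prevalence between two groups.

    Pearson chi-square on the 2x2 table with 1 df, Yates-corrected by
    default.  Degenerate tables (a zero margin, e.g. no presences in
    either group) return statistic 0 and p 1 with a warning.
    """
    if len(c.groups) != 2:
        raise ValueError("two_group_prevalence_test needs exactly 2 groups")
    (k1, n1), (k2, n2) = c.groups.values()
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    method = "chi-square proportion test" + (
        " (Yates)" if continuity_correction else ""
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 table (zero margin); returning p = 1")
        return TestResult(0.0, 1.0, method)
    res = sps.chi2_contingency(table, correction=continuity_correction)
    return TestResult(float(res.statistic), float(res.pvalue), method)


def _check_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(groups) < 3:
        raise ValueError("need >= 3 groups (use the two-group proportion test)")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for label, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"group {label!r} needs >= 2 samples")
    return arrays


def multi_group_prevalence_anova(
    groups: Mapping[str, Sequence[float]],
) -> TestResult:
    """One-way ANOVA over per-sample presence indicators (3+ groups)."""
    arrays = _check_groups(groups)
    pooled = np.concatenate(list(arrays.values()))
    if np.ptp(pooled) == 0:
        return TestResult(0.0, 1.0, "one-way ANOVA on presence")
    with warnings.catch_warnings():
        # zero between-group variance triggers a harmless precision warning
        warnings.simplefilter("ignore")
        f, p = sps.f_oneway(*arrays.values())
    if np.isnan(f):  # 0/0: no variance anywhere
        f, p = 0.0, 1.0
    return TestResult(float(f), float(p), "one-way ANOVA on presence")


def tukey_hsd(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> list[TestResult]:
    """All pairwise Tukey HSD comparisons on presence indicators.

    Adjusted p-values come from the studentized range distribution; one
    result per unordered group pair, labelled ``"a vs b"``.
    """
    arrays = _check_groups(groups)
    labels = list(arrays)
    constant = np.ptp(np.concatenate(list(arrays.values()))) == 0
    if not constant:
        with np.errstate(divide="ignore", invalid="ignore"):
            res = sps.tukey_hsd(*[arrays[k] for k in labels])
    out: list[TestResult] = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if constant:
                stat, p = 0.0, 1.0
            else:
                stat = float(res.statistic[i, j])
                p = float(np.clip(res.pvalue[i, j], 0.0, 1.0))
                if np.isnan(p):  # 0/0: zero difference over zero pooled error
                    p = 1.0 if stat == 0 else 0.0
            out.append(
                TestResult(
                    statistic=stat,
                    p_value=p,
                    method="Tukey HSD",
                    p_adjusted=p,
                    comparison=f"{labels[i]} vs {labels[j]}",
                )
            )
    return out


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def adjust_results(results: Sequence[TestResult]) -> list[TestResult]:
    """Attach BH-adjusted p-values to a family of test results."""
    adj = bh_adjust([r.p_value for r in results])
    return [replace(r, p_adjusted=a) for r, a in zip(results, adj)]


def significant(
    results: Sequence[TestResult], alpha: float = 0.05
) -> list[bool]:
    """Flag results with adjusted p <= alpha (inclusive)."""
    flags = []
    for r in results:
        if r.p_adjusted is None:
            raise ValueError("p_adjusted missing; run bh_adjust/adjust_results first")
        flags.append(r.p_adjusted <= alpha)
    return flags
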