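"""Nonparametric group statistics with Benjamini-Yekutieli FDR correction.

All tests use the tie-corrected normal approximation *without* continuity
correction, matching the convention of mainstream commercial statistics
packages: for an all-positive one-sample signed-rank input of size n the
standardized statistic is Z = (n(n+1)/4) / sqrt(n(n+1)(2n+1)/24), e.g.
Z = 4.94 at n = 32 and Z = 3.92 at n = 20.  Zero differences are dropped
before ranking.  Multiple-comparison correction uses the
Benjamini-Yekutieli step-up procedure, applied separately within
caller-declared families ("sections").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as ss
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "wilcoxon_signed_rank",
    "mann_whitney",
    "spearman_correlation",
    "fdr_by",
    "apply_fdr",
    "results_to_frame",
]


@dataclass
class TestResult:
    """One hypothesis test: statistic, standardized Z, raw and adjusted p."""

    name: str
    statistic: float
    z: float
    p_raw: float
    n: tuple[int, ...]
    family: str = ""
    p_fdr: float | None = None
    kind: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        p = self.p_fdr if self.p_fdr is not None else self.p_raw
        return p < 0.05


def _tie_term(ranked_values: np.ndarray) -> float:
    """sum(t^3 - t) over groups of tied values."""
    _, counts = np.unique(ranked_values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def wilcoxon_signed_rank(
    values: Sequence[float],
    mu0: float = 0.0,
    name: str = "",
    family: str = "",
) -> TestResult:
    """One-sample Wilcoxon signed-rank test against location ``mu0``.

    Differences equal to ``mu0`` are dropped; |differences| are mid-ranked;
    the variance is tie-corrected; the two-sided p comes from the normal
    approximation without continuity correction.  The reported statistic is
    W+ (sum of ranks of positive differences); ``z`` keeps its sign.
    """
    d = np.asarray(values, dtype=float) - mu0
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all values equal mu0: signed-rank test undefined")
    if n < 5:
        raise ValueError(f"need at least 5 nonzero differences, got {n}")
    ranks = ss.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - _tie_term(np.abs(d)) / 48.0
    if var <= 0:
        raise ValueError("zero variance in signed-rank statistic")
    z = (w_plus - mean) / math.sqrt(var)
    p = 2.0 * ss.norm.sf(abs(z))
    return TestResult(
        name=name,
        statistic=w_plus,
        z=z,
        p_raw=float(min(p, 1.0)),
        n=(n,),
        family=family,
        kind="wilcoxon",
    )


def mann_whitney(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "two-sided",
    name: str = "",
    family: str = "",
) -> TestResult:
    """Mann-Whitney U test between two independent groups.

    The reported statistic is min(U_a, U_b); ``z`` is the tie-corrected
    normal-approximation Z reported as |Z| for two-sided tests (signed Z is
    kept under ``extra['z_signed']``, positive when group_a tends larger).
    ``alternative='greater'`` tests group_a > group_b one-sided.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n_a, n_b = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = ss.rankdata(combined)
    r_a = float(ranks[:n_a].sum())
    u_a = r_a - n_a * (n_a + 1) / 2.0
    u_b = n_a * n_b - u_a
    n_tot = n_a + n_b
    mean = n_a * n_b / 2.0
    tie = _tie_term(combined)
    var = (n_a * n_b / 12.0) * ((n_tot + 1) - tie / (n_tot * (n_tot - 1)))
    if var <= 0:
        raise ValueError("zero variance in rank sum (all values tied)")
    z_signed = (u_a - mean) / math.sqrt(var)
    if alternative == "two-sided":
        p = 2.0 * ss.norm.sf(abs(z_signed))
    elif alternative == "greater":
        p = float(ss.norm.sf(z_signed))
    elif alternative == "less":
        p = float(ss.norm.cdf(z_signed))
    else:
        raise ValueError("alternative must be 'two-sided', 'greater' or 'less'")
    return TestResult(
        name=name,
        statistic=float(min(u_a, u_b)),
        z=abs(z_signed),
        p_raw=float(min(p, 1.0)),
        n=(n_a, n_b),
        family=family,
        kind="mann-whitney",
        extra={"z_signed": z_signed, "u_a": u_a, "u_b": u_b, "alternative": alternative},
    )


def spearman_correlation(
    x: Sequence[float],
    y: Sequence[float],
    name: str = "",
    family: str = "",
) -> TestResult:
    """Spearman rank correlation with mid-ranks for ties, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input: correlation undefined")
    res = ss.spearmanr(x, y)
    rho = float(res.statistic)
    # large-sample normal approximation of the null distribution of rho
    z = rho * math.sqrt(x.size - 1)
    return TestResult(
        name=name,
        statistic=rho,
        z=z,
        p_raw=float(res.pvalue),
        n=(x.size,),
        family=family,
        kind="spearman",
    )


def fdr_by(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values (arbitrary dependence).

    adjusted p_(i) = min_{j >= i} min(1, (m * c(m) / j) * p_(j)) with
    c(m) = sum_{k=1..m} 1/k; monotone non-decreasing in the raw p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def apply_fdr(results: Iterable[TestResult]) -> list[TestResult]:
    """Fill ``p_fdr`` on every result, correcting within each family separately."""
    results = list(results)
    families: dict[str, list[TestResult]] = {}
    for r in results:
        families.setdefault(r.family, []).append(r)
    for members in families.values():
        adjusted = fdr_by([r.p_raw for r in members])
        for r, p in zip(members, adjusted):
            r.p_fdr = float(p)
    return results


def results_to_frame(results: Iterable[TestResult]) -> pd.DataFrame:
    """Tabulate test results, one row per test."""
    rows = []
    for r in results:
        rows.append(
            {
                "name": r.name,
                "family": r.family,
                "kind": r.kind,
                "statistic": r.statistic,
                "z": r.z,
                "p_raw": r.p_raw,
                "p_fdr": r.p_fdr,
                "n": "/".join(str(k) for k in r.n),
            }
        )
    return pd.DataFrame(rows)
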