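"""Baseline paired tests, BH-FDR ranking, and gene-list overlap statistics.

The paired Student t-test and the standard Wilcoxon signed-rank test (the
same signed-rank machinery as the MWT but on raw, un-normalized paired
differences) are the canonical comparators.  Their p-values are
Benjamini-Hochberg adjusted and features rank-ordered by the adjusted
value, so same-size top-k lists can be intersected across methods; overlap
significance is measured with the upper-tail hypergeometric test on a gene
universe of configurable size (default 13,074, the non-redundant RefSeq
gene count of the U133A array).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mwt import pvalues_from_differences
from .paired_data import PairedExpressionMatrix

__all__ = [
    "OverlapTestResult",
    "paired_t_test",
    "standard_wilcoxon",
    "bh_fdr",
    "top_k",
    "overlap_test",
    "DEFAULT_UNIVERSE",
]

DEFAULT_UNIVERSE = 13074


def paired_t_test(pem: PairedExpressionMatrix) -> np.ndarray:
    """Two-sided paired t-test p-value per feature, on raw intensities.

    t = D̄ * sqrt(N) / sd(D) with N-1 degrees of freedom, D = y - x.
    Zero-variance rows are degenerate: p = 0 if the mean difference is
    nonzero (perfectly consistent shift), else p = 1.
    """
    d = pem.y - pem.x
    n = pem.n_patients
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    p = np.empty(pem.n_features)
    zero_var = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean * np.sqrt(n) / sd
    p[~zero_var] = 2.0 * stats.t.sf(np.abs(t[~zero_var]), df=n - 1)
    p[zero_var] = np.where(mean[zero_var] != 0, 0.0, 1.0)
    return p


def standard_wilcoxon(
    pem: PairedExpressionMatrix, z_correction: str = "continuity"
) -> np.ndarray:
    """Standard Wilcoxon signed-rank p per feature on raw paired differences.

    Identical machinery to the MWT but without cross-normalization.
    """
    return pvalues_from_differences(pem.y - pem.x, z_correction)


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def top_k(results: pd.DataFrame, k: int, key: str = "p_adjusted") -> list:
    """First ``k`` feature ids under (key ascending, feature_id ascending)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    ordered = results.sort_values(
        by=[key, "feature_id"], ascending=[True, True], kind="mergesort"
    )
    return list(ordered["feature_id"].head(k))


@dataclass
class OverlapTestResult:
    k: int
    n: int
    m: int
    n_universe: int
    p_value: float
    fold_enrichment: float
    two_sided: bool = False


def overlap_test(
    k: int, n: int, m: int, n_universe: int = DEFAULT_UNIVERSE,
    two_sided: bool = False,
) -> OverlapTestResult:
    """Significance of an overlap of ``k`` between lists of sizes n and m.

    One-sided: upper-tail hypergeometric P(overlap >= k) when n items are
    drawn from a universe containing m marked ones.  Two-sided: Fisher's
    exact test on the corresponding 2x2 table (sum of tables at most as
    probable as the observed one).
    """
    if k > min(n, m):
        raise ValueError(f"overlap k={k} exceeds min(n, m)={min(n, m)}")
    if max(n, m) > n_universe:
        raise ValueError("list size exceeds universe")
    if n_universe - n - m + k < 0:
        raise ValueError("impossible overlap geometry for this universe")
    if two_sided:
        table = [[k, n - k], [m - k, n_universe - n - m + k]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    else:
        p = float(stats.hypergeom.sf(k - 1, n_universe, m, n))
    expected = n * m / n_universe
    fe = k / expected if expected > 0 else float("nan")
    return OverlapTestResult(
        k=k, n=n, m=m, n_universe=n_universe,
        p_value=min(1.0, p), fold_enrichment=fe, two_sided=two_sided,
    )
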