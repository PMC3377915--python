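"""Modified Wilcoxon test (MWT) on cross-normalized paired differences.

For each feature the signed-rank machinery is applied to the N per-pair
differences d_ij: absolute differences are ranked (average ranks for ties,
exact zeros dropped), the rank sums R+ and R- are formed, and the smaller
sum is converted to a normal-approximation Z

    Z = (R_min - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24),     n = N - #zeros,

with a pluggable small-sample correction before the two-sided p-value
2*Phi(Z) is read off the standard normal.  Alongside the test the sign
pattern of the differences is tabulated: the misclassification count
min(t+, t-) says in how many patients the feature orders the pair the
"wrong" way, and a feature separating every one of the N pairs in the same
direction is a completely discriminative signal (CDS); anything else is an
incomplete discriminative signal (IDS).

Correction policies
-------------------
``continuity``  recompute Z from R_min + 0.5 (default; the usual continuity
                correction for a discrete statistic under a continuous
                approximation).
``none``        the raw normal approximation.
``shrink:c``    multiply Z by sqrt((n - c)/n) for a small integer c, a
                variance-inflation style shrinkage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cross_norm import cn_differences
from .paired_data import PairedExpressionMatrix

__all__ = [
    "SignPattern",
    "signed_rank_sums",
    "z_value",
    "corrected_z",
    "mwt_pvalue",
    "misclassification",
    "classify_cds",
    "fold_change",
    "sign_pattern",
    "score_differences",
    "mwt_table",
]


@dataclass
class SignPattern:
    """Indicator table of difference signs: 1 for d>0, 0 for d<0, zeros apart."""

    indicators: np.ndarray  # M x N, 1.0 / 0.0 / nan for exact zeros
    t_plus: np.ndarray
    t_minus: np.ndarray
    n_zero: np.ndarray


def sign_pattern(d: np.ndarray) -> SignPattern:
    """Tabulate signs of a difference matrix (features in rows)."""
    d = np.atleast_2d(np.asarray(d, dtype=float))
    ind = np.full(d.shape, np.nan)
    ind[d > 0] = 1.0
    ind[d < 0] = 0.0
    return SignPattern(
        indicators=ind,
        t_plus=(d > 0).sum(axis=1),
        t_minus=(d < 0).sum(axis=1),
        n_zero=(d == 0).sum(axis=1),
    )


def signed_rank_sums(d_row: np.ndarray) -> tuple[float, float]:
    """Rank |d| ascending (average ranks for ties, zeros dropped) and sum
    the ranks of positive and negative differences."""
    d = np.asarray(d_row, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two paired differences")
    nz = d != 0
    dd = d[nz]
    if dd.size == 0:
        return 0.0, 0.0
    ranks = stats.rankdata(np.abs(dd))
    return float(ranks[dd > 0].sum()), float(ranks[dd < 0].sum())


def z_value(r_min: float, n_eff: int) -> float:
    """Normal-approximation Z for the smaller rank sum; <= 0 by construction."""
    if n_eff < 2:
        raise ValueError("n_eff must be at least 2")
    mean = n_eff * (n_eff + 1) / 4.0
    sd = np.sqrt(n_eff * (n_eff + 1) * (2 * n_eff + 1) / 24.0)
    return (r_min - mean) / sd


_SHRINK_RE = re.compile(r"^shrink[:(](\d+)\)?$")


def corrected_z(z_raw: float, n_eff: int, policy: str = "continuity",
                r_min: float | None = None) -> float:
    """Apply the configured small-sample correction to a raw Z value.

    The continuity policy needs the rank sum the Z came from; callers that
    only hold Z can pass ``r_min=None`` and it is reconstructed.
    """
    if policy == "none":
        return z_raw
    if policy == "continuity":
        mean = n_eff * (n_eff + 1) / 4.0
        sd = np.sqrt(n_eff * (n_eff + 1) * (2 * n_eff + 1) / 24.0)
        if r_min is None:
            r_min = z_raw * sd + mean
        return min((r_min + 0.5 - mean) / sd, 0.0)
    m = _SHRINK_RE.match(policy)
    if m:
        c = int(m.group(1))
        if not 0 <= c < n_eff:
            raise ValueError(f"shrink constant {c} out of range for n_eff={n_eff}")
        return z_raw * np.sqrt((n_eff - c) / n_eff)
    raise ValueError(f"unknown z-correction policy {policy!r}")


def mwt_pvalue(z_corrected: float) -> float:
    """Two-sided standard-normal tail probability for a (non-positive) Z."""
    return float(min(1.0, 2.0 * stats.norm.cdf(-abs(z_corrected))))


def misclassification(t_plus: int, t_minus: int, n_pairs: int) -> tuple[int, float]:
    """Separation errors: the minority sign count and its fraction of N."""
    count = int(min(t_plus, t_minus))
    return count, count / n_pairs


def classify_cds(t_plus: int, t_minus: int, n_zero: int, n_pairs: int) -> str:
    """CDS iff every pair carries the same strict sign; zeros break CDS."""
    if n_zero == 0 and (t_plus == n_pairs or t_minus == n_pairs):
        return "CDS"
    return "IDS"


def fold_change(x_row: np.ndarray, y_row: np.ndarray) -> tuple[float, str]:
    """Symmetrized ratio of class means (>= 1) with an up/down direction."""
    r = float(np.mean(y_row)) / float(np.mean(x_row))
    direction = "up" if r > 1 else "down"
    return max(r, 1.0 / r), direction


def _rank_sums_matrix(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized R+/R- per row; rows containing exact zeros fall back to the
    scalar path so zeros are dropped before ranking."""
    has_zero = (d == 0).any(axis=1)
    ranks = stats.rankdata(np.abs(d), axis=1)
    r_plus = np.where(d > 0, ranks, 0.0).sum(axis=1)
    r_minus = np.where(d < 0, ranks, 0.0).sum(axis=1)
    for i in np.flatnonzero(has_zero):
        r_plus[i], r_minus[i] = signed_rank_sums(d[i])
    return r_plus, r_minus


def score_differences(
    d: np.ndarray, z_correction: str = "continuity"
) -> pd.DataFrame:
    """Score a difference matrix (features in rows): rank sums, Z, p, signs.

    Degenerate rows (fewer than 2 nonzero differences) get p = 1 and NaN Z.
    """
    d = np.atleast_2d(np.asarray(d, dtype=float))
    m, n = d.shape
    sp = sign_pattern(d)
    n_eff = n - sp.n_zero
    r_plus, r_minus = _rank_sums_matrix(d)
    r_min = np.minimum(r_plus, r_minus)

    ok = n_eff >= 2
    z = np.full(m, np.nan)
    p = np.ones(m)
    ne = n_eff[ok].astype(float)
    mean = ne * (ne + 1) / 4.0
    sd = np.sqrt(ne * (ne + 1) * (2 * ne + 1) / 24.0)
    z_raw = (r_min[ok] - mean) / sd
    if z_correction == "none":
        z_ok = z_raw
    elif z_correction == "continuity":
        z_ok = np.minimum((r_min[ok] + 0.5 - mean) / sd, 0.0)
    else:
        mshr = _SHRINK_RE.match(z_correction)
        if not mshr:
            raise ValueError(f"unknown z-correction policy {z_correction!r}")
        c = int(mshr.group(1))
        z_ok = z_raw * np.sqrt(np.maximum(ne - c, 0.0) / ne)
    z[ok] = z_ok
    p[ok] = np.minimum(1.0, 2.0 * stats.norm.cdf(-np.abs(z_ok)))

    mis = np.minimum(sp.t_plus, sp.t_minus)
    return pd.DataFrame(
        {
            "n_pairs": n,
            "t_plus": sp.t_plus,
            "t_minus": sp.t_minus,
            "n_zero_diffs": sp.n_zero,
            "misclassification_count": mis,
            "misclassification_rate": mis / n,
            "r_plus": r_plus,
            "r_minus": r_minus,
            "z_value": z,
            "p_mwt": p,
            "cds_flag": np.where(
                (sp.n_zero == 0) & ((sp.t_plus == n) | (sp.t_minus == n)),
                "CDS",
                "IDS",
            ),
            "degenerate": ~ok,
        }
    )


def pvalues_from_differences(d: np.ndarray, z_correction: str = "continuity") -> np.ndarray:
    """Per-row MWT p-values only — the hot path for bootstrap replicates."""
    d = np.atleast_2d(np.asarray(d, dtype=float))
    m, n = d.shape
    n_zero = (d == 0).sum(axis=1)
    n_eff = n - n_zero
    r_plus, r_minus = _rank_sums_matrix(d)
    r_min = np.minimum(r_plus, r_minus)
    p = np.ones(m)
    ok = n_eff >= 2
    ne = n_eff[ok].astype(float)
    mean = ne * (ne + 1) / 4.0
    sd = np.sqrt(ne * (ne + 1) * (2 * ne + 1) / 24.0)
    if z_correction == "none":
        z = (r_min[ok] - mean) / sd
    elif z_correction == "continuity":
        z = np.minimum((r_min[ok] + 0.5 - mean) / sd, 0.0)
    else:
        mshr = _SHRINK_RE.match(z_correction)
        if not mshr:
            raise ValueError(f"unknown z-correction policy {z_correction!r}")
        c = int(mshr.group(1))
        z = (r_min[ok] - mean) / sd * np.sqrt(np.maximum(ne - c, 0.0) / ne)
    p[ok] = np.minimum(1.0, 2.0 * stats.norm.cdf(-np.abs(z)))
    return p


def mwt_table(
    pem: PairedExpressionMatrix,
    z_correction: str = "continuity",
    cn_strategy: str = "divide",
) -> pd.DataFrame:
    """Full MWT scoring of a paired matrix: CN, differences, test, fold change."""
    diff = cn_differences(pem, cn_strategy)
    table = score_differences(diff.d, z_correction)
    table.insert(0, "feature_id", pem.feature_ids)
    ratio = pem.y.mean(axis=1) / pem.x.mean(axis=1)
    table["fold_change"] = np.maximum(ratio, 1.0 / ratio)
    table["direction"] = np.where(ratio > 1, "up", "down")
    table["mean_difference"] = diff.d_bar
    return table
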