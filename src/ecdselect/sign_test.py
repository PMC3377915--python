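"""Sign-symmetry test: how unlikely is a near-perfect sign split by chance?

Under the null that a feature carries no disease effect, each patient's
cross-normalized difference is positive or negative with probability 1/2
independently, so the number of minority signs ("misclassifications") s
among N pairs is Binomial(N, 1/2).  The one-sided lower tail

    P(S <= s) = sum_{k=0..s} C(N, k) / 2^N

is the chance of seeing at most s misclassifications by luck alone; a
Bonferroni multiplier over the M features screened turns it into a
genome-wide plausibility bound.  With s = 2 errors in N = 27 pairs and
M = 22,283 probe sets the adjusted value is 0.062 — the screening-wide
argument that complete or near-complete separation is not a fluke.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = ["SignTestResult", "sign_test_pvalue", "bonferroni", "sign_test"]


@dataclass
class SignTestResult:
    s: int
    n_pairs: int
    p_raw: float
    m_tests: int
    p_adjusted: float


def sign_test_pvalue(s: int, n_pairs: int, two_sided: bool = False) -> float:
    """Binomial tail probability of at most ``s`` minority signs in ``n_pairs``.

    One-sided lower tail by default; ``two_sided=True`` doubles it (capped
    at 1).
    """
    if not 0 <= s <= n_pairs:
        raise ValueError(f"s={s} outside 0..{n_pairs}")
    p = float(stats.binom.cdf(s, n_pairs, 0.5))
    if two_sided:
        p = min(1.0, 2.0 * p)
    return p


def bonferroni(p_raw: float, m_tests: int) -> float:
    """Bonferroni family-wise adjustment min(1, p * m)."""
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return min(1.0, p_raw * m_tests)


def sign_test(
    s: int, n_pairs: int, m_tests: int = 1, two_sided: bool = False
) -> SignTestResult:
    """Full sign-symmetry test with Bonferroni adjustment over m features."""
    p_raw = sign_test_pvalue(s, n_pairs, two_sided=two_sided)
    return SignTestResult(
        s=s,
        n_pairs=n_pairs,
        p_raw=p_raw,
        m_tests=m_tests,
        p_adjusted=bonferroni(p_raw, m_tests),
    )
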