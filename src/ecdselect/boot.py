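"""Bootstrap significance filter for MWT-scored features.

Patient *pairs* are resampled with replacement — the pair, not the single
sample, is the exchangeable unit in a matched design — and the whole
CN + MWT scoring is rerun on each replicate (class means move under
resampling, so cross-normalization must be recomputed).  For each feature

    Bootstrap P = #(P_boot < P_test) / n_boot

counts how often a replicate beats the observed p-value strictly.  A
feature whose observed separation is already the best its N pairs can show
(zero misclassifications, no rank ties) can never be beaten, so its
Bootstrap P is exactly 0; fragile separations are beaten often and are
filtered out at the ``alpha`` threshold (default 0.05).

An alternative ``signflip`` null swaps the tumour/normal roles of random
pairs instead of resampling them, for users wanting a classical
permutation-style reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mwt import pvalues_from_differences
from .paired_data import PairedExpressionMatrix

__all__ = ["BootstrapResult", "bootstrap_filter"]

DEFAULT_N_BOOT = 9999


@dataclass
class BootstrapResult:
    """Per-feature bootstrap summary; ``table`` has one row per feature."""

    table: pd.DataFrame  # feature_id, p_test, n_less, p_boot
    n_boot: int
    seed: int
    null: str


def _cn_diffs(x: np.ndarray, y: np.ndarray, strategy: str) -> np.ndarray:
    x_bar = x.mean(axis=1)[:, None]
    y_bar = y.mean(axis=1)[:, None]
    if strategy == "divide":
        return y / x_bar - x / y_bar
    if strategy == "subtract":
        return (y - x_bar) - (x - y_bar)
    raise ValueError(f"unknown CN strategy {strategy!r}")


def bootstrap_filter(
    pem: PairedExpressionMatrix,
    feature_idx: np.ndarray,
    p_test: np.ndarray,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
    z_correction: str = "continuity",
    cn_strategy: str = "divide",
    null: str = "resample",
) -> BootstrapResult:
    """Compute Bootstrap P for the features at ``feature_idx``.

    Parameters
    ----------
    feature_idx
        Integer indices (or boolean mask) into ``pem`` rows, typically the
        features that survived the misclassification filter.
    p_test
        Observed MWT p-values for exactly those features, in the same order.
    null
        ``resample`` draws N patient pairs with replacement (default);
        ``signflip`` randomly exchanges the class roles within pairs.
    """
    if seed is None:
        raise ValueError("bootstrap requires an explicit seed")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if null not in ("resample", "signflip"):
        raise ValueError(f"unknown null {null!r}")

    feature_idx = np.asarray(feature_idx)
    if feature_idx.dtype == bool:
        feature_idx = np.flatnonzero(feature_idx)
    p_test = np.asarray(p_test, dtype=float)
    if p_test.shape != feature_idx.shape:
        raise ValueError("p_test must align with feature_idx")

    rng = np.random.default_rng(seed)
    x = pem.x[feature_idx]
    y = pem.y[feature_idx]
    n = pem.n_patients
    n_less = np.zeros(len(feature_idx), dtype=int)

    for _ in range(n_boot):
        if null == "resample":
            idx = rng.integers(0, n, size=n)
            while len(np.unique(idx)) < 2:  # degenerate draw: one patient only
                idx = rng.integers(0, n, size=n)
            xb, yb = x[:, idx], y[:, idx]
        else:
            flip = rng.integers(0, 2, size=n).astype(bool)
            xb = np.where(flip, y, x)
            yb = np.where(flip, x, y)
        p_boot = pvalues_from_differences(_cn_diffs(xb, yb, cn_strategy), z_correction)
        n_less += p_boot < p_test

    table = pd.DataFrame(
        {
            "feature_id": pem.feature_ids[feature_idx],
            "p_test": p_test,
            "n_less": n_less,
            "p_boot": n_less / n_boot,
        }
    )
    return BootstrapResult(table=table, n_boot=n_boot, seed=seed, null=null)
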