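"""The ECD selection pipeline: CN -> MWT -> error filter -> bootstrap -> fold change.

Two selection regimes are evaluated in a single pass:

* **strict** — zero misclassifications (CDS), MWT p below ``mwt_alpha``,
  Bootstrap P below 0.05, fold change above 1.35;
* **relaxed** — up to ``relaxed_max_errors`` misclassifications (default 2),
  a lower fold-change floor of 1.2, and a tighter bootstrap cut of 0.01 to
  compensate for the loosened error criterion.

The bootstrap, the expensive stage, runs once over the union of candidates
(features within the relaxed error budget that pass the MWT alpha), so
evaluating both regimes costs no more than evaluating the relaxed one.
The Bonferroni-adjusted sign-symmetry p-value for each feature's observed
error count is attached as an annotation; it is a plausibility bound, not a
filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boot import DEFAULT_N_BOOT, bootstrap_filter
from .mwt import mwt_table
from .paired_data import RESULT_COLUMNS, PairedExpressionMatrix
from .sign_test import sign_test_pvalue

__all__ = ["ECDConfig", "ECDSelection", "run_ecd", "misclassification_histogram"]

log = logging.getLogger("ecdselect")


@dataclass
class ECDConfig:
    """Thresholds for the strict and relaxed ECD selections."""

    mwt_alpha: float = 0.05
    strict_min_fold_change: float = 1.35
    strict_boot_alpha: float = 0.05
    relaxed_max_errors: int = 2
    relaxed_min_fold_change: float = 1.2
    relaxed_boot_alpha: float = 0.01
    n_boot: int = DEFAULT_N_BOOT
    seed: int = 0
    z_correction: str = "continuity"
    cn_strategy: str = "divide"
    boot_null: str = "resample"
    bonferroni_m: int | None = None  # defaults to the number of features
    mode: str = "strict"
    compute_relaxed: bool = True

    def __post_init__(self) -> None:
        for name in ("mwt_alpha", "strict_boot_alpha", "relaxed_boot_alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.strict_min_fold_change < 1 or self.relaxed_min_fold_change < 1:
            raise ValueError("fold-change thresholds must be >= 1")
        if self.relaxed_max_errors < 0:
            raise ValueError("relaxed_max_errors must be >= 0")
        if self.mode not in ("strict", "relaxed"):
            raise ValueError(f"mode must be strict or relaxed, got {self.mode!r}")


@dataclass
class ECDSelection:
    """Selected features with per-filter provenance and the error histogram."""

    feature_ids: list
    mode: str
    provenance: pd.DataFrame  # feature_id + pass_* flags per filter
    histogram: pd.DataFrame
    config: ECDConfig
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_ecd(
    pem: PairedExpressionMatrix, config: ECDConfig | None = None
) -> tuple[ECDSelection, pd.DataFrame]:
    """Score every feature and apply the ECD filters.

    Returns the selection for ``config.mode`` plus the full results table
    (canonical column set) with both ``selected_strict`` and
    ``selected_relaxed`` populated.
    """
    cfg = config or ECDConfig()
    if cfg.relaxed_max_errors >= pem.n_patients / 2:
        raise ValueError("relaxed_max_errors must be below N/2")
    if not cfg.compute_relaxed and cfg.mode == "relaxed":
        raise ValueError("mode='relaxed' requires compute_relaxed=True")

    table = mwt_table(pem, cfg.z_correction, cfg.cn_strategy)
    m = len(table)
    log.info("scored %d features on %d pairs", m, pem.n_patients)

    mis = table["misclassification_count"].to_numpy()
    p_mwt = table["p_mwt"].to_numpy()
    fc = table["fold_change"].to_numpy()
    degenerate = table["degenerate"].to_numpy()

    pass_mwt = (p_mwt <= cfg.mwt_alpha) & ~degenerate
    error_budget = cfg.relaxed_max_errors if cfg.compute_relaxed else 0
    pass_error_strict = (mis == 0) & ~degenerate
    pass_error_relaxed = (mis <= error_budget) & ~degenerate
    candidates = np.flatnonzero(pass_error_relaxed & pass_mwt)
    log.info(
        "error filter: %d strict / %d relaxed candidates (of %d)",
        int((pass_error_strict & pass_mwt).sum()), len(candidates), m,
    )

    p_boot = np.full(m, np.nan)
    if len(candidates):
        boot = bootstrap_filter(
            pem,
            candidates,
            p_mwt[candidates],
            n_boot=cfg.n_boot,
            seed=cfg.seed,
            z_correction=cfg.z_correction,
            cn_strategy=cfg.cn_strategy,
            null=cfg.boot_null,
        )
        p_boot[candidates] = boot.table["p_boot"].to_numpy()

    pass_boot_strict = np.nan_to_num(p_boot, nan=1.0) < cfg.strict_boot_alpha
    pass_boot_relaxed = np.nan_to_num(p_boot, nan=1.0) < cfg.relaxed_boot_alpha
    pass_fc_strict = fc > cfg.strict_min_fold_change
    pass_fc_relaxed = fc > cfg.relaxed_min_fold_change

    selected_strict = pass_error_strict & pass_mwt & pass_boot_strict & pass_fc_strict
    selected_relaxed = (
        pass_error_relaxed & pass_mwt & pass_boot_relaxed & pass_fc_relaxed
    )
    if not cfg.compute_relaxed:
        selected_relaxed = np.zeros(m, dtype=bool)
    log.info(
        "selected %d strict / %d relaxed features",
        int(selected_strict.sum()), int(selected_relaxed.sum()),
    )

    table["p_bootstrap"] = p_boot
    table["selected_strict"] = selected_strict
    table["selected_relaxed"] = selected_relaxed

    selected = selected_strict if cfg.mode == "strict" else selected_relaxed
    provenance = pd.DataFrame(
        {
            "feature_id": table["feature_id"],
            "pass_error_strict": pass_error_strict,
            "pass_error_relaxed": pass_error_relaxed,
            "pass_mwt_alpha": pass_mwt,
            "pass_boot_strict": pass_boot_strict,
            "pass_boot_relaxed": pass_boot_relaxed,
            "pass_fc_strict": pass_fc_strict,
            "pass_fc_relaxed": pass_fc_relaxed,
            "direction": table["direction"],
            "selected": selected,
        }
    )

    m_bonf = cfg.bonferroni_m or m
    n = pem.n_patients
    p_sign = np.array([sign_test_pvalue(int(s), n) for s in mis])
    annotations = pd.DataFrame(
        {
            "feature_id": table["feature_id"],
            "p_sign": p_sign,
            "p_sign_bonferroni": np.minimum(1.0, p_sign * m_bonf),
        }
    )

    selection = ECDSelection(
        feature_ids=list(table.loc[selected, "feature_id"]),
        mode=cfg.mode,
        provenance=provenance,
        histogram=misclassification_histogram(table),
        config=cfg,
        annotations=annotations,
    )
    result = table[[c for c in RESULT_COLUMNS if c in table.columns]].copy()
    return selection, result


def misclassification_histogram(results: pd.DataFrame) -> pd.DataFrame:
    """Count features per (direction, misclassification level).

    Rows are directions (up/down), columns the error levels present; the
    attached attr ``fraction_ge2`` is the fraction of features with two or
    more misclassified pairs.
    """
    hist = (
        results.groupby(["direction", "misclassification_count"])
        .size()
        .unstack(fill_value=0)
    )
    total = len(results)
    ge2 = int((results["misclassification_count"] >= 2).sum())
    hist.attrs["fraction_ge2"] = ge2 / total if total else 0.0
    return hist
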