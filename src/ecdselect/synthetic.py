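"""Synthetic paired expression data with known ground truth.

The generator follows the additive random-effects model of a matched
tumour/normal design.  On a latent log2 scale,

    x_ij = mu_j + alpha_i + eps^x_ij
    y_ij = mu_j + theta_j + alpha_i + eps^y_ij

where mu_j is the per-feature baseline, alpha_i a per-patient effect shared
by both halves of a pair (the "stable confounders" a paired test cancels),
eps the independent residual noise, and theta_j the disease effect — zero
for null features, a signed log2 shift for the spiked fraction.  With the
default ``intensity_transform`` the latent values are exponentiated base 2
into strictly positive MAS5-like intensities; a linear mode (latent values
shifted to be positive) exists for closed-form unit checks.

What this emulates: positive paired intensities with strong within-pair
correlation and a multiplicative disease effect.  What it does not: probe-
level noise, batch effects, or inter-gene correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .paired_data import PairedExpressionMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SelectionMetrics",
    "simulate_paired",
    "evaluate_selection",
    "write_simulation",
]


@dataclass
class SimulationConfig:
    """Parameters of the paired random-effects generator.

    All location/scale parameters are on the latent log2 scale.  Defaults
    describe a 27-patient, 10,000-feature screen with 1% truly affected
    features at a 4-fold (theta = 2 log2-units) average effect, patient
    effects (alpha_sd = 1) twice as large as residual noise (eps_sd = 0.5),
    and baselines around 2^9 = 512 intensity units.
    """

    n_patients: int = 27
    n_features: int = 10000
    effect_fraction: float = 0.01
    theta_mean: float = 2.0
    theta_sd: float = 0.5
    alpha_sd: float = 1.0
    eps_sd: float = 0.5
    mu_mean: float = 9.0
    mu_sd: float = 1.5
    intensity_transform: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least two patients")
        if self.n_features < 1:
            raise ValueError("need at least one feature")
        if not 0 <= self.effect_fraction <= 1:
            raise ValueError("effect_fraction must lie in [0, 1]")
        for name in ("theta_sd", "alpha_sd", "eps_sd", "mu_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulation: theta per feature and realized alphas."""

    feature_ids: np.ndarray
    theta: np.ndarray          # 0.0 for null features
    direction: np.ndarray      # "up" / "down" / "" for nulls
    alpha: np.ndarray          # realized per-patient effects
    seed: int

    @property
    def spiked_ids(self) -> list:
        return list(self.feature_ids[self.theta != 0])

    @property
    def null_ids(self) -> list:
        return list(self.feature_ids[self.theta == 0])


def simulate_paired(
    config: SimulationConfig,
) -> tuple[PairedExpressionMatrix, SyntheticTruth]:
    """Draw one paired dataset and its ground truth, deterministically.

    Each model component (baselines, effects, patient effects, residuals)
    consumes an independent child stream spawned from the seed, so the
    realized values of one component do not depend on the sizes of the
    others.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_mu, rng_theta, rng_alpha, rng_eps = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    m, n = cfg.n_features, cfg.n_patients

    mu = rng_mu.normal(cfg.mu_mean, cfg.mu_sd, size=m)

    n_spiked = round(cfg.effect_fraction * m)
    theta = np.zeros(m)
    if n_spiked:
        spiked = rng_theta.choice(m, size=n_spiked, replace=False)
        signs = rng_theta.choice([-1.0, 1.0], size=n_spiked)
        magnitudes = np.abs(rng_theta.normal(cfg.theta_mean, cfg.theta_sd, n_spiked))
        theta[spiked] = signs * magnitudes

    alpha = rng_alpha.normal(0.0, cfg.alpha_sd, size=n)
    lat_x = mu[:, None] + alpha[None, :] + rng_eps.normal(0, cfg.eps_sd, (m, n))
    lat_y = (
        mu[:, None] + theta[:, None] + alpha[None, :]
        + rng_eps.normal(0, cfg.eps_sd, (m, n))
    )

    if cfg.intensity_transform:
        x, y = np.exp2(lat_x), np.exp2(lat_y)
    else:
        # linear mode: shift so intensities stay positive, preserving diffs
        shift = min(lat_x.min(), lat_y.min())
        offset = 1.0 - shift if shift < 1.0 else 0.0
        x, y = lat_x + offset, lat_y + offset

    feature_ids = np.array([f"F{j:06d}" for j in range(m)], dtype=object)
    patient_ids = np.array([f"P{i:03d}" for i in range(n)], dtype=object)
    direction = np.where(theta > 0, "up", np.where(theta < 0, "down", ""))
    pem = PairedExpressionMatrix(feature_ids, patient_ids, x, y)
    truth = SyntheticTruth(
        feature_ids=feature_ids, theta=theta, direction=direction.astype(object),
        alpha=alpha, seed=cfg.seed,
    )
    return pem, truth


@dataclass
class SelectionMetrics:
    power: float
    type_i_error: float
    fdp: float
    direction_accuracy: float
    n_selected: int
    n_true: int
    n_null: int


def evaluate_selection(
    selected_ids,
    truth: SyntheticTruth,
    directions: dict | None = None,
) -> SelectionMetrics:
    """Score a selection against the simulation truth.

    power = selected true effects / true effects; type-I = selected nulls /
    nulls; FDP = selected nulls / selected (0 when nothing is selected);
    direction accuracy over true positives (1.0 when directions are not
    supplied or there are no true positives).
    """
    known = set(truth.feature_ids)
    selected = list(selected_ids)
    unknown = [f for f in selected if f not in known]
    if unknown:
        raise ValueError(f"selection contains unknown feature id {unknown[0]!r}")

    spiked = set(truth.spiked_ids)
    nulls = set(truth.null_ids)
    sel = set(selected)
    tp = sel & spiked
    fp = sel & nulls
    power = len(tp) / len(spiked) if spiked else 0.0
    type_i = len(fp) / len(nulls) if nulls else 0.0
    fdp = len(fp) / len(sel) if sel else 0.0

    dir_acc = 1.0
    if directions and tp:
        true_dir = dict(zip(truth.feature_ids, truth.direction))
        hits = sum(1 for f in tp if directions.get(f) == true_dir[f])
        dir_acc = hits / len(tp)
    return SelectionMetrics(
        power=power, type_i_error=type_i, fdp=fdp, direction_accuracy=dir_acc,
        n_selected=len(sel), n_true=len(spiked), n_null=len(nulls),
    )


def write_simulation(
    pem: PairedExpressionMatrix, truth: SyntheticTruth, out_prefix: str
) -> tuple[str, str, str]:
    """Emit matrix, manifest, and truth TSVs for a simulated dataset."""
    cols_x = [f"{p}_N" for p in pem.patient_ids]
    cols_y = [f"{p}_T" for p in pem.patient_ids]
    matrix = pd.DataFrame(
        np.hstack([pem.x, pem.y]),
        index=pd.Index(pem.feature_ids, name="feature_id"),
        columns=cols_x + cols_y,
    )
    matrix_path = f"{out_prefix}_matrix.tsv"
    matrix.to_csv(matrix_path, sep="\t", float_format="%.6g")

    manifest = pd.DataFrame(
        {
            "sample_id": cols_x + cols_y,
            "patient_id": list(pem.patient_ids) * 2,
            "class": ["normal"] * pem.n_patients + ["tumour"] * pem.n_patients,
        }
    )
    manifest_path = f"{out_prefix}_manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)

    truth_path = f"{out_prefix}_truth.tsv"
    pd.DataFrame(
        {
            "feature_id": truth.feature_ids,
            "theta": truth.theta,
            "direction": truth.direction,
        }
    ).to_csv(truth_path, sep="\t", index=False)
    return matrix_path, manifest_path, truth_path
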