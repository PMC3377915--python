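"""Domain types and TSV I/O for paired two-class expression data.

The central container is :class:`PairedExpressionMatrix`: for each of M
features and N patients it holds one class-X (normal / adjacent tissue) and
one class-Y (tumour) intensity.  Intensities are non-log, strictly positive
values such as MAS5-summarized microarray signals.  Pairing is defined by a
manifest that maps every sample column of the expression matrix to a patient
and a class; column order in the matrix file carries no information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PairedDataError",
    "UnpairedSampleError",
    "InvalidIntensityError",
    "PairedExpressionMatrix",
    "PairingManifest",
    "RESULT_COLUMNS",
    "read_pairing_manifest",
    "read_paired_matrix",
    "write_results",
    "read_results",
    "sort_results",
]


class PairedDataError(ValueError):
    """Malformed paired expression input."""


class UnpairedSampleError(PairedDataError):
    """A patient is missing one half of its tumour/normal pair."""


class InvalidIntensityError(PairedDataError):
    """A cell of the expression matrix is non-numeric or non-positive."""


# class-label vocabulary, matched case-insensitively
_X_LABELS = {"normal", "adjacent", "control"}
_Y_LABELS = {"tumour", "tumor", "cancer", "case"}


@dataclass
class PairedExpressionMatrix:
    """M features x N patients, one intensity per (feature, patient, class).

    ``x`` holds the class-X (normal) intensities and ``y`` the class-Y
    (tumour) intensities, both with shape ``(M, N)`` and column ``i``
    belonging to patient ``patient_ids[i]`` in either matrix.
    """

    feature_ids: np.ndarray
    patient_ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    n_floored: int = 0

    def __post_init__(self) -> None:
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        m, n = self.x.shape
        if self.y.shape != (m, n):
            raise PairedDataError(
                f"class matrices disagree in shape: {self.x.shape} vs {self.y.shape}"
            )
        if m < 1:
            raise PairedDataError("need at least one feature")
        if n < 2:
            raise PairedDataError("need at least two patients")
        if len(self.feature_ids) != m:
            raise PairedDataError("feature_ids length does not match matrix")
        if len(self.patient_ids) != n:
            raise PairedDataError("patient_ids length does not match matrix")
        if len(set(self.feature_ids)) != m:
            raise PairedDataError("duplicate feature id")
        if len(set(self.patient_ids)) != n:
            raise PairedDataError("duplicate patient id")
        for name, mat in (("x", self.x), ("y", self.y)):
            if not np.isfinite(mat).all():
                i, j = np.argwhere(~np.isfinite(mat))[0]
                raise InvalidIntensityError(
                    f"invalid intensity in class {name} at feature "
                    f"{self.feature_ids[i]!r}, patient {self.patient_ids[j]!r}"
                )
            if (mat <= 0).any():
                i, j = np.argwhere(mat <= 0)[0]
                raise InvalidIntensityError(
                    f"non-positive intensity {mat[i, j]!r} in class {name} at "
                    f"feature {self.feature_ids[i]!r}, patient {self.patient_ids[j]!r}"
                )

    @property
    def n_features(self) -> int:
        return self.x.shape[0]

    @property
    def n_patients(self) -> int:
        return self.x.shape[1]

    def swap_classes(self) -> "PairedExpressionMatrix":
        """Return a copy with the tumour and normal roles exchanged."""
        return PairedExpressionMatrix(
            self.feature_ids.copy(), self.patient_ids.copy(),
            self.y.copy(), self.x.copy(),
        )

    def subset_patients(self, idx: np.ndarray) -> "PairedExpressionMatrix":
        """Restrict (or resample, with repeats relabelled) to patients ``idx``."""
        idx = np.asarray(idx)
        pids = np.array(
            [f"{self.patient_ids[k]}#{r}" for r, k in enumerate(idx)], dtype=object
        )
        return PairedExpressionMatrix(
            self.feature_ids.copy(), pids, self.x[:, idx], self.y[:, idx]
        )


@dataclass
class PairingManifest:
    """Rows of (sample_id, patient_id, class_label) defining the pairing."""

    rows: pd.DataFrame  # columns: sample_id, patient_id, class

    # patient -> (x_sample, y_sample), insertion-ordered
    pairs: dict = field(init=False)

    def __post_init__(self) -> None:
        df = self.rows
        required = {"sample_id", "patient_id", "class"}
        if not required.issubset(df.columns):
            raise PairedDataError(
                f"manifest must have columns {sorted(required)}, got {list(df.columns)}"
            )
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise PairedDataError(f"duplicate sample id {dup!r} in manifest")
        pairs: dict = {}
        for patient, grp in df.groupby("patient_id", sort=False):
            labels = [str(c).strip().lower() for c in grp["class"]]
            xs = [s for s, c in zip(grp["sample_id"], labels) if c in _X_LABELS]
            ys = [s for s, c in zip(grp["sample_id"], labels) if c in _Y_LABELS]
            bad = [c for c in labels if c not in _X_LABELS | _Y_LABELS]
            if bad:
                raise PairedDataError(
                    f"unrecognised class label {bad[0]!r} for patient {patient!r}"
                )
            if len(xs) != 1 or len(ys) != 1:
                raise UnpairedSampleError(
                    f"unpaired sample: patient {patient!r} has {len(xs)} normal and "
                    f"{len(ys)} tumour samples (expected exactly one of each)"
                )
            pairs[patient] = (xs[0], ys[0])
        self.pairs = pairs

    @property
    def patient_ids(self) -> list:
        return list(self.pairs)


def read_pairing_manifest(path) -> PairingManifest:
    """Read a TSV manifest with columns sample_id, patient_id, class."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    return PairingManifest(df)


def read_paired_matrix(
    matrix_path,
    manifest_path,
    floor_eps: float = 0.01,
) -> PairedExpressionMatrix:
    """Read an expression TSV plus pairing manifest into a validated matrix.

    The matrix file has a header of sample ids and a first column of feature
    ids (header literally ``feature_id``).  Zero or negative intensities are
    floored at ``floor_eps`` with a warning; ``floor_eps=None`` disables
    flooring and makes them an error.
    """
    manifest = read_pairing_manifest(manifest_path)
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise PairedDataError(f"duplicate feature id {dup!r} in matrix")

    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            feat = bad[0] if len(bad) else df.index[df[col].isna()][0]
            raise InvalidIntensityError(
                f"invalid intensity {df.loc[feat, col]!r} at feature {feat!r}, "
                f"sample {col!r}"
            )

    missing = [
        s for pair in manifest.pairs.values() for s in pair if s not in df.columns
    ]
    if missing:
        raise PairedDataError(f"manifest sample {missing[0]!r} not found in matrix")

    values = df.to_numpy(dtype=float)
    n_floored = 0
    if floor_eps is not None:
        mask = values <= 0
        n_floored = int(mask.sum())
        if n_floored:
            values = np.where(mask, floor_eps, values)
            warnings.warn(
                f"floored {n_floored} non-positive intensity value(s) at {floor_eps}",
                stacklevel=2,
            )
    col_pos = {c: k for k, c in enumerate(df.columns)}
    patients = manifest.patient_ids
    x_cols = [col_pos[manifest.pairs[p][0]] for p in patients]
    y_cols = [col_pos[manifest.pairs[p][1]] for p in patients]
    pem = PairedExpressionMatrix(
        feature_ids=df.index.to_numpy(dtype=object),
        patient_ids=np.array(patients, dtype=object),
        x=values[:, x_cols],
        y=values[:, y_cols],
        n_floored=n_floored,
    )
    return pem


RESULT_COLUMNS = [
    "feature_id",
    "n_pairs",
    "t_plus",
    "t_minus",
    "n_zero_diffs",
    "misclassification_count",
    "misclassification_rate",
    "r_plus",
    "r_minus",
    "z_value",
    "p_mwt",
    "p_bootstrap",
    "fold_change",
    "direction",
    "cds_flag",
    "selected_strict",
    "selected_relaxed",
]


def sort_results(table: pd.DataFrame) -> pd.DataFrame:
    """Deterministic result order: p ascending, |z| descending, id ascending."""
    key = table.assign(_absz=table["z_value"].abs())
    key = key.sort_values(
        by=["p_mwt", "_absz", "feature_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return key.drop(columns="_absz").reset_index(drop=True)


def write_results(table: pd.DataFrame, path) -> None:
    """Write a results table as TSV in the canonical column set and order."""
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise PairedDataError(f"results table missing columns {missing}")
    out = sort_results(table[RESULT_COLUMNS].copy())
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results(path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")
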