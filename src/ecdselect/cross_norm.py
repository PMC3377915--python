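"""Cross-normalization (CN) and per-pair differences.

CN rescales each class of a paired expression matrix by the *opposite*
class's per-feature mean: tumour values are divided by the normal-class
mean X̄_j and normal values by the tumour-class mean Ȳ_j.  For a feature
with a genuine disease effect this inflates the tumour ratios and deflates
the normal ratios, widening the gap between the classes before the paired
differences d_ij = y_cn_ij - x_cn_ij are taken.  The transform is
dimensionless and invariant under a common positive rescaling of all raw
intensities.

The division-by-opposite-mean form is one of several algebraically
plausible CN variants; it is the package default and alternatives
(subtracting the opposite-class mean) are selectable by strategy name.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .paired_data import PairedExpressionMatrix

__all__ = [
    "ClassMeans",
    "CNMatrix",
    "DifferenceMatrix",
    "class_means",
    "cross_normalize",
    "paired_differences",
    "CN_STRATEGIES",
]


@dataclass
class ClassMeans:
    """Per-feature arithmetic means of each class across patients."""

    x_bar: np.ndarray  # length M, strictly positive
    y_bar: np.ndarray

    def __post_init__(self) -> None:
        if (self.x_bar <= 0).any() or (self.y_bar <= 0).any():
            raise ValueError("class means must be strictly positive")


@dataclass
class CNMatrix:
    """Cross-normalized intensities (dimensionless ratios), M x N per class."""

    x_cn: np.ndarray
    y_cn: np.ndarray


@dataclass
class DifferenceMatrix:
    """Per-pair differences of cross-normalized values and their feature means."""

    d: np.ndarray       # M x N
    d_bar: np.ndarray   # length M


def class_means(pem: PairedExpressionMatrix) -> ClassMeans:
    """Arithmetic mean of each class across the N patients, per feature."""
    return ClassMeans(x_bar=pem.x.mean(axis=1), y_bar=pem.y.mean(axis=1))


def _cn_divide(pem: PairedExpressionMatrix, means: ClassMeans) -> CNMatrix:
    return CNMatrix(
        x_cn=pem.x / means.y_bar[:, None],
        y_cn=pem.y / means.x_bar[:, None],
    )


def _cn_subtract(pem: PairedExpressionMatrix, means: ClassMeans) -> CNMatrix:
    # additive variant; not scale-invariant, provided for comparison only
    return CNMatrix(
        x_cn=pem.x - means.y_bar[:, None],
        y_cn=pem.y - means.x_bar[:, None],
    )


CN_STRATEGIES = {"divide": _cn_divide, "subtract": _cn_subtract}


def cross_normalize(
    pem: PairedExpressionMatrix, strategy: str = "divide"
) -> CNMatrix:
    """Rescale each class by the opposite class's per-feature mean."""
    try:
        fn = CN_STRATEGIES[strategy]
    except KeyError:
        raise ValueError(
            f"unknown CN strategy {strategy!r}; choose from {sorted(CN_STRATEGIES)}"
        ) from None
    return fn(pem, class_means(pem))


def paired_differences(cn: CNMatrix) -> DifferenceMatrix:
    """Per-pair differences d_ij = y_cn_ij - x_cn_ij and feature means D̄_j."""
    d = cn.y_cn - cn.x_cn
    if not np.isfinite(d).all():
        raise ValueError("non-finite difference encountered")
    return DifferenceMatrix(d=d, d_bar=d.mean(axis=1))


def cn_differences(
    pem: PairedExpressionMatrix, strategy: str = "divide"
) -> DifferenceMatrix:
    """Convenience: cross-normalize then take paired differences."""
    return paired_differences(cross_normalize(pem, strategy))
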