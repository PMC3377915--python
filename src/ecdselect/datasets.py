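"""Bundled reference tables from the published 27-pair lung adenocarcinoma study.

These small tables record published *outputs* of the original 27-pair
tumour/adjacent-tissue analysis on the Affymetrix U133A platform.  They let
users reproduce the study's summary arithmetic (marker coverage of the
strict and relaxed discriminative signatures, misclassification-rate
comparisons across feature-selection methods) without access to the raw
GEO intensities, and serve as fixed inputs to the acceptance checks.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

__all__ = [
    "U133A_PROBE_SETS",
    "U133A_REFSEQ_UNIVERSE",
    "STUDY_N_PAIRS",
    "marker_coverage_table",
    "marker_coverage",
    "GE2_ERROR_COUNTS",
    "MUTAGENESIS_COMMON",
]

# Affymetrix U133A platform constants
U133A_PROBE_SETS = 22283        # probe sets on the array (Bonferroni multiplier)
U133A_REFSEQ_UNIVERSE = 13074   # non-redundant RefSeq genes (overlap universe)
STUDY_N_PAIRS = 27              # matched tumour/adjacent pairs in the study

# Literature-curated early-diagnostic lung AC marker genes and whether each
# is covered by the strict (zero-error) discriminative signature, its
# relaxed extension (up to 3 misclassification errors), and the EDGE
# comparator.  Genes lacking a U133A probe set cannot be covered and are
# excluded from coverage denominators.
_MARKER_COVERAGE_TSV = """\
gene\tin_strict_signature\tin_extended_set\tin_edge\thas_probe_sets
ATP10B\tYES\tYES\tNO\tTRUE
AURKA\tYES\tYES\tYES\tTRUE
CLDN5\tYES\tYES\tYES\tTRUE
COL11A1\tYES\tYES\tYES\tTRUE
DNAI2\tNO\tYES\tNO\tTRUE
FABP6\tNO\tNO\tNO\tTRUE
HIGD1B\tYES\tYES\tYES\tTRUE
ILF3\tYES\tYES\tNO\tTRUE
IQCG\tNO\tNO\tNO\tTRUE
LRRC48\tNO\tNO\tNO\tTRUE
LRRC50\tNO\tNO\tNO\tTRUE
MCM6\tYES\tYES\tNO\tTRUE
MUC4\tNO\tYES\tNO\tTRUE
RARRES2\tYES\tYES\tYES\tTRUE
RFTN1\tYES\tYES\tNO\tTRUE
SCG5\tYES\tYES\tNO\tTRUE
SCGB1A1\tNO\tYES\tYES\tTRUE
SFTPA2\tYES\tYES\tNO\tTRUE
SFTPB\tNO\tYES\tNO\tTRUE
SFTPC\tYES\tYES\tYES\tTRUE
TFPI2\tYES\tYES\tYES\tTRUE
TM4SF4\tNO\tYES\tNO\tTRUE
TOP2A\tYES\tYES\tYES\tTRUE
XAGE1A\tYES\tYES\tYES\tTRUE
XAGE1B\tNO\tNO\tNO\tFALSE
XAGE1C\tNO\tNO\tNO\tFALSE
XAGE1D\tNO\tNO\tNO\tFALSE
XAGE1E\tNO\tNO\tNO\tFALSE
"""

# Published counts of probe sets (out of the 2,829-strong top list per
# method) with two or more misclassified sample pairs, on cross-normalized
# data.
GE2_ERROR_COUNTS = {
    "ECD": (0, 2829),
    "WT": (90, 2829),
    "EDGE": (111, 2829),
    "t-test": (105, 2829),
    "PAM": (335, 2829),
}

# Published mutagenesis-site accounting for the genes common to the
# discriminative signature and the literature meta-signature: 98 of the 499
# common genes encode proteins with experimentally characterized
# mutagenesis sites.
MUTAGENESIS_COMMON = {"n_with_sites": 98, "n_common_genes": 499}


def marker_coverage_table() -> pd.DataFrame:
    """The curated marker-gene coverage table as a DataFrame."""
    df = pd.read_csv(StringIO(_MARKER_COVERAGE_TSV), sep="\t")
    for col in ("in_strict_signature", "in_extended_set", "in_edge"):
        df[col] = df[col] == "YES"
    df["has_probe_sets"] = df["has_probe_sets"].astype(str).str.upper() == "TRUE"
    return df


def marker_coverage(column: str = "in_strict_signature") -> tuple[int, int, float]:
    """Coverage of the curated markers by a signature column.

    Returns (covered, eligible, percent) where eligible counts only genes
    with at least one U133A probe set.
    """
    df = marker_coverage_table()
    eligible = df[df["has_probe_sets"]]
    covered = int(eligible[column].sum())
    n = len(eligible)
    return covered, n, 100.0 * covered / n
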