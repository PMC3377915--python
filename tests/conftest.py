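import numpy as np
import pandas as pd
import pytest

from ecdselect import PairedExpressionMatrix


@pytest.fixture
def small_pem() -> PairedExpressionMatrix:
    """One strongly up-regulated feature and one null-ish feature, 3 patients."""
    return PairedExpressionMatrix(
        feature_ids=np.array(["gA", "gB"], dtype=object),
        patient_ids=np.array(["P1", "P2", "P3"], dtype=object),
        x=np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]),
        y=np.array([[2.0, 4.0, 6.0], [5.0, 4.0, 6.0]]),
    )


@pytest.fixture
def random_pem() -> PairedExpressionMatrix:
    rng = np.random.default_rng(42)
    m, n = 30, 9
    return PairedExpressionMatrix(
        feature_ids=np.array([f"f{i}" for i in range(m)], dtype=object),
        patient_ids=np.array([f"p{i}" for i in range(n)], dtype=object),
        x=rng.lognormal(5, 1, (m, n)),
        y=rng.lognormal(5, 1, (m, n)),
    )


def write_matrix_files(tmp_path, df: pd.DataFrame, manifest: pd.DataFrame):
    matrix_path = tmp_path / "matrix.tsv"
    manifest_path = tmp_path / "manifest.tsv"
    df.to_csv(matrix_path, sep="\t")
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return matrix_path, manifest_path


@pytest.fixture
def tsv_pair(tmp_path):
    """A well-formed 2-feature, 3-patient matrix + manifest on disk."""
    df = pd.DataFrame(
        {
            "s1n": [1.0, 5.0], "s1t": [2.0, 5.0],
            "s2n": [2.0, 5.0], "s2t": [4.0, 4.0],
            "s3n": [3.0, 5.0], "s3t": [6.0, 6.0],
        },
        index=pd.Index(["gA", "gB"], name="feature_id"),
    )
    manifest = pd.DataFrame(
        {
            "sample_id": ["s1n", "s1t", "s2n", "s2t", "s3n", "s3t"],
            "patient_id": ["P1", "P1", "P2", "P2", "P3", "P3"],
            "class": ["normal", "tumour", "normal", "tumour", "normal", "tumour"],
        }
    )
    return write_matrix_files(tmp_path, df, manifest)
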