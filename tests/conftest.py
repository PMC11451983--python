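import numpy as np
import pandas as pd
import pytest

from cogtex.io import ExpressionMatrix, Scale
from cogtex.synthetic import CohortConfig, PlantedPair, generate_cohort


@pytest.fixture
def toy_gct(tmp_path):
    """A 2-gene x 3-sample GCT file."""
    path = tmp_path / "toy.gct"
    path.write_text(
        "#1.2\n2\t3\nName\tDescription\tS-A-1\tS-B-1\tS-C-1\n"
        "ENSG00000001.5\tgeneA\t1.0\t2.5\t0.0\n"
        "ENSG00000002.1\tgeneB\t10.0\t0.1\t3.0\n"
    )
    return path


@pytest.fixture
def metadata_files(tmp_path):
    attr = tmp_path / "attrs.tsv"
    attr.write_text(
        "SAMPID\tSMTSD\tSMNABTCH\tSMGEBTCH\tSMTSISCH\n"
        "S-A-1\tLung\tB1\tG1\t100\n"
        "S-B-1\tLung\tB1\t\t200\n"
        "S-C-1\tLiver\tB2\tG2\t700\n"
    )
    pheno = tmp_path / "pheno.tsv"
    pheno.write_text(
        "SUBJID\tSEX\tAGE\nS-A\t1\t30\nS-B\t2\t50-59\nS-C\t1\t70\n"
    )
    return attr, pheno


@pytest.fixture(scope="session")
def small_cohort():
    """5 tissues x 30 samples, 60 genes, no planted pairs."""
    return generate_cohort(CohortConfig(n_tissues=5, samples_per_tissue=30, n_genes=60, seed=7))


@pytest.fixture(scope="session")
def planted_cohort():
    """A larger cohort with two pairs of every coexpression scenario."""
    scenarios = ["SYS_ONLY", "TISSUE_ONLY", "XOR", "TISSUE_EXCEPTION", "NONLINEAR", "BOTH", "NULL"]
    pairs = [
        PlantedPair(2 * i + r * len(scenarios) * 2, 2 * i + r * len(scenarios) * 2 + 1, s)
        for r in range(2)
        for i, s in enumerate(scenarios)
    ]
    cfg = CohortConfig(
        n_tissues=14, samples_per_tissue=80, n_genes=60, seed=5, planted_pairs=pairs
    )
    return generate_cohort(cfg)


def expr_from_array(arr, scale=Scale.TPM, prefix="g"):
    arr = np.asarray(arr, float)
    genes = [f"{prefix}{i}" for i in range(arr.shape[0])]
    samples = [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), scale)
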