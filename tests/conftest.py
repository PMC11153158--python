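import numpy as np
import pandas as pd
import pytest

from dosagecomp.datatypes import ExpressionMatrix, Karyotype, validate_annotation
from dosagecomp.integrate import build_integrated_cohort
from dosagecomp.simulate import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Modest noisy cohort shared by read-only tests."""
    spec = CohortSpec(n_strains=80, n_chromosomes=8, genes_per_chromosome=40,
                      seed=11)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Deterministic cohort: mRNA slope exactly 1, no noise or missingness."""
    spec = CohortSpec(n_strains=60, n_chromosomes=8, genes_per_chromosome=30,
                      mrna_noise_sd=0.0, protein_noise_sd=0.0,
                      mrna_slope_sd=0.0, missing_rate=0.0,
                      trans_proteasome_shift=0.0, seed=7)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def noise_free_integrated(noise_free_cohort):
    c = noise_free_cohort
    return build_integrated_cohort(
        {"mRNA": c.mrna, "protein": c.protein}, c.karyotypes, c.annotation
    )


@pytest.fixture
def tiny_annotation():
    return validate_annotation(
        pd.DataFrame(
            {
                "chromosome": ["chr1", "chr1", "chr2", "chr2"],
                "position_index": [0, 1, 0, 1],
                "complex_member": [True, False, False, True],
            },
            index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
        )
    )


@pytest.fixture
def tiny_karyotypes():
    chroms = {"chr1": 2, "chr2": 2}
    return [
        Karyotype("eu1", 2, dict(chroms)),
        Karyotype("eu2", 2, dict(chroms)),
        Karyotype("eu3", 2, dict(chroms)),
        Karyotype("tri", 2, {"chr1": 3, "chr2": 2}),
    ]


def make_matrix(values, genes, strains, layer="protein"):
    return ExpressionMatrix(
        layer,
        pd.DataFrame(np.asarray(values, dtype=float),
                     index=pd.Index(genes, name="gene_id"), columns=strains),
    )
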