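import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from embedeval import GenotypeMatrix, SubjectTable, make_genotype_matrix

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


def variant_frame(n, chrom="1", spacing=1_000_000):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos_bp": 1 + np.arange(n) * spacing,
            "id": [f"var{j:05d}" for j in range(n)],
            "effect_allele": "A",
            "other_allele": "B",
        }
    )


def toy_genotypes(dosages, subject_ids=None, **kw) -> GenotypeMatrix:
    dosages = np.asarray(dosages, dtype=float)
    n, v = dosages.shape
    ids = subject_ids or [f"S{i:04d}" for i in range(n)]
    return make_genotype_matrix(ids, dosages, variant_frame(v, **kw))


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture
def small_genotypes(rng) -> GenotypeMatrix:
    """60 subjects x 12 variants, common alleles, no missingness."""
    maf = rng.uniform(0.2, 0.5, size=12)
    return toy_genotypes(rng.binomial(2, maf, size=(60, 12)))


@pytest.fixture
def subject_table(rng, small_genotypes) -> SubjectTable:
    ids = small_genotypes.subject_ids
    df = pd.DataFrame(
        {
            "age": rng.uniform(40, 69, size=len(ids)),
            "sex": rng.integers(0, 2, size=len(ids)).astype(float),
        },
        index=ids,
    )
    return SubjectTable(df)
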