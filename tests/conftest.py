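import numpy as np
import pandas as pd
import pytest

from polyres.io import GenotypeStudy


def make_study(rng, n_samples=30, n_variants=8, study_id="s1",
               case_fraction=0.5, n_pcs=2):
    """Small random study for unit tests (integer dosages, A/G alleles)."""
    chroms = [str(c % 4 + 1) for c in range(n_variants)]
    variants = pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(n_variants)],
        "chrom": chroms,
        "pos": [1000 + 500 * i for i in range(n_variants)],
        "effect_allele": "A",
        "other_allele": "G",
    })
    freqs = rng.uniform(0.1, 0.5, n_variants)
    dosages = rng.binomial(2, freqs, size=(n_samples, n_variants)).astype(float)
    status = np.where(rng.uniform(size=n_samples) < case_fraction, 2, 1)
    samples = pd.DataFrame({
        "sample_id": [f"{study_id}_{i:03d}" for i in range(n_samples)],
        "status": status,
        "sex": rng.integers(1, 3, n_samples),
        "age": rng.uniform(60, 90, n_samples).round(1),
    })
    for k in range(n_pcs):
        samples[f"PC{k + 1}"] = rng.standard_normal(n_samples)
    return GenotypeStudy(study_id=study_id, variants=variants,
                        dosages=dosages, samples=samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_study(rng):
    return make_study(rng)
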