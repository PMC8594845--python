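import numpy as np
import pandas as pd
import pytest

from wsplab import PhenotypeModelParams, SimulationSeed, simulate_individuals


@pytest.fixture
def seed():
    return SimulationSeed(12345, "tests")


@pytest.fixture
def null_params():
    """Two variants with no effects: phenotype is pure noise plus age/sex."""
    return PhenotypeModelParams(
        variant_count=2,
        allele_freqs=(0.3, 0.5),
        variant_effects=(0.0, 0.0),
        noise_sd=1.0,
    )


@pytest.fixture
def effect_params():
    return PhenotypeModelParams(
        variant_count=2,
        allele_freqs=(0.3, 0.5),
        variant_effects=(0.3, 0.2),
        age_effect=0.01,
        sex_effect=0.1,
        noise_sd=1.0,
    )


@pytest.fixture
def small_cohort(effect_params, seed):
    return simulate_individuals(effect_params, 200, seed.child("small-cohort"))


def toy_paired_cohort(scores_m, scores_f, extra_cols=None):
    """Minimal cohort with named males/females and given assortment scores."""
    ids = list(scores_m) + list(scores_f)
    frame = pd.DataFrame(
        {
            "id": ids,
            "sex": [1] * len(scores_m) + [0] * len(scores_f),
            "A": list(scores_m.values()) + list(scores_f.values()),
        }
    )
    if extra_cols:
        for name, values in extra_cols.items():
            frame[name] = [values[i] for i in ids]
    return frame
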