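import numpy as np
import pandas as pd
import pytest

from vitreomics.synthetic import build_cohort, simulate_sample_peaks


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort: ~60 truth peptides, 20 cases / 15 controls."""
    return build_cohort(n_proteins=4, group_sizes=(20, 15), seed=0)


@pytest.fixture(scope="session")
def small_sample(small_cohort):
    return simulate_sample_peaks(small_cohort, "case01")


def jittered_feature_tables(
    masses, times, n_samples, rng, mass_jitter_ppm=5.0, time_jitter_min=0.05
):
    """Per-sample feature tables for given truth coordinates, with jitter."""
    tables = {}
    for s in range(n_samples):
        m = masses * (1.0 + rng.normal(0.0, mass_jitter_ppm * 1e-6, masses.size))
        t = times + rng.normal(0.0, time_jitter_min, times.size)
        tables[f"s{s:02d}"] = pd.DataFrame(
            {
                "neutral_mass": m,
                "migration_time_min": t,
                "intensity": rng.lognormal(np.log(1e4), 0.5, masses.size),
            }
        )
    return tables
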