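import numpy as np
import pandas as pd
import pytest

from wgpred import SimConfig, simulate_cohort
from wgpred.data import Pedigree


@pytest.fixture(scope="session")
def small_cohort():
    """Family cohort with injected missingness and planted rare markers."""
    cfg = SimConfig(
        n_founders=80,
        n_offspring=140,
        n_markers=500,
        n_low_maf_markers=8,
        missing_rate_range=(0.0, 0.25),
        seed=101,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """Complete-genotype cohort (no missingness) for model-fitting tests."""
    cfg = SimConfig(
        n_founders=80,
        n_offspring=120,
        n_markers=1000,
        missing_rate_range=(0.0, 0.0),
        seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def big_cohort():
    """Large cohort for Monte-Carlo convergence checks (n=5000, p=2000)."""
    cfg = SimConfig(
        n_founders=2000,
        n_offspring=3000,
        n_markers=2000,
        missing_rate_range=(0.0, 0.0),
        seed=42,
    )
    return simulate_cohort(cfg)


def random_pedigree(rng: np.random.Generator, n_founders: int, n_offspring: int) -> Pedigree:
    """Ad-hoc two-generation pedigree with arbitrary mating structure,
    built directly (independent of the package generator) for oracle tests."""
    rows = []
    for i in range(n_founders):
        rows.append(
            {"individual_id": f"f{i}", "sire_id": None, "dam_id": None,
             "sex": "M" if i % 2 == 0 else "F", "generation": 0, "cohort": "original"}
        )
    males = [f"f{i}" for i in range(0, n_founders, 2)]
    females = [f"f{i}" for i in range(1, n_founders, 2)]
    for j in range(n_offspring):
        rows.append(
            {"individual_id": f"o{j}",
             "sire_id": males[rng.integers(len(males))],
             "dam_id": females[rng.integers(len(females))],
             "sex": "M" if rng.random() < 0.5 else "F",
             "generation": 1, "cohort": "offspring"}
        )
    return Pedigree(pd.DataFrame(rows))
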