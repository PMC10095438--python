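import numpy as np
import pandas as pd
import pytest

from eqtmkit import simulate
from eqtmkit.methylation import CELL_TYPES


def make_samples(n_cases=4, n_controls=6, seed=0) -> pd.DataFrame:
    """Minimal valid sample table with Dirichlet cell fractions."""
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    tab = pd.DataFrame(
        {
            "group": ["case"] * n_cases + ["control"] * n_controls,
            "age": rng.uniform(3, 18, size=n).round(2),
            "sex": rng.choice(["M", "F"], size=n),
        },
        index=pd.Index([f"S{i + 1:03d}" for i in range(n)], name="sample_id"),
    )
    frac = rng.dirichlet((6, 9, 3, 3, 6, 33), size=n)
    for j, ct in enumerate(CELL_TYPES):
        tab[f"cf_{ct}"] = frac[:, j]
    return tab


@pytest.fixture(scope="session")
def small_cohort() -> simulate.Cohort:
    """A reduced-scale cohort with planted effects, shared across tests."""
    cfg = simulate.SimConfig(seed=42, n_cpgs=600, n_genes=300, n_chromosomes=3)
    return simulate.generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort() -> simulate.Cohort:
    """The study-scale default cohort (20,000 CpGs, 2,000 genes, 12+51)."""
    return simulate.generate_cohort(simulate.SimConfig(seed=7))
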