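import numpy as np
import pandas as pd
import pytest

import gwasaudit as ga


@pytest.fixture(scope="session")
def panel20k():
    return ga.simulate_ld_scores(20_000, seed=1)


@pytest.fixture(scope="session")
def strong_pair(panel20k):
    """A full/down pair with no cohort heterogeneity and enough signal to
    yield genome-wide significant SNPs (the regime of the concordance
    checks)."""
    cfg = ga.SimConfig(
        h2=0.5, heterogeneity=0.0, seed=10,
        cohorts=[ga.CohortSpec("retained", 0.5, 200_000),
                 ga.CohortSpec("restricted", 0.5, 100_000)],
        drop_cohorts=("restricted",),
    )
    full, down, truth = ga.simulate_sumstats_pair(cfg, panel20k)
    return full, down, truth


def small_table(n=5, seed=0):
    """A tiny valid summary-statistic frame for unit tests."""
    rng = np.random.default_rng(seed)
    se = rng.uniform(0.01, 0.05, n)
    beta = rng.normal(0, 0.05, n)
    z = beta / se
    from scipy import stats

    return pd.DataFrame({
        "snp_id": [f"rs{i+1}" for i in range(n)],
        "chrom": "1", "pos": np.arange(1, n + 1),
        "a1": ["A", "C", "A", "G", "T"][:n] if n <= 5 else "A",
        "a2": ["G", "T", "C", "A", "C"][:n] if n <= 5 else "G",
        "beta": beta, "se": se, "z": z,
        "p": 2 * stats.norm.sf(np.abs(z)),
        "n": 10_000.0,
    })
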