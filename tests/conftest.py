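"""Shared fixtures.

The replicate-simulation fixtures are session-scoped because the method
comparison (GBLUP vs weighted GBLUP across replicates) is consumed by several
tests; each replicate is an independent seeded population.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import wgblup as w
from wgblup.pipeline import default_cutoff, run_study

N_REPLICATES = 20

# Desk-scale forward-validation scenario: three training generations
# (400 founders + 2 x 300) and one validation generation of 300, genotyped at
# 1000 SNPs, trait h2 = 0.4.
SCENARIO = dict(
    n_founders=400,
    n_generations=4,
    offspring_per_mating=2,
    matings_per_generation=(150, 150, 150),
    n_snps=1000,
    n_qtl=10,
    h2_true=0.4,
)


def _replicate(seed: int, qtl_variance_fraction: float, schemes: list[dict]) -> pd.DataFrame:
    cfg = w.SimConfig(
        **SCENARIO, qtl_variance_fraction=qtl_variance_fraction, seed=seed
    )
    sim = w.simulate(cfg)
    res = run_study(
        sim.pedigree,
        sim.genotypes,
        sim.phenotypes,
        w.ModelSpec(),
        schemes=schemes,
        cutoff_date=default_cutoff(cfg),
    )
    rows = res.report.rows.copy()
    rows["seed"] = seed
    # extra columns for the truth-based directional checks
    vids = list(res.split.validation_ids)
    tbv = sim.true_breeding_values.loc[vids]
    rows["cor_tbv_pblup"] = float(np.corrcoef(res.pblup.ebv.loc[vids], tbv)[0, 1])
    first_trace = res.traces[next(iter(res.traces))]
    rows["cor_tbv_gblup"] = float(np.corrcoef(first_trace.gebv(1).loc[vids], tbv)[0, 1])
    return rows


@pytest.fixture(scope="session")
def major_qtl_replicates() -> pd.DataFrame:
    """20 replicates, 10 QTL explaining 50% of additive variance.

    nonlinearA (CT=1.25, limit 20) is run to iteration 4 and the linear scheme
    to iteration 10; iteration 1 of each trace is plain GBLUP.
    """
    schemes = [
        {"kind": "nonlinearA", "ct": 1.25, "exponent_limit": 20, "n_iterations": 4},
        {"kind": "linear", "n_iterations": 10},
    ]
    return pd.concat(
        [_replicate(1000 + r, 0.5, schemes) for r in range(N_REPLICATES)],
        ignore_index=True,
    )


@pytest.fixture(scope="session")
def polygenic_replicates() -> pd.DataFrame:
    """20 replicates of the same scenario with purely polygenic determinism."""
    schemes = [
        {"kind": "nonlinearA", "ct": 1.25, "exponent_limit": 20, "n_iterations": 4},
    ]
    return pd.concat(
        [_replicate(2000 + r, 0.0, schemes) for r in range(N_REPLICATES)],
        ignore_index=True,
    )


@pytest.fixture(scope="session")
def small_sim() -> w.SimOutput:
    cfg = w.SimConfig(
        n_founders=60,
        n_generations=3,
        offspring_per_mating=2,
        matings_per_generation=(25, 25),
        n_snps=150,
        n_qtl=5,
        seed=42,
    )
    return w.simulate(cfg)
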