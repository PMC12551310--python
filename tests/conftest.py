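"""Shared fixtures: synthetic cohorts at several study conditions.

The expensive full-scale cohorts (100 diploids, ~1 Mbp) are session-scoped
and shared between the acceptance tests; unit tests use small cohorts.
"""

from __future__ import annotations

import numpy as np
import pytest

from collapsemask import (
    FilterConfig,
    SimParams,
    apply_filters,
    run_pipeline,
    simulate_cohort,
    truth_compare,
)

# analysis filter used for all simulation experiments (see docs/methods.md)
SIM_FILTER = FilterConfig(min_gq=0, min_depth_per_genotype=2, max_missing_fraction=0.1)


def run_setting(seed, **params):
    """Simulate one cohort, run the full pipeline, evaluate against truth."""
    sim = simulate_cohort(SimParams(seed=seed, **params))
    table = apply_filters(sim.table, SIM_FILTER)
    keep = np.isin(sim.table.pos, table.pos)
    truth = sim.truth.snp_labels[keep]
    result = run_pipeline(table, seed=seed)
    report = truth_compare(result.classifications, truth, sim.truth.intervals)
    return sim, table, truth, result, report


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort for unit tests: 40 diploids, 300 kb, 10% duplications."""
    sim = simulate_cohort(
        SimParams(n_ind=40, genome_length=300_000, dup_fraction=0.1, seed=11)
    )
    table = apply_filters(sim.table, SIM_FILTER)
    keep = np.isin(sim.table.pos, table.pos)
    return sim, table, sim.truth.snp_labels[keep]


@pytest.fixture(scope="session")
def small_pipeline(small_cohort):
    sim, table, truth = small_cohort
    result = run_pipeline(table, seed=11)
    return sim, table, truth, result


@pytest.fixture(scope="session")
def recall_grid():
    """Full-scale runs at the four (dup_fraction, F_IS) study settings."""
    out = {}
    for fis, dup in [(0.0, 0.1), (0.9, 0.1), (0.0, 0.5), (0.9, 0.5)]:
        out[(fis, dup)] = run_setting(
            1, n_ind=100, mean_depth=10.0, fis=fis, dup_fraction=dup,
            genome_length=1_000_000,
        )
    return out
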