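"""Shared fixtures: the default synthetic scenario and one full pipeline run.

Session-scoped so the end-to-end objects are computed once and shared by the
module tests and the acceptance tests.
"""

from __future__ import annotations

import pytest

from satscan.io_core import GenomeSequence
from satscan.pipeline import RunConfig, run_all
from satscan.profile_model import SeedAlignment, build_profile
from satscan.synthetic_genome import SimParams, make_seed_alignment, simulate

SEED_ALN_ROWS = 20
SEED_ALN_DIVERGENCE = 0.03


def small_params(**overrides) -> SimParams:
    """A fast scenario for unit tests: 2 x 400 kb chromosomes."""
    defaults = dict(
        n_chrom=2,
        chrom_length=400_000,
        subtelomere_span=80_000,
        cent_copies=100,
        blocks_per_arm_mean=3.0,
        centromere_frac=(0.4, 0.6),
        inter_block_gap=(1_000, 3_000),
        seed=7,
    )
    defaults.update(overrides)
    return SimParams(**defaults)


@pytest.fixture(scope="session")
def default_scenario():
    params = SimParams(seed=42)
    genome, truth = simulate(params)
    return params, genome, truth


@pytest.fixture(scope="session")
def default_profile(default_scenario):
    _, _, truth = default_scenario
    seed = SeedAlignment(
        make_seed_alignment(truth.monomer, SEED_ALN_ROWS, SEED_ALN_DIVERGENCE, seed=1)
    )
    return build_profile(seed)


@pytest.fixture(scope="session")
def default_run(default_scenario, tmp_path_factory):
    """Full pipeline run on the default scenario (seed 42)."""
    params, genome, truth = default_scenario
    seed = SeedAlignment(
        make_seed_alignment(truth.monomer, SEED_ALN_ROWS, SEED_ALN_DIVERGENCE, seed=1)
    )
    cent = [GenomeSequence("CentSim1", truth.cent_monomer)]
    out = tmp_path_factory.mktemp("default_run")
    config = RunConfig(out_dir=str(out), seed=1)
    result = run_all(config, genome=genome, seed_alignment=seed, cent_repeats=cent)
    return params, genome, truth, result


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """Pipeline run on the small scenario, for cheap smoke checks."""
    params = small_params()
    genome, truth = simulate(params)
    seed = SeedAlignment(
        make_seed_alignment(truth.monomer, SEED_ALN_ROWS, SEED_ALN_DIVERGENCE, seed=1)
    )
    cent = [GenomeSequence("CentSim1", truth.cent_monomer)]
    out = tmp_path_factory.mktemp("small_run")
    config = RunConfig(out_dir=str(out), seed=3, n_reps=25)
    result = run_all(config, genome=genome, seed_alignment=seed, cent_repeats=cent)
    return params, genome, truth, result
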