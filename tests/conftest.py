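import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from covsex import SimConfig, analyze_cohort, simulate_cohort
from covsex.io_formats import GenotypeMatrix

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

logging.getLogger("covsex").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def xy_sim():
    """XY cohort at the cohort's nominal conditions with a clean dosage
    signal: fixed 4.4x depth, 30% hemizygous / 70% PAR, Poisson noise."""
    return simulate_cohort(SimConfig(
        seed=11, depth_fixed=4.4,
        par_fraction=0.7, hemizygous_fraction=0.3, diverged_fraction=0.0,
    ))


@pytest.fixture(scope="session")
def xy_sim_div():
    """XY cohort with diverged-gametolog regions (default region plan),
    fixed 4.4x depth so the heterozygosity contrast is well powered."""
    return simulate_cohort(SimConfig(seed=7, depth_fixed=4.4))


@pytest.fixture(scope="session")
def xy_report(xy_sim):
    return analyze_cohort(xy_sim.summary, xy_sim.sheet, xy_sim.windows,
                          xy_sim.track, xy_sim.genotypes)


def make_genotype_matrix(genotypes, depth, chromosome="chr12", positions=None):
    """Small GenotypeMatrix from explicit arrays (sites x samples)."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    depth = np.asarray(depth, dtype=np.int32)
    n_sites, n_samples = genotypes.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 10
    sites = pd.DataFrame({
        "chromosome": chromosome,
        "position": positions,
        "ref": "A",
        "alt": "G",
    })
    samples = [f"s{i + 1}" for i in range(n_samples)]
    return GenotypeMatrix(sites, genotypes, depth, samples)
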