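import numpy as np
import pytest

from hsctrace.filtering import build_pseudobulk, callable_fraction, filter_somatic
from hsctrace.phylogeny import build_tree, genotype_matrix, map_and_reassign
from hsctrace.regions import union
from hsctrace.simulate import SimulationParams, simulate_dataset


def analyze(truth, obs, members=("WT01", "WT02"), n_boot=30, seed=1):
    """Run filtering + tree building on a simulated dataset."""
    pb = build_pseudobulk(obs.table, members)
    catalog = filter_somatic(obs.table, pb)
    pb_regions = union(obs.callable_regions[members[0]],
                       obs.callable_regions[members[1]])
    for s in catalog.samples:
        catalog.callable_fraction[s] = callable_fraction(
            obs.callable_regions[s], pb_regions
        )
    matrix = genotype_matrix(catalog, obs.table)
    tree = build_tree(matrix, n_boot=n_boot, seed=seed)
    assignment = map_and_reassign(tree, matrix)
    return catalog, matrix, tree, assignment


@pytest.fixture(scope="session")
def driver_dataset():
    """One recipient: 10 colonies, driver clone of 5 acquired at 3.0 y."""
    params = SimulationParams(
        n_colonies=10, hsc_age=20.0, driver_time=3.0, clone_size=5, seed=11
    )
    truth, obs = simulate_dataset(params)
    return params, truth, obs


@pytest.fixture(scope="session")
def driver_analysis(driver_dataset):
    params, truth, obs = driver_dataset
    return (params, truth, obs, *analyze(truth, obs))


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free conditions: high coverage, full callable genome, no
    artifacts, polyclonal base with zero embryonic sharing."""
    params = SimulationParams(
        n_colonies=8, hsc_age=10.0, driver_time=2.0, clone_size=4,
        embryonic_split_burden=0.0, coverage_mean=40.0,
        callable_fraction_range=(1.0, 1.0), germline_count=50,
        artifact_rate=0.0, lowqual_count=0, seed=5,
    )
    truth, obs = simulate_dataset(params)
    return params, truth, obs
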