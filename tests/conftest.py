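"""Shared fixtures: one reference simulation and one fit of each kind,
computed once per session and reused across test modules."""

import numpy as np
import pytest

from floranet import (
    REFERENCE_X0,
    SPECIES,
    SynthConfig,
    calibrate,
    fit_decoupled,
    generate_dataset,
    generate_inputs,
    refine_full_system,
    reference_parameters,
    simulate,
)


@pytest.fixture(scope="session")
def ref_params():
    return reference_parameters()


@pytest.fixture(scope="session")
def inputs():
    return generate_inputs(SynthConfig(seed=0))


@pytest.fixture(scope="session")
def wt_traj(ref_params, inputs):
    return simulate(ref_params, inputs, REFERENCE_X0)


@pytest.fixture(scope="session")
def calibration(wt_traj):
    return calibrate(wt_traj)


@pytest.fixture(scope="session")
def noise_free_dataset():
    cfg = SynthConfig(seed=7, noise_cv=0.0)
    return generate_dataset(cfg, params=reference_parameters())


@pytest.fixture(scope="session")
def noise_free_fit(noise_free_dataset):
    """Two-stage fit of the noise-free dataset, shared by several tests."""
    problem = noise_free_dataset.fit_problem()
    params1, diag1 = fit_decoupled(problem, starts=12, seed=1)
    params2, diag2 = refine_full_system(problem, params1, max_nfev=60)
    return {
        "problem": problem,
        "decoupled": (params1, diag1),
        "refined": (params2, diag2),
    }


@pytest.fixture(scope="session")
def noisy_dataset():
    cfg = SynthConfig(seed=11, noise_cv=0.05)
    return generate_dataset(cfg, params=reference_parameters())


@pytest.fixture(scope="session")
def noisy_fit(noisy_dataset):
    problem = noisy_dataset.fit_problem()
    params1, diag1 = fit_decoupled(problem, starts=12, seed=3)
    params2, diag2 = refine_full_system(problem, params1, max_nfev=60)
    return {
        "problem": problem,
        "decoupled": (params1, diag1),
        "refined": (params2, diag2),
    }


@pytest.fixture(scope="session")
def first_points():
    return {g: REFERENCE_X0[g] for g in SPECIES}


@pytest.fixture(scope="session")
def hill_selection():
    """Model selection of the LFY->AP1 cooperativity on data generated with
    n = 1 and n = 3 (noise-free; decoupled scoring)."""
    from floranet import select_hill_coefficient

    out = {}
    for gen_n in (1, 3):
        cfg = SynthConfig(seed=21, noise_cv=0.0, n=gen_n)
        ds = generate_dataset(cfg, params=reference_parameters(n=gen_n))
        out[gen_n] = select_hill_coefficient(
            ds.fit_problem(), candidates=(1, 2, 3, 4, 5), starts=8, seed=2, refine=False
        )
    return out
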