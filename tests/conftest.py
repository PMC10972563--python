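import numpy as np
import pytest

import vesikin as vk


@pytest.fixture(scope="session")
def params():
    return vk.default_parameters()


@pytest.fixture(scope="session")
def state_space():
    return vk.enumerate_states()


@pytest.fixture(scope="session")
def genotype_sims(params):
    """Full 10-AP, 20-Hz simulations and metrics for all four genotypes."""
    out = {}
    for g in vk.GENOTYPES:
        traj = vk.simulate(params, genotype=g)
        out[g] = (traj, vk.per_stimulus_metrics(traj))
    return out


@pytest.fixture(scope="session")
def wt_traj(genotype_sims):
    return genotype_sims["wt"][0]


def flat_trajectory(params, t_end=0.5, n=501):
    """Hand-built resting trajectory: all pools constant, no fusion."""
    t = np.linspace(0.0, t_end, n)
    pi, S = vk.steady_state(params)
    occ = np.tile(pi, (n, 1))
    syt7 = np.tile(S, (n, 1))
    return vk.Trajectory(
        t=t,
        occupancies=occ,
        syt7=syt7,
        fused=np.zeros(n),
        params=params,
        ap_onsets=(0.0,),
    )
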