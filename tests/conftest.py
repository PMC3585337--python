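import numpy as np
import pytest

from groovetraj.synthetic import (build_helix, contact_pair_spec,
                                  calibrated_shielding_spec,
                                  replicate_bundle_spec, simulate_trajectory,
                                  unwinding_spec)


@pytest.fixture(scope="session")
def ideal_helix():
    return build_helix("A" * 20)


@pytest.fixture(scope="session")
def replicate_set():
    """4-replicate unwinding set: region 26-40 unwinds in replicates 1-3."""
    out = []
    for rep in (1, 2, 3, 4):
        spec = replicate_bundle_spec(rep, seed=7, n_frames=300)
        out.append(simulate_trajectory(spec))
    return out


@pytest.fixture(scope="session")
def contact_sim():
    """Scheduled Bernoulli contact (p=0.70) between residues 6 and 106."""
    return simulate_trajectory(contact_pair_spec(probability=0.70,
                                                 n_frames=2000, seed=11))


@pytest.fixture(scope="session")
def unwind_sim():
    """Residues 8-15 switch from helix to coil at 40% of a 1000-frame run."""
    return simulate_trajectory(unwinding_spec(n_frames=1000,
                                              switch_fraction=0.4, seed=5))


@pytest.fixture(scope="session")
def shield_sim():
    """A plate chain covers residue 5 of the target helix at half-run."""
    return simulate_trajectory(calibrated_shielding_spec(n_frames=20, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
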