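import numpy as np
import pytest

from hergnet.pipeline import RunConfig
from hergnet.synthetic import ChainPlantSpec, generate_chain_trajectory


@pytest.fixture(scope="session")
def small_plant_spec():
    """Cheap planted-chain spec used by several integration tests."""
    return ChainPlantSpec(
        n_residues=12,
        chain_indices=(0, 1, 2, 3),
        coupling_strength=0.9,
        noise_sd=0.25,
        n_frames=600,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_plant_traj(small_plant_spec):
    return generate_chain_trajectory(small_plant_spec)


@pytest.fixture()
def endpoint_config():
    """Config whose regions are the endpoints of the default planted chain."""

    def _make(spec, **overrides):
        first = spec.chain_indices[0] + 1
        last = spec.chain_indices[-1] + 1
        base = dict(
            regions={
                "SRC": {"members": [["A", first]]},
                "TGT": {"members": [["A", last]]},
            },
            region_pairs=[["SRC", "TGT"]],
        )
        base.update(overrides)
        return RunConfig(**base)

    return _make


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
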