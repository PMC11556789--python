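import numpy as np
import pytest
from hypothesis import settings

from saltcondense.synthetic import (ContactPlant, IonPlant, PlantSpec,
                                    make_planted_condensate)

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_planted():
    """A 3-chain fixture with one binding plant per flavour plus a bridge."""
    spec = PlantSpec(
        n_chains=3, chain_length=24, box=(140.0, 140.0, 140.0), n_waters=40,
        ion_plan=(IonPlant("CL", "first", "ARG:sidechain_N", (0,)),
                  IonPlant("CL", "second", "ARG:sidechain_N", (0,)),
                  IonPlant("NA", "first", "backbone_O", (1, 2),
                           distance=2.5),
                  IonPlant("NA", "unbound"),
                  IonPlant("CL", "unbound")),
        seed=11)
    return make_planted_condensate(spec)


def random_plant_spec(seed: int) -> PlantSpec:
    """A randomized but realizable plant drawn from a safe menu."""
    rng = np.random.default_rng(seed)
    n_chains = int(rng.integers(3, 5))
    plan = []
    # one bridge claiming the first chains
    k = int(rng.integers(2, 4))
    k = min(k, n_chains)
    species = "NA" if rng.random() < 0.5 else "CL"
    site = "backbone_O" if rng.random() < 0.5 else "ARG:sidechain_N"
    plan.append(IonPlant(species, "first", site, tuple(range(k))))
    # single-chain plants on the remaining chains
    for c in range(k, n_chains):
        shell = ["first", "second"][int(rng.integers(0, 2))]
        sp = "CL" if rng.random() < 0.5 else "NA"
        st = ["ARG:sidechain_N", "backbone_O",
              "ASP:sidechain_O"][int(rng.integers(0, 3))]
        plan.append(IonPlant(sp, shell, st, (c,)))
    for _ in range(int(rng.integers(1, 3))):
        plan.append(IonPlant("CL" if rng.random() < 0.5 else "NA", "unbound"))
    return PlantSpec(n_chains=n_chains, chain_length=12,
                     box=(120.0, 120.0, 120.0), ion_plan=tuple(plan),
                     n_waters=int(rng.integers(0, 30)), seed=seed)
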