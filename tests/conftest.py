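import numpy as np
import pytest

from midtail import (
    Proteoform,
    QuantParams,
    SimulationConfig,
    default_modification_registry,
    default_run_design,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def registry():
    return default_modification_registry()


@pytest.fixture(scope="session")
def design():
    return default_run_design()


@pytest.fixture(scope="session")
def params():
    return QuantParams()


@pytest.fixture(scope="session")
def small_dataset():
    """40 scans at the default study conditions; shared across tests."""
    return simulate_dataset(SimulationConfig(seed=11, n_scans=40))


@pytest.fixture(scope="session")
def noiseless_dataset():
    return simulate_dataset(SimulationConfig(seed=11, n_scans=40).noiseless())


def random_proteoform(rng: np.random.Generator) -> Proteoform:
    """A random valid proteoform over the acetyl/methyl/phospho search space."""
    base = rng.choice(["H3.1", "H3.3"])
    p = Proteoform(base)
    # candidate (position, mod) pairs on the surrogate sequence
    lys = [i + 1 for i, aa in enumerate(p.sequence) if aa == "K"]
    st = [i + 1 for i, aa in enumerate(p.sequence) if aa in "ST"]
    pool = [(pos, m) for pos in lys for m in ("Acetyl", "Methyl", "Dimethyl", "Trimethyl")]
    pool += [(pos, "Phospho") for pos in st]
    rng.shuffle(pool)
    per_mod: dict[str, int] = {}
    caps = {"Acetyl": 5, "Methyl": 3, "Dimethyl": 3, "Trimethyl": 3, "Phospho": 2}
    used: set[int] = set()
    mods = []
    n_target = int(rng.integers(0, 6))
    for pos, name in pool:
        if len(mods) >= n_target:
            break
        if pos in used or per_mod.get(name, 0) >= caps[name]:
            continue
        used.add(pos)
        per_mod[name] = per_mod.get(name, 0) + 1
        mods.append((pos, name))
    return Proteoform(base, tuple(mods))
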