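import numpy as np
import pandas as pd
import pytest

import wheatscreen as ws


@pytest.fixture
def toy_fieldbook():
    """2 blocks x 2 checks + 2 tests, hand-enumerable values."""
    df = pd.DataFrame(
        [
            {"genotype": "C1", "block": "B1", "is_check": True, "Y": 10.0},
            {"genotype": "C2", "block": "B1", "is_check": True, "Y": 12.0},
            {"genotype": "C1", "block": "B2", "is_check": True, "Y": 14.0},
            {"genotype": "C2", "block": "B2", "is_check": True, "Y": 16.0},
            {"genotype": "T1", "block": "B1", "is_check": False, "Y": 20.0},
            {"genotype": "T2", "block": "B2", "is_check": False, "Y": 20.0},
        ]
    )
    return ws.FieldBook(df)


@pytest.fixture
def default_sim():
    """Study-design simulation (4 blocks, 5 checks, 41 tests), fixed seed."""
    spec = ws.SimulationSpec(seed=11)
    fb, geno_truth, block_truth = ws.simulate_fieldbook(spec)
    return spec, fb, geno_truth, block_truth


@pytest.fixture
def noisefree_sim():
    """Zero-error simulation with known effects: exact recovery expected."""
    rng = np.random.default_rng(5)
    genos = ["K", "D", "R"] + [f"T{i:02d}" for i in range(1, 9)]
    effects = {g: float(rng.normal(0, 2)) for g in genos}
    spec = ws.SimulationSpec(
        n_blocks=3,
        checks=("K", "D", "R"),
        n_tests=8,
        traits={"Y": ws.TraitSim(mean=10.0, error_sd=0.0, genotype_effects=effects)},
        block_effects=(-1.0, 0.5, 0.5),
        seed=0,
    )
    fb, geno_truth, block_truth = ws.simulate_fieldbook(spec)
    return fb, geno_truth, block_truth
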