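import numpy as np
import pandas as pd
import pytest

from rootgroups.design import adjust_augmented, estimate_block_effects
from rootgroups.io import DesignLayout
from rootgroups.simulate import FIXTURE_SOIL_VOLUME, SimulationConfig, simulate_dataset
from rootgroups.traits import TraitConfig, derive_all


@pytest.fixture(scope="session")
def trait_config():
    return TraitConfig(soil_volume=FIXTURE_SOIL_VOLUME)


@pytest.fixture(scope="session")
def sim_default():
    """One full-scale simulated dataset (300 tubes, 114 genotypes)."""
    cfg = SimulationConfig(seed=20260920)
    records, truth = simulate_dataset(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def sim_tables(sim_default, trait_config):
    """Derived, block-adjusted tables for the default simulation."""
    cfg, records, truth = sim_default
    layout = cfg.layout()
    table = derive_all(records, trait_config)
    effects = estimate_block_effects(table, layout)
    adjusted = adjust_augmented(table, effects, layout)
    return {"cfg": cfg, "layout": layout, "truth": truth,
            "table": table, "effects": effects, "adjusted": adjusted}


def additive_table(rng, n_geno=20, n_blocks=4, n_checks=4, traits=("root_length",)):
    """Noise-free additive data y = genotype + block + condition on an
    augmented layout; returns (table, layout, genotype effects, block effects)."""
    check_ids = list(range(1, n_checks + 1))
    test_ids = list(range(n_checks + 1, n_geno + 1))
    n_tests = len(test_ids)
    assert n_tests % n_blocks == 0
    per_block = n_tests // n_blocks
    g_eff = {g: float(rng.normal(50, 10)) for g in range(1, n_geno + 1)}
    rows = []
    b_eff = {}
    for cond, c_eff in (("normal", 0.0), ("stress", float(rng.normal(-5, 2)))):
        for j in range(1, n_blocks + 1):
            b_eff[(cond, j)] = float(rng.normal(0, 3))
        perm = rng.permutation(test_ids)
        for j in range(1, n_blocks + 1):
            block_tests = perm[(j - 1) * per_block: j * per_block]
            for g in list(block_tests) + check_ids:
                row = {"genotype_id": int(g), "is_check": g in check_ids,
                       "block": j, "condition": cond}
                for t in traits:
                    row[t] = g_eff[g] + b_eff[(cond, j)] + c_eff
                rows.append(row)
    layout = DesignLayout(n_blocks, frozenset(check_ids), frozenset(test_ids))
    return pd.DataFrame(rows), layout, g_eff, b_eff
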