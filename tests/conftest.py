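import numpy as np
import pytest

import mycodyn as md


@pytest.fixture(scope="session")
def pool():
    return md.default_pool()


@pytest.fixture(scope="session")
def cohort(pool):
    """One default simulated cohort (seed 7), shared read-only."""
    config = md.SimulationConfig(seed=7)
    records, measurements, t16, tits = md.simulate_experiment(config, pool)
    return config, records, measurements, t16, tits


@pytest.fixture(scope="session")
def noiseless_cohort(pool):
    config = md.SimulationConfig(seed=7, qpcr_cv=0.0)
    records, measurements, t16, tits = md.simulate_experiment(config, pool)
    return config, records, measurements, t16, tits


def random_lineage_set(rng: np.random.Generator, max_leaves: int = 6) -> dict:
    """Random OTU -> lineage map over a small random taxonomy."""
    kingdoms = ["Fungi", "Bacteria"]
    phyla = ["P1", "P2", "P3"]
    classes = ["C1", "C2"]
    genera = ["Ga", "Gb", "Gc", "Gd"]
    n = int(rng.integers(2, max_leaves + 1))
    out = {}
    for i in range(n):
        depth = int(rng.integers(1, 5))
        parts = [
            rng.choice(kingdoms),
            rng.choice(phyla),
            rng.choice(classes),
            rng.choice(genera),
        ][:depth]
        out[f"otu{i}"] = ";".join(parts)
    return out
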