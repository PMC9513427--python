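import numpy as np
import pandas as pd
import pytest

from qpcrkit import GeneSpec, SimulationConfig, simulate_cq_experiment


@pytest.fixture
def small_cq_table():
    """2 genes x 2 groups x 3 bio reps, noiseless, target fold change 4 (A=2)."""
    cfg = SimulationConfig(
        seed=0,
        genes={"target": GeneSpec(2.0, 24.0), "ref": GeneSpec(2.0, 20.0)},
        fold_changes={"control": {"target": 1.0}, "treatment": {"target": 4.0}},
        n_bio=3, n_tech=2, cq_noise_sd=0.0,
    )
    return simulate_cq_experiment(cfg)


@pytest.fixture
def noisy_cq_table():
    """Same design with technical noise, for statistics paths."""
    cfg = SimulationConfig(
        seed=7,
        genes={"target": GeneSpec(2.0, 24.0), "ref": GeneSpec(2.0, 20.0)},
        fold_changes={"control": {"target": 1.0}, "treatment": {"target": 4.0}},
        n_bio=4, n_tech=3, cq_noise_sd=0.15,
    )
    return simulate_cq_experiment(cfg)


@pytest.fixture
def exact_dilution_table():
    """Two genes on exact lines: A=2 (slope -3.32193) and A=3."""
    rows = []
    for gene, a, b0 in [("g2", 2.0, 25.0), ("g3", 3.0, 20.0)]:
        for step in range(4):
            rows.append({"gene": gene, "rel_conc": 10.0 ** (-step),
                         "cq": b0 + step * np.log(10) / np.log(a)})
    df = pd.DataFrame(rows)
    df.attrs["dilution_factor"] = 10.0
    return df
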