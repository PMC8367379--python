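import numpy as np
import pandas as pd
import pytest

from asedyn import synthetic
from asedyn.ase import AlleleCountMatrix


@pytest.fixture(scope="session")
def null_matrix():
    """Effect-free allele counts under the exchangeable null.

    Flat trajectories and constant library size keep the (f_i, w_i) pairs
    iid across timepoints, the regime where both ASE tests are exactly
    calibrated.
    """
    cfg = synthetic.SimulationConfig(
        n_genes=2000,
        depth=600,
        dispersion=0.01,
        depth_sigma=0.0,
        flat_trajectories=True,
        seed=7,
    )
    matrix, _ = synthetic.simulate_ase_counts(cfg)
    return matrix


@pytest.fixture(scope="session")
def genome_fixture():
    return synthetic.simulate_genome_fixture(
        n_genes=4, intergenic_len=400, seed=3
    )


@pytest.fixture()
def tiny_matrix():
    """Three genes x four timepoints with easily hand-checked counts."""
    counts = np.array(
        [
            [[30, 10], [30, 10], [30, 10], [30, 10]],
            [[20, 20], [20, 20], [20, 20], [20, 20]],
            [[50, 50], [60, 40], [40, 60], [50, 50]],
        ]
    )
    return AlleleCountMatrix(["gA", "gB", "gC"], [0, 1, 2, 3], counts)


@pytest.fixture(scope="session")
def small_manifest():
    rows = []
    for c, construct in enumerate(["conA", "conB"]):
        for r in range(4):
            rows.append(
                {
                    "construct_id": construct,
                    "gene": "gene000",
                    "region_index": 0,
                    "allele_label": "P1" if construct == "conA" else "P2",
                    "variant_ids": "",
                    "barcode": f"{'ACGT'[c] * 5}{'TGCA'[c] * 4}{'ACGT'[r]}",
                }
            )
    return pd.DataFrame(rows)
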