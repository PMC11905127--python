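import numpy as np
import pandas as pd
import pytest

from gnrhtraj.io import CountMatrix, GeneSetCollection
from gnrhtraj.simulate import SimulationParams, simulate_counts, simulate_lr_pairs


@pytest.fixture(scope="session")
def study():
    """One simulated study at defaults: counts + planted LR pairs + truth."""
    params = SimulationParams(seed=11)
    m, truth = simulate_counts(params)
    pairs, m = simulate_lr_pairs(m, truth, params, n_pairs=60)
    return {"params": params, "matrix": m, "truth": truth, "pairs": pairs}


@pytest.fixture(scope="session")
def study_de(study):
    """Per-transition GFP+ DE tables for the session study (computed once)."""
    from gnrhtraj.de import de_test
    from gnrhtraj.io import TRANSITION_LABELS

    return {t: de_test(study["matrix"], t, "GFP+") for t in TRANSITION_LABELS}


@pytest.fixture(scope="session")
def small_matrix():
    """Tiny deterministic count matrix: 5 genes x 4 GFP+ samples, 2 stages."""
    samples = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "stage": ["E12.5-nose", "E12.5-nose", "E14.5-nose", "E14.5-nose"],
            "fraction": ["GFP+"] * 4,
            "replicate": [1, 2, 1, 2],
        }
    )
    counts = np.array(
        [
            [10, 12, 40, 44],
            [100, 90, 95, 105],
            [0, 1, 0, 2],
            [50, 55, 20, 18],
            [7, 8, 9, 6],
        ]
    )
    return CountMatrix(genes=["GA", "GB", "GC", "GD", "GE"], samples=samples, counts=counts)


@pytest.fixture()
def trajectory_sets():
    return GeneSetCollection(
        sets={f"T{i:02d}": {f"GENE{i}_{j}" for j in range(30)} for i in range(6)}
    )
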