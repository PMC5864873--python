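import numpy as np
import pandas as pd
import pytest

from scrobust import CountsMatrix, SpikeInReference


@pytest.fixture
def small_counts() -> CountsMatrix:
    """3 genes (one spike-in) x 2 cells."""
    values = pd.DataFrame(
        [[4, 0], [10, 12], [0, 3]],
        index=["G1", "ERCC-00002", "G2"],
        columns=["c1", "c2"],
    )
    return CountsMatrix(
        values=values,
        is_spikein=pd.Series([False, True, False], index=values.index),
    )


@pytest.fixture
def spike_reference() -> SpikeInReference:
    return SpikeInReference(
        molecules=pd.Series([10.0, 40.0], index=["ERCC-00002", "ERCC-00003"])
    )


def make_consensus(values: np.ndarray, n_replicates: int = 100):
    from scrobust import ConsensusMatrix

    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    return ConsensusMatrix(
        values=np.asarray(values, dtype=float),
        cell_ids=[f"c{i}" for i in range(n)],
        n_replicates=n_replicates,
    )
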