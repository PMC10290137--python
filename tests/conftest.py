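import numpy as np
import pandas as pd
import pytest

from epinet import simulate
from epinet.grading import SpectralCountTable


def make_table(bait_rows, control_rows, protein_ids=None):
    """Build a SpectralCountTable from per-protein bait/control count tuples."""
    bait = np.atleast_2d(np.asarray(bait_rows, dtype=np.int64))
    control = np.atleast_2d(np.asarray(control_rows, dtype=np.int64))
    n = bait.shape[0]
    if protein_ids is None:
        protein_ids = [f"P{i:03d}" for i in range(n)]
    bait_ids = [f"bait_{j + 1}" for j in range(bait.shape[1])]
    ctrl_ids = [f"control_{j + 1}" for j in range(control.shape[1])]
    counts = pd.DataFrame(
        np.hstack([bait, control]),
        index=pd.Index(protein_ids, name="protein_id"),
        columns=bait_ids + ctrl_ids,
    )
    roles = pd.Series(
        ["bait"] * len(bait_ids) + ["control"] * len(ctrl_ids),
        index=bait_ids + ctrl_ids,
    )
    return SpectralCountTable(counts, roles)


@pytest.fixture
def ppi_fixture(tmp_path):
    cfg = simulate.PpiSimConfig(n_nodes=50, n_chaperome=8, ortholog_noise=0.2, seed=1234)
    paths, truth = simulate.generate_ppi_fixture(cfg, tmp_path / "ppi")
    return cfg, paths, truth
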