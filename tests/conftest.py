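import numpy as np
import pytest

from omnigwas import LDSpec, StudyTruth, make_ld_matrix, simulate_z_panel
from omnigwas.containers import LDBlock


def ar_corr(decay: float, size: int) -> np.ndarray:
    idx = np.arange(size)
    return decay ** np.abs(idx[:, None] - idx[None, :])


@pytest.fixture
def ar_block():
    def _make(decay: float, size: int, start: int = 0, spacing: int = 1000):
        idx = np.arange(size)
        return LDBlock(corr=ar_corr(decay, size), start=start,
                       positions=(start + idx + 1) * spacing)
    return _make


@pytest.fixture
def null_panel():
    """Small null panel: 2,500 SNPs x 3 traits, moderate LD and overlap."""
    k = 3
    omega = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.3], [0.2, 0.3, 1.0]])
    spec = LDSpec(n_snps=2500, block_sizes=[50] * 50, within_block_decay=0.7)
    truth = StudyTruth(gamma=np.zeros((2500, k)), omega_true=omega,
                       sample_sizes=np.full(k, 1e4))
    blocks = make_ld_matrix(spec)
    panel = simulate_z_panel(blocks, truth, seed=7)
    return panel, blocks, omega
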