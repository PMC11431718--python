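import numpy as np
import pytest

from taucor import LDMatrix, repair_psd


def random_correlation(rng: np.random.Generator, m: int) -> np.ndarray:
    """Random PSD correlation matrix (unit diagonal) via normalized Wishart."""
    A = rng.standard_normal((m, m + 2))
    S = A @ A.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def random_partition_blocks(rng: np.random.Generator, m_g: int, m_r: int):
    """Random joint correlation matrix split into U_g, U_r, U_gr blocks."""
    U = random_correlation(rng, m_g + m_r)
    return U[:m_g, :m_g], U[m_g:, m_g:], U[:m_g, m_g:]


@pytest.fixture
def rng():
    return np.random.default_rng(20240907)
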