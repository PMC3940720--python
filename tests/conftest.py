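import numpy as np
import pytest

from kv13tcell import Kv13Model


@pytest.fixture(scope="session")
def model() -> Kv13Model:
    """Default calibrated Kv1.3 model (published rate constants)."""
    return Kv13Model()


def euler_propagate(Q: np.ndarray, p0: np.ndarray, t_ms: float, dt_ms: float = 1e-3) -> np.ndarray:
    """Independent fine-step explicit-Euler oracle for fixed-voltage propagation."""
    n = int(round(t_ms / dt_ms))
    M = np.eye(Q.shape[0]) + dt_ms * Q
    p = p0.copy()
    for _ in range(n):
        p = p @ M
    return p
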