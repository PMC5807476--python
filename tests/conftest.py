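import numpy as np
import pytest

from aunpcount.voltammetry_io import Voltammogram


def triangular_potential(k: int, e_lo: float = 0.9, e_hi: float = 1.5, n_half: int = 201) -> np.ndarray:
    """k triangular periods e_lo -> e_hi -> e_lo, concatenated."""
    up = np.linspace(e_lo, e_hi, n_half)
    down = np.linspace(e_hi, e_lo, n_half)[1:]
    return np.concatenate([np.concatenate([up, down]) for _ in range(k)])


@pytest.fixture
def ramp_trace() -> Voltammogram:
    """Single anodic ramp 0 -> 0.8 V at 0.1 V/s, zero current."""
    e = np.linspace(0.0, 0.8, 801)
    return Voltammogram(potential=e, current=np.zeros_like(e), scan_rate=0.1)


@pytest.fixture
def gaussian_peak_trace():
    """Factory: anodic ramp carrying a Gaussian current peak (+ optional line)."""

    def make(a=1e-4, sigma=0.04, e0=1.2, nu=0.1, e_lo=0.9, e_hi=1.5, n=1201,
             base_slope=0.0, base_intercept=0.0):
        e = np.linspace(e_lo, e_hi, n)
        i = a * np.exp(-((e - e0) ** 2) / (2 * sigma**2)) + base_intercept + base_slope * e
        return Voltammogram(potential=e, current=i, scan_rate=nu)

    return make
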