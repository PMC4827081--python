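"""Counter-based uniform random stream for surface-hopping ensembles.

Each hop decision draws ``uniform(seed, trajectory, step)``: a stateless
splitmix64-style hash of the (seed, trajectory index, time-step index)
counter triple.  This makes ensembles reproducible, order-independent and
embarrassingly parallel, and lets the pure-Python reference engine and the
compiled kernels consume bit-identical streams (`numpy.random.Generator`
objects cannot cross the njit boundary).
"""

from __future__ import annotations

import numpy as np

_MASK = (1 << 64) - 1
_GOLDEN = 0x9E3779B97F4A7C15
_K_TRAJ = 0xD1B54A32D192ED03
_K_STEP = 0x8CB92BA72F3D8DD7
_M1 = 0xBF58476D1CE4E5B9
_M2 = 0x94D049BB133111EB


def _finalize(z: int) -> int:
    """splitmix64 output mixer on a 64-bit integer."""
    z &= _MASK
    z ^= z >> 30
    z = (z * _M1) & _MASK
    z ^= z >> 27
    z = (z * _M2) & _MASK
    z ^= z >> 31
    return z


def uniform(seed: int, traj: int, step: int) -> float:
    """Deterministic uniform draw in [0, 1) for one (trajectory, step)."""
    z = (seed * _GOLDEN + traj * _K_TRAJ + step * _K_STEP + _GOLDEN) & _MASK
    return (_finalize(z) >> 11) * 2.0 ** -53


def uniform_array(seed: int, traj: int, n_steps: int) -> np.ndarray:
    """The first ``n_steps`` draws of one trajectory's stream."""
    return np.array([uniform(seed, traj, k) for k in range(n_steps)])
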