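"""Two-state diabatic model potentials.

Four benchmark one-dimensional curve-crossing problems, each defined by a real
symmetric 2x2 diabatic potential matrix in atomic units (Hartree, Bohr,
hbar = 1, reduced mass 2000 au):

* Model 1 -- dual Rosen-Zener-Demkov non-crossing: two parallel diabats
  separated by ``A`` with a coupling built from two Gaussians centred at
  ``+-x0``.  The adiabatic gap peaks at x = +-3.0 Bohr.
* Model 2 -- dual Landau-Zener-Stueckelberg avoided crossings: a flat diabat
  and an inverted-Gaussian diabat offset by ``E0``; the diabats cross at
  x = +-2.07 Bohr.
* Model 3 -- simple avoided crossing: antisymmetric saturating diabats that
  cross once at x = 0 under a Gaussian coupling.
* Model 4 -- Renner-Teller crossing: same diabats as Model 3 (with A = 0.005)
  but a coupling proportional to x^2, so the adiabatic surfaces are exactly
  degenerate at x = 0.

A generic :class:`DiabaticModel` container lets users supply custom two-state
models, either from closed-form callables or from tabulated grids
(:func:`model_from_table`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

__all__ = [
    "DiabaticModel",
    "Model1Params",
    "Model2Params",
    "Model3Params",
    "Model4Params",
    "build_model1",
    "build_model2",
    "build_model3",
    "build_model4",
    "get_model",
    "model_from_table",
    "MODEL_BUILDERS",
]

#: Default reduced mass for all benchmark models (atomic units).
DEFAULT_MASS = 2000.0


@dataclass(frozen=True)
class DiabaticModel:
    """A 1D two-state model in the diabatic representation.

    ``v11``, ``v22``, ``v12`` (and gradients ``dv11`` ...) are vectorized
    callables mapping position in Bohr to energy in Hartree (gradients in
    Hartree/Bohr).  ``asym_left``/``asym_right`` hold the asymptotic channel
    energies ``(V11, V22)`` at x -> -inf / +inf.  ``x_span`` is the
    half-width of the interaction region: couplings are numerically
    negligible (< 1e-10 Hartree) beyond it.

    ``kernel_id``/``kernel_params`` identify a compiled fast path for the
    built-in models; custom models leave ``kernel_id=0`` and run through the
    pure-Python engines.
    """

    name: str
    v11: Callable
    v22: Callable
    v12: Callable
    dv11: Callable
    dv22: Callable
    dv12: Callable
    asym_left: tuple[float, float]
    asym_right: tuple[float, float]
    mass: float = DEFAULT_MASS
    x_span: float = 10.0
    kernel_id: int = 0
    kernel_params: tuple[float, ...] = ()

    # -- matrix views -----------------------------------------------------
    def matrix(self, x):
        """Diabatic matrix V(x); for array x the shape is (..., 2, 2)."""
        v11, v22, v12 = self.v11(x), self.v22(x), self.v12(x)
        out = np.empty(np.shape(v11) + (2, 2))
        out[..., 0, 0] = v11
        out[..., 1, 1] = v22
        out[..., 0, 1] = v12
        out[..., 1, 0] = v12
        return out

    def gradient_matrix(self, x):
        """dV/dx with the same shape convention as :meth:`matrix`."""
        d11, d22, d12 = self.dv11(x), self.dv22(x), self.dv12(x)
        out = np.empty(np.shape(d11) + (2, 2))
        out[..., 0, 0] = d11
        out[..., 1, 1] = d22
        out[..., 0, 1] = d12
        out[..., 1, 0] = d12
        return out

    # -- asymptotic channel bookkeeping -----------------------------------
    def asym(self, side: str) -> tuple[float, float]:
        if side == "left":
            return self.asym_left
        if side == "right":
            return self.asym_right
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")

    def channel_order(self, side: str) -> tuple[int, int]:
        """(lower, upper) adiabatic ordering of the diabatic channels at
        the given asymptote (0-based channel indices)."""
        e = self.asym(side)
        lo = 0 if e[0] <= e[1] else 1
        return lo, 1 - lo

    def lower_asymptote(self, side: str) -> float:
        return min(self.asym(side))

    def upper_asymptote(self, side: str) -> float:
        return max(self.asym(side))

    def with_coupling_off(self) -> "DiabaticModel":
        """Copy of the model with V12 = 0 (uncoupled-channel limit)."""
        zero = lambda x: np.zeros_like(np.asarray(x, dtype=float))  # noqa: E731
        return replace(self, name=self.name + "-uncoupled", v12=zero,
                       dv12=zero, kernel_id=0, kernel_params=())


def _positive(**kwargs) -> None:
    for key, val in kwargs.items():
        if not val > 0.0:
            raise ValueError(f"parameter {key} must be positive, got {val}")


@dataclass(frozen=True)
class Model1Params:
    """Dual non-crossing model: diabat offset A, Gaussian coupling amplitude
    B, centres +-x0 and exponent C."""

    A: float = 0.025  # Hartree
    B: float = 0.025  # Hartree
    x0: float = 3.0   # Bohr
    C: float = 0.7    # Bohr^-2


@dataclass(frozen=True)
class Model2Params:
    """Dual avoided-crossing model: well depth A, Gaussian exponent B,
    channel offset E0, coupling amplitude C and exponent D."""

    A: float = 0.1    # Hartree
    B: float = 0.28   # Bohr^-2
    E0: float = 0.03  # Hartree
    C: float = 0.01   # Hartree
    D: float = 0.06   # Bohr^-2


@dataclass(frozen=True)
class Model3Params:
    """Single-crossing model: asymptotic splitting A, saturation rate B,
    coupling amplitude C and exponent D."""

    A: float = 0.01  # Hartree
    B: float = 1.6   # Bohr^-1
    C: float = 0.01  # Hartree
    D: float = 1.0   # Bohr^-2


@dataclass(frozen=True)
class Model4Params:
    """Renner-Teller model: Model 3 diabats with A = 0.005 and a coupling
    C * x^2 * exp(-D x^2) vanishing quadratically at the crossing."""

    A: float = 0.005  # Hartree
    B: float = 1.6    # Bohr^-1
    C: float = 0.01   # Hartree
    D: float = 1.0    # Bohr^-2


def build_model1(params: Model1Params | None = None, *,
                 mass: float = DEFAULT_MASS, x_span: float = 10.0) -> DiabaticModel:
    """Dual Rosen-Zener-Demkov non-crossing model.

    V11 = 0, V22 = A, V12 = B [exp(-C (x-x0)^2) + exp(-C (x+x0)^2)].
    """
    p = params or Model1Params()
    _positive(C=p.C)
    A, B, x0, C = p.A, p.B, p.x0, p.C

    def v11(x):
        return np.zeros_like(np.asarray(x, dtype=float))

    def v22(x):
        return np.full_like(np.asarray(x, dtype=float), A)

    def v12(x):
        x = np.asarray(x, dtype=float)
        return B * (np.exp(-C * (x - x0) ** 2) + np.exp(-C * (x + x0) ** 2))

    def dv12(x):
        x = np.asarray(x, dtype=float)
        return B * (-2.0 * C * (x - x0) * np.exp(-C * (x - x0) ** 2)
                    - 2.0 * C * (x + x0) * np.exp(-C * (x + x0) ** 2))

    zero = v11
    return DiabaticModel("model1", v11, v22, v12, zero, zero, dv12,
                         asym_left=(0.0, A), asym_right=(0.0, A),
                         mass=mass, x_span=x_span,
                         kernel_id=1, kernel_params=(A, B, x0, C))


def build_model2(params: Model2Params | None = None, *,
                 mass: float = DEFAULT_MASS, x_span: float = 18.0) -> DiabaticModel:
    """Dual Landau-Zener-Stueckelberg avoided-crossing model.

    V11 = 0, V22 = -A exp(-B x^2) + E0, V12 = C exp(-D x^2).

    The default ``x_span`` is 18 Bohr: the slowly decaying coupling
    (D = 0.06 Bohr^-2) only drops below 1e-10 Hartree around |x| = 17.5.
    """
    p = params or Model2Params()
    _positive(B=p.B, D=p.D)
    A, B, E0, C, D = p.A, p.B, p.E0, p.C, p.D

    def v11(x):
        return np.zeros_like(np.asarray(x, dtype=float))

    def v22(x):
        x = np.asarray(x, dtype=float)
        return -A * np.exp(-B * x * x) + E0

    def v12(x):
        x = np.asarray(x, dtype=float)
        return C * np.exp(-D * x * x)

    def dv22(x):
        x = np.asarray(x, dtype=float)
        return 2.0 * A * B * x * np.exp(-B * x * x)

    def dv12(x):
        x = np.asarray(x, dtype=float)
        return -2.0 * D * x * C * np.exp(-D * x * x)

    zero = v11
    return DiabaticModel("model2", v11, v22, v12, zero, dv22, dv12,
                         asym_left=(0.0, E0), asym_right=(0.0, E0),
                         mass=mass, x_span=x_span,
                         kernel_id=2, kernel_params=(A, B, E0, C, D))


def _saturating_diabats(A: float, B: float):
    """V11 = sign(x) A (1 - exp(-B|x|)), V22 = -V11 and their gradients."""

    def v11(x):
        x = np.asarray(x, dtype=float)
        return np.sign(x) * A * (1.0 - np.exp(-B * np.abs(x)))

    def v22(x):
        return -v11(x)

    def dv11(x):
        x = np.asarray(x, dtype=float)
        return A * B * np.exp(-B * np.abs(x))

    def dv22(x):
        return -dv11(x)

    return v11, v22, dv11, dv22


def build_model3(params: Model3Params | None = None, *,
                 mass: float = DEFAULT_MASS, x_span: float = 10.0) -> DiabaticModel:
    """Simple avoided-crossing model.

    V11 = A (1 - exp(-B x)) for x >= 0 and -A (1 - exp(B x)) for x < 0,
    V22 = -V11, V12 = C exp(-D x^2).
    """
    p = params or Model3Params()
    _positive(B=p.B, D=p.D)
    A, B, C, D = p.A, p.B, p.C, p.D
    v11, v22, dv11, dv22 = _saturating_diabats(A, B)

    def v12(x):
        x = np.asarray(x, dtype=float)
        return C * np.exp(-D * x * x)

    def dv12(x):
        x = np.asarray(x, dtype=float)
        return -2.0 * D * x * C * np.exp(-D * x * x)

    return DiabaticModel("model3", v11, v22, v12, dv11, dv22, dv12,
                         asym_left=(-A, A), asym_right=(A, -A),
                         mass=mass, x_span=x_span,
                         kernel_id=3, kernel_params=(A, B, C, D))


def build_model4(params: Model4Params | None = None, *,
                 mass: float = DEFAULT_MASS, x_span: float = 10.0) -> DiabaticModel:
    """Renner-Teller degenerate-crossing model.

    Same diabats as Model 3 (with A = 0.005); V12 = C x^2 exp(-D x^2)
    vanishes quadratically at the crossing, so the adiabatic surfaces touch
    at x = 0.
    """
    p = params or Model4Params()
    _positive(B=p.B, D=p.D)
    A, B, C, D = p.A, p.B, p.C, p.D
    v11, v22, dv11, dv22 = _saturating_diabats(A, B)

    def v12(x):
        x = np.asarray(x, dtype=float)
        return C * x * x * np.exp(-D * x * x)

    def dv12(x):
        x = np.asarray(x, dtype=float)
        return C * (2.0 * x - 2.0 * D * x ** 3) * np.exp(-D * x * x)

    return DiabaticModel("model4", v11, v22, v12, dv11, dv22, dv12,
                         asym_left=(-A, A), asym_right=(A, -A),
                         mass=mass, x_span=x_span,
                         kernel_id=4, kernel_params=(A, B, C, D))


MODEL_BUILDERS = {
    "model1": build_model1,
    "model2": build_model2,
    "model3": build_model3,
    "model4": build_model4,
}


def get_model(name: str, **kwargs) -> DiabaticModel:
    """Build one of the benchmark models by name (``model1`` ... ``model4``)."""
    try:
        builder = MODEL_BUILDERS[name]
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; choose from {sorted(MODEL_BUILDERS)}"
        ) from None
    return builder(**kwargs)


def model_from_table(x, v11, v22, v12, *, name: str = "custom",
                     mass: float = DEFAULT_MASS,
                     x_span: float | None = None) -> DiabaticModel:
    """Build a custom model from tabulated (x, V11, V22, V12) grids.

    Cubic splines interpolate the tables; gradients come from the spline
    derivative.  Outside the table the potentials are held at their edge
    values (couplings should already have decayed there).
    """
    from scipy.interpolate import CubicSpline

    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 4 or np.any(np.diff(x) <= 0):
        raise ValueError("x must be a strictly increasing 1D grid of >= 4 points")
    splines = [CubicSpline(x, np.asarray(v, dtype=float), bc_type="natural")
               for v in (v11, v22, v12)]
    span = x_span if x_span is not None else float(min(-x[0], x[-1]))

    def clamp(z):
        return np.clip(np.asarray(z, dtype=float), x[0], x[-1])

    def make_eval(s):
        return lambda z: s(clamp(z))

    def make_grad(s):
        ds = s.derivative()
        return lambda z: np.where(
            (np.asarray(z) > x[0]) & (np.asarray(z) < x[-1]), ds(clamp(z)), 0.0)

    s11, s22, s12 = splines
    return DiabaticModel(name, make_eval(s11), make_eval(s22), make_eval(s12),
                         make_grad(s11), make_grad(s22), make_grad(s12),
                         asym_left=(float(s11(x[0])), float(s22(x[0]))),
                         asym_right=(float(s11(x[-1])), float(s22(x[-1]))),
                         mass=mass, x_span=span)
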