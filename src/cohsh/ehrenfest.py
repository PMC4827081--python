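"""Semiclassical Ehrenfest (mean-field) dynamics in one dimension.

A single deterministic trajectory starts on the lower adiabatic surface at
x = -x_span and moves on the population-averaged potential

    U_avg(x) = rho_11 u1(x) + rho_22 u2(x)

with the mean-field force (gradient of the coherent electronic energy in
the adiabatic representation)

    F = -rho_11 u1' - rho_22 u2' - 2 Re(rho_12) d12 (u2 - u1),

which conserves p^2/2m + Tr(rho H_el) under joint RK4 propagation with the
original electronic equations.  The modified scheme changes only the
diagonal phase term of the electronic equations (reference potential
U_ref = U_avg); the nuclear force is unchanged.

The transition probability is the final rho_22 at exit; a trajectory that
fails to transmit to x -> +infinity is flagged rather than silently
counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .adiabatic import AdiabaticPoint, adiabatize
from .electronic import ElectronicState, PhaseScheme
from .fssh import default_max_steps
from .models import DiabaticModel

__all__ = ["MeanFieldState", "MeanFieldResult", "mean_field_potential",
           "mean_field_force", "run_mean_field", "mean_field_curve"]


@dataclass
class MeanFieldState:
    x: float
    p: float
    t: float
    electronic: ElectronicState
    e_total: float
    u_avg: float
    mass: float = 2000.0


@dataclass
class MeanFieldResult:
    exit_side: str               # "right", "left" or "none"
    state: MeanFieldState
    p_transition: float          # final rho_22
    reflected: bool              # did not transmit to x -> +infinity
    truncated: bool
    energy_drift: float          # max |KE + Tr(rho H) - E| along the path


def mean_field_potential(rho: np.ndarray, point: AdiabaticPoint) -> float:
    """Population-averaged potential sum_j rho_jj u_j."""
    return float(rho[0, 0].real * point.u1 + rho[1, 1].real * point.u2)


def mean_field_force(rho: np.ndarray, point: AdiabaticPoint) -> float:
    """Mean-field force including the coherence-coupling term."""
    return float(-rho[0, 0].real * point.du1 - rho[1, 1].real * point.du2
                 - 2.0 * rho[0, 1].real * point.d12 * (point.u2 - point.u1))


def run_mean_field(model: DiabaticModel, e_total: float,
                   scheme: PhaseScheme | str, *, dt: float = 1.0,
                   max_steps: int | None = None,
                   engine: str = "python") -> MeanFieldResult:
    """Propagate the single Ehrenfest trajectory at one total energy.

    The default engine is the Python reference (it keeps the full density
    matrix, including coherences, in the returned state); energy scans
    should use :func:`mean_field_curve`, which runs the compiled kernel.
    """
    modified = _is_modified(scheme)
    u1s = adiabatize(model, -model.x_span).u1
    if e_total <= u1s:
        raise ValueError(
            f"total energy {e_total} does not open the entrance channel")
    if max_steps is None:
        max_steps = default_max_steps(model, e_total, dt)

    if engine in ("kernel", "auto") and model.kernel_id > 0:
        from ._kernels import ehrenfest_batch
        par = np.asarray(model.kernel_params, dtype=float)
        code, rho22, xf, pf, drift = ehrenfest_batch(
            model.kernel_id, par, model.mass, model.x_span,
            np.array([e_total]), dt, modified, max_steps)
        exit_side = {1: "right", -1: "left", 0: "none"}[int(code[0])]
        rho = np.array([[1.0 - rho22[0], 0.0], [0.0, rho22[0]]],
                       dtype=complex)  # coherences not returned by kernel
        pt = adiabatize(model, float(xf[0]))
        state = MeanFieldState(float(xf[0]), float(pf[0]),
                               max_steps * dt, ElectronicState(rho),
                               e_total, mean_field_potential(rho, pt),
                               model.mass)
        return MeanFieldResult(exit_side, state, float(rho22[0]),
                               reflected=exit_side != "right",
                               truncated=exit_side == "none",
                               energy_drift=float(drift[0]))
    return _run_mean_field_python(model, e_total, modified, dt, max_steps)


def _is_modified(scheme: PhaseScheme | str) -> bool:
    if isinstance(scheme, PhaseScheme):
        return scheme.modified
    if scheme not in ("original", "modified"):
        raise ValueError("scheme must be 'original' or 'modified'")
    return scheme == "modified"


def _run_mean_field_python(model: DiabaticModel, e_total: float,
                           modified: bool, dt: float,
                           max_steps: int) -> MeanFieldResult:
    """Pure-Python reference engine (any model, full density matrix)."""
    mass = model.mass
    span = model.x_span
    x = -span
    p = math.sqrt(2.0 * mass * (e_total - adiabatize(model, x).u1))
    n1, n2, cr, ci = 1.0, 0.0, 0.0, 0.0
    drift = 0.0
    exit_side = "none"
    step = 0

    def deriv(x, p, n1, n2, cr, ci):
        pt = adiabatize(model, x)
        v = p / mass
        force = -(n1 * pt.du1 + n2 * pt.du2) \
            - 2.0 * cr * pt.d12 * (pt.u2 - pt.u1)
        if modified:
            u_ref = n1 * pt.u1 + n2 * pt.u2
            t_ref = max(e_total - u_ref, 0.0)
            s1 = math.sqrt(max(e_total - pt.u1, 0.0))
            s2 = math.sqrt(max(e_total - pt.u2, 0.0))
            delta = 2.0 * math.sqrt(t_ref) * (s2 - s1)
        else:
            delta = pt.u1 - pt.u2
        vd = v * pt.d12
        flux = 2.0 * vd * cr
        return (v, force, -flux, flux, delta * ci - vd * (n2 - n1),
                -delta * cr)

    for step in range(max_steps):
        pt = adiabatize(model, x)
        drift = max(drift, abs(p * p / (2.0 * mass)
                               + n1 * pt.u1 + n2 * pt.u2 - e_total))
        a1, b1, c1, d1, e1, f1 = deriv(x, p, n1, n2, cr, ci)
        h2 = 0.5 * dt
        a2, b2, c2, d2, e2, f2 = deriv(x + h2 * a1, p + h2 * b1,
                                       n1 + h2 * c1, n2 + h2 * d1,
                                       cr + h2 * e1, ci + h2 * f1)
        a3, b3, c3, d3, e3, f3 = deriv(x + h2 * a2, p + h2 * b2,
                                       n1 + h2 * c2, n2 + h2 * d2,
                                       cr + h2 * e2, ci + h2 * f2)
        a4, b4, c4, d4, e4, f4 = deriv(x + dt * a3, p + dt * b3,
                                       n1 + dt * c3, n2 + dt * d3,
                                       cr + dt * e3, ci + dt * f3)
        w = dt / 6.0
        x += w * (a1 + 2.0 * a2 + 2.0 * a3 + a4)
        p += w * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
        n1 += w * (c1 + 2.0 * c2 + 2.0 * c3 + c4)
        n2 += w * (d1 + 2.0 * d2 + 2.0 * d3 + d4)
        cr += w * (e1 + 2.0 * e2 + 2.0 * e3 + e4)
        ci += w * (f1 + 2.0 * f2 + 2.0 * f3 + f4)
        if x > span and p > 0.0:
            exit_side = "right"
            break
        if x < -span and p < 0.0:
            exit_side = "left"
            break

    rho = np.array([[n1, cr + 1j * ci], [cr - 1j * ci, n2]], dtype=complex)
    pt = adiabatize(model, x)
    state = MeanFieldState(x, p, (step + 1) * dt, ElectronicState(rho),
                           e_total, mean_field_potential(rho, pt), mass)
    return MeanFieldResult(exit_side, state, float(n2),
                           reflected=exit_side != "right",
                           truncated=exit_side == "none",
                           energy_drift=drift)


def mean_field_curve(model: DiabaticModel, energies, scheme, *,
                     dt: float = 1.0) -> dict:
    """Vectorized Ehrenfest energy scan (one trajectory per energy).

    Returns arrays ``energy, p_transition, reflected, truncated,
    energy_drift``.
    """
    energies = np.asarray(energies, dtype=float)
    modified = _is_modified(scheme)
    if model.kernel_id > 0:
        from ._kernels import ehrenfest_batch
        par = np.asarray(model.kernel_params, dtype=float)
        max_steps = max(default_max_steps(model, float(e), dt)
                        for e in energies)
        code, rho22, _xf, _pf, drift = ehrenfest_batch(
            model.kernel_id, par, model.mass, model.x_span, energies, dt,
            modified, max_steps)
        return {"energy": energies, "p_transition": rho22,
                "reflected": code != 1, "truncated": code == 0,
                "energy_drift": drift}
    out = [run_mean_field(model, float(e), scheme, dt=dt) for e in energies]
    return {"energy": energies,
            "p_transition": np.array([r.p_transition for r in out]),
            "reflected": np.array([r.reflected for r in out]),
            "truncated": np.array([r.truncated for r in out]),
            "energy_drift": np.array([r.energy_drift for r in out])}
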