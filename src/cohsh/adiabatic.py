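"""Diabatic -> adiabatic transformation for two-state models.

The 2x2 real symmetric diabatic matrix V(x) is diagonalized analytically.
With dv = V11 - V22 and the mixing angle theta = atan2(2 V12, dv) / 2:

    u_{1,2} = (V11 + V22 -/+ gap) / 2,   gap = sqrt(dv^2 + 4 V12^2)

and the scalar nonadiabatic coupling <phi1|d phi2/dx> equals d theta/dx:

    d12 = (V12' dv - V12 dv') / (dv^2 + 4 V12^2)

State 1 is the lower adiabatic surface everywhere, state 2 the upper one.
At an exact degeneracy with vanishing coupling (Model 4 at x = 0) d12 is a
0/0 limit; it is regularized by averaging the analytic value one small step
(1e-6 Bohr) to either side, and the point is flagged.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .models import DiabaticModel

__all__ = ["AdiabaticPoint", "adiabatize", "adiabatize_grid",
           "find_diabatic_crossings", "find_gap_extrema", "GapExtremum"]

#: below this value of dv^2 + 4 v12^2 (Hartree^2) a point counts as degenerate
_DEGENERACY_FLOOR = 1e-30
#: one-sided offset used to regularize d12 at a degeneracy (Bohr)
_DEGENERACY_STEP = 1e-6


class AdiabaticPoint(NamedTuple):
    """Adiabatic data at a single position (atomic units)."""

    x: float
    u1: float
    u2: float
    du1: float
    du2: float
    theta: float
    d12: float
    degenerate: bool = False


def _raw_point(model: DiabaticModel, x: float):
    v11 = float(model.v11(x))
    v22 = float(model.v22(x))
    v12 = float(model.v12(x))
    d11 = float(model.dv11(x))
    d22 = float(model.dv22(x))
    d12v = float(model.dv12(x))
    dv = v11 - v22
    ddv = d11 - d22
    s = dv * dv + 4.0 * v12 * v12
    return v11, v22, v12, d11, d22, d12v, dv, ddv, s


def adiabatize(model: DiabaticModel, x: float) -> AdiabaticPoint:
    """Adiabatic energies, gradients, mixing angle and coupling at ``x``."""
    x = float(x)
    if not np.isfinite(x):
        raise ValueError("position must be finite")
    v11, v22, v12, d11, d22, d12v, dv, ddv, s = _raw_point(model, x)
    if s < _DEGENERACY_FLOOR:
        # exact degeneracy with zero coupling: take the limiting coupling
        # from one regularization step away on each side.
        lo = adiabatize(model, x - _DEGENERACY_STEP)
        hi = adiabatize(model, x + _DEGENERACY_STEP)
        mean_u = 0.5 * (v11 + v22)
        mean_du = 0.5 * (d11 + d22)
        return AdiabaticPoint(x, mean_u, mean_u, mean_du, mean_du,
                              theta=0.5 * (lo.theta + hi.theta),
                              d12=0.5 * (lo.d12 + hi.d12), degenerate=True)
    gap = np.sqrt(s)
    dgap = (dv * ddv + 4.0 * v12 * d12v) / gap
    u1 = 0.5 * (v11 + v22 - gap)
    u2 = 0.5 * (v11 + v22 + gap)
    du1 = 0.5 * (d11 + d22 - dgap)
    du2 = 0.5 * (d11 + d22 + dgap)
    theta = 0.5 * np.arctan2(2.0 * v12, dv)
    d12 = (d12v * dv - v12 * ddv) / s
    return AdiabaticPoint(x, u1, u2, du1, du2, theta, d12)


def adiabatize_grid(model: DiabaticModel, x: np.ndarray) -> dict:
    """Vectorized adiabatic scan.

    Returns a dict of arrays ``x, u1, u2, du1, du2, theta, d12, gap`` with
    ``theta`` made continuous along increasing x (the 2*theta angle is
    unwrapped), matching the sign-continuity convention used along
    trajectories.
    """
    x = np.asarray(x, dtype=float)
    v11, v22, v12 = model.v11(x), model.v22(x), model.v12(x)
    d11, d22, d12v = model.dv11(x), model.dv22(x), model.dv12(x)
    dv = v11 - v22
    ddv = d11 - d22
    s = dv * dv + 4.0 * v12 * v12
    safe = np.maximum(s, _DEGENERACY_FLOOR)
    gap = np.sqrt(s)
    dgap = np.where(gap > 0, (dv * ddv + 4.0 * v12 * d12v) / np.sqrt(safe), 0.0)
    mean = 0.5 * (v11 + v22)
    dmean = 0.5 * (d11 + d22)
    theta = 0.5 * np.unwrap(np.arctan2(2.0 * v12, dv))
    d12 = (d12v * dv - v12 * ddv) / safe
    return {
        "x": x,
        "u1": mean - 0.5 * gap,
        "u2": mean + 0.5 * gap,
        "du1": dmean - 0.5 * dgap,
        "du2": dmean + 0.5 * dgap,
        "theta": theta,
        "d12": d12,
        "gap": gap,
    }


def find_diabatic_crossings(model: DiabaticModel, *, grid_step: float = 0.01,
                            xtol: float = 1e-10) -> list[float]:
    """Positions where V11(x) = V22(x), sorted.

    Sign changes of V11 - V22 are bracketed on a dense grid (default step
    0.01 Bohr) and refined by Brent bisection.  An empty list means the
    diabats never cross (Model 1).
    """
    span = model.x_span
    n = max(int(np.ceil(2 * span / grid_step)) + 1, 11)
    x = np.linspace(-span, span, n)
    f = np.asarray(model.v11(x) - model.v22(x), dtype=float)
    roots: list[float] = []
    fun = lambda z: float(model.v11(z) - model.v22(z))  # noqa: E731
    for i in np.flatnonzero(np.sign(f[:-1]) * np.sign(f[1:]) < 0):
        roots.append(brentq(fun, x[i], x[i + 1], xtol=xtol))
    # grid points that are exact zeros (Model 3 at x = 0)
    for i in np.flatnonzero(f == 0.0):
        roots.append(float(x[i]))
    return sorted(roots)


class GapExtremum(NamedTuple):
    x: float
    kind: str  # "min" or "max"
    gap: float


def find_gap_extrema(model: DiabaticModel, *, grid_step: float = 0.01,
                     kind: str = "all") -> list[GapExtremum]:
    """Interior local extrema of the adiabatic gap u2 - u1.

    A three-point test on a dense grid locates candidates which are refined
    by bounded scalar minimization (golden/Brent) to ~1e-8 Bohr.  ``kind``
    filters for "min", "max" or returns "all".
    """
    if kind not in ("all", "min", "max"):
        raise ValueError("kind must be 'all', 'min' or 'max'")
    span = model.x_span
    n = max(int(np.ceil(2 * span / grid_step)) + 1, 11)
    x = np.linspace(-span, span, n)
    scan = adiabatize_grid(model, x)
    g = scan["gap"]

    def gap_at(z: float) -> float:
        p = adiabatize(model, z)
        return p.u2 - p.u1

    out: list[GapExtremum] = []
    interior = np.arange(1, n - 1)
    is_min = (g[interior] <= g[interior - 1]) & (g[interior] <= g[interior + 1])
    is_max = (g[interior] >= g[interior - 1]) & (g[interior] >= g[interior + 1])
    for idx, m_lo, m_hi in zip(interior, is_min, is_max):
        if not (m_lo or m_hi):
            continue
        if m_lo and m_hi:
            continue  # flat plateau (asymptotically constant gap)
        # ignore float-noise wiggles where the gap is flat to ~1e-15 Hartree
        if max(abs(g[idx - 1] - g[idx]), abs(g[idx + 1] - g[idx])) < 1e-15:
            continue
        sign = 1.0 if m_lo else -1.0
        res = minimize_scalar(lambda z: sign * gap_at(z),
                              bounds=(x[idx - 1], x[idx + 1]), method="bounded",
                              options={"xatol": 1e-8})
        label = "min" if m_lo else "max"
        if kind in ("all", label):
            out.append(GapExtremum(float(res.x), label, gap_at(float(res.x))))
    # collapse duplicates from flat plateaus
    dedup: list[GapExtremum] = []
    for e in sorted(out):
        if not dedup or abs(e.x - dedup[-1].x) > 10 * grid_step * 1e-3 or \
                e.kind != dedup[-1].kind:
            dedup.append(e)
    return dedup
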