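"""Fewest-switches surface hopping in one dimension.

A trajectory starts on the lower adiabatic surface at x = -x_span with all
of the total energy E shared between the entrance kinetic energy and
u1(-x_span), and a pure |1><1| density matrix.  Nuclei move on the active
adiabatic surface; the electronic density matrix is propagated jointly by
RK4 (original or JWKB-modified diagonal term, reference potential = active
surface).  Each step one uniform number is drawn and a switch to the other
surface is attempted with the fewest-switches probability

    g = max(0, 2 dt xdot d12 Re(rho_other,active) / rho_active,active).

An accepted hop rescales the momentum along x to conserve E exactly;
a hop with insufficient energy is frustrated: the trajectory stays on its
surface with unchanged momentum (no velocity reversal).

The ensemble observable is the overall nonadiabatic transition
probability: the fraction of trajectories transmitted to x -> +infinity on
the upper surface (count estimator), alongside the ensemble mean of the
final rho_22 over transmitted trajectories (wavefunction estimator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _rng
from .adiabatic import AdiabaticPoint, adiabatize
from .electronic import ElectronicState, PhaseScheme
from .models import DiabaticModel

__all__ = ["TrajectoryState", "TrajectoryResult", "EnsembleResult",
           "hop_probability", "attempt_hop", "run_trajectory",
           "transition_probability", "default_max_steps"]

#: starved active population below which the hop probability is defined as 0
_POP_FLOOR = 1e-12


@dataclass
class TrajectoryState:
    """Instantaneous state of one surface-hopping trajectory."""

    x: float
    p: float
    t: float
    active: int                  # 1 = lower, 2 = upper adiabatic surface
    electronic: ElectronicState
    e_total: float
    mass: float = 2000.0


@dataclass
class TrajectoryResult:
    exit_side: str               # "right", "left" or "none" (truncated)
    state: TrajectoryState
    frustrated_hops: int
    n_steps: int
    truncated: bool
    energy_drift: float          # max |KE + u_active - E| between hops

    @property
    def transmitted_upper(self) -> bool:
        return self.exit_side == "right" and self.state.active == 2


@dataclass
class EnsembleResult:
    """Transition-probability estimates from a trajectory ensemble."""

    energy: float
    n_traj: int
    p_transition_counts: float   # fraction transmitted on the upper surface
    p_transition_wavefn: float   # mean final rho_22 over transmitted
    stderr: float                # binomial sqrt(p(1-p)/n) of the count rate
    n_transmitted: int
    n_reflected: int
    n_truncated: int
    n_frustrated: int
    seed: int
    scheme: str
    dt: float

    def __post_init__(self):
        for p in (self.p_transition_counts, self.p_transition_wavefn):
            if not -1e-12 <= p <= 1.0 + 1e-12:
                raise ValueError(f"probability {p} outside [0, 1]")


def hop_probability(traj: TrajectoryState, point: AdiabaticPoint,
                    dt: float) -> float:
    """Fewest-switches probability of leaving the active surface this step."""
    rho = traj.electronic.rho
    a = traj.active - 1
    o = 1 - a
    na = rho[a, a].real
    if na <= _POP_FLOOR:
        return 0.0
    d_ao = point.d12 if traj.active == 1 else -point.d12
    g = 2.0 * dt * (traj.p / traj.mass) * d_ao * rho[o, a].real / na
    return min(max(g, 0.0), 1.0)


def attempt_hop(traj: TrajectoryState, point: AdiabaticPoint,
                rng, *, dt: float | None = None,
                g: float | None = None) -> tuple[TrajectoryState, bool, bool]:
    """Stochastic switch attempt.

    ``rng`` is either a float draw in [0, 1) or an object with
    ``.uniform()``.  Returns (state, hopped, frustrated); an accepted hop
    rescales the momentum to conserve the total energy exactly, a
    frustrated one leaves the state untouched.
    """
    if g is None:
        if dt is None:
            raise ValueError("attempt_hop needs dt when g is not given")
        g = hop_probability(traj, point, dt)
    u = rng if isinstance(rng, float) else float(rng.uniform())
    if not (g > 0.0 and u < g):
        return traj, False, False
    target = 2 if traj.active == 1 else 1
    u_target = point.u2 if target == 2 else point.u1
    t_new = traj.e_total - u_target
    if t_new <= 0.0:
        return traj, False, True  # frustrated: keep surface and momentum
    p_new = math.copysign(math.sqrt(2.0 * traj.mass * t_new), traj.p)
    new = TrajectoryState(traj.x, p_new, traj.t, target,
                          traj.electronic, traj.e_total, traj.mass)
    return new, True, False


def default_max_steps(model: DiabaticModel, e_total: float,
                      dt: float) -> int:
    """Step budget: six crossings of the box at the slowest open-channel
    speed (guards against trapped mean-field-like paths)."""
    floor = max(model.upper_asymptote("left"),
                model.upper_asymptote("right"))
    ke = e_total - floor
    if ke <= 0.0:
        ke = e_total - model.lower_asymptote("left")
    v_slow = math.sqrt(2.0 * ke / model.mass)
    return int(math.ceil(6.0 * (2.0 * model.x_span) / (v_slow * dt)))


def run_trajectory(model: DiabaticModel, e_total: float,
                   scheme: PhaseScheme | str, seed: int, *,
                   traj_id: int = 0, dt: float = 1.0,
                   max_steps: int | None = None) -> TrajectoryResult:
    """Propagate one surface-hopping trajectory (pure-Python reference).

    Mirrors the compiled kernel step for step, drawing the same
    counter-based uniform stream, so both engines produce the same hops
    for the same (seed, traj_id).
    """
    scheme = _as_scheme(scheme, e_total)
    u1s = adiabatize(model, -model.x_span).u1
    ke0 = e_total - u1s
    if ke0 <= 0.0:
        raise ValueError(
            f"total energy {e_total} does not open the entrance channel")
    if max_steps is None:
        max_steps = default_max_steps(model, e_total, dt)
    mass = model.mass
    span = model.x_span
    modified = scheme.modified

    x = -span
    p = math.sqrt(2.0 * mass * ke0)
    active = 1
    n1, n2, cr, ci = 1.0, 0.0, 0.0, 0.0
    nfrus = 0
    drift = 0.0
    exit_side = "none"
    step = 0

    def deriv(active, x, p, n1, n2, cr, ci):
        pt = adiabatize(model, x)
        v = p / mass
        if active == 1:
            force, u_ref = -pt.du1, pt.u1
        else:
            force, u_ref = -pt.du2, pt.u2
        if modified:
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
        ua = pt.u1 if active == 1 else pt.u2
        drift = max(drift, abs(p * p / (2.0 * mass) + ua - e_total))
        na = n1 if active == 1 else n2
        if na > _POP_FLOOR:
            vd = (p / mass) * pt.d12
            g = (dt * 2.0 * vd * cr / na if active == 1
                 else -dt * 2.0 * vd * cr / na)
            g = min(g, 1.0)
            if g > 0.0 and _rng.uniform(seed, traj_id, step) < g:
                u_target = pt.u2 if active == 1 else pt.u1
                t_new = e_total - u_target
                if t_new > 0.0:
                    p = math.copysign(math.sqrt(2.0 * mass * t_new), p)
                    active = 2 if active == 1 else 1
                else:
                    nfrus += 1
        a1, b1, c1, d1, e1, f1 = deriv(active, x, p, n1, n2, cr, ci)
        h2 = 0.5 * dt
        a2, b2, c2, d2, e2, f2 = deriv(active, x + h2 * a1, p + h2 * b1,
                                       n1 + h2 * c1, n2 + h2 * d1,
                                       cr + h2 * e1, ci + h2 * f1)
        a3, b3, c3, d3, e3, f3 = deriv(active, x + h2 * a2, p + h2 * b2,
                                       n1 + h2 * c2, n2 + h2 * d2,
                                       cr + h2 * e2, ci + h2 * f2)
        a4, b4, c4, d4, e4, f4 = deriv(active, x + dt * a3, p + dt * b3,
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
    state = TrajectoryState(x, p, (step + 1) * dt, active,
                            ElectronicState(rho), e_total, mass)
    return TrajectoryResult(exit_side, state, nfrus, step + 1,
                            truncated=(exit_side == "none"),
                            energy_drift=drift)


def _as_scheme(scheme: PhaseScheme | str, e_total: float) -> PhaseScheme:
    if isinstance(scheme, PhaseScheme):
        return scheme
    if scheme == "modified":
        return PhaseScheme("modified", e_total=e_total, reference="active")
    return PhaseScheme("original")


def transition_probability(model: DiabaticModel, e_total: float,
                           scheme: PhaseScheme | str, n_traj: int,
                           seed: int, *, dt: float = 1.0,
                           max_steps: int | None = None,
                           engine: str = "auto") -> EnsembleResult:
    """Ensemble transition probability at one total energy.

    ``engine`` is "auto" (compiled kernel for built-in models, Python
    otherwise), "kernel" or "python".
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    scheme = _as_scheme(scheme, e_total)
    if max_steps is None:
        max_steps = default_max_steps(model, e_total, dt)

    use_kernel = (engine == "kernel"
                  or (engine == "auto" and model.kernel_id > 0))
    if use_kernel:
        if model.kernel_id <= 0:
            raise ValueError("model has no compiled kernel")
        from ._kernels import fssh_ensemble
        par = np.asarray(model.kernel_params, dtype=float)
        exit_code, final_active, final_rho22, frustrated, _drift = \
            fssh_ensemble(model.kernel_id, par, model.mass, model.x_span,
                          e_total, n_traj, dt, scheme.modified, seed,
                          max_steps)
        transmitted = exit_code == 1
        upper = transmitted & (final_active == 2)
        rho22_t = final_rho22[transmitted]
        n_trans = int(transmitted.sum())
        n_refl = int((exit_code == -1).sum())
        n_trunc = int((exit_code == 0).sum())
        n_frus = int(frustrated.sum())
        p_counts = float(upper.sum()) / n_traj
        p_wavefn = float(rho22_t.mean()) if n_trans else 0.0
    else:
        n_upper = 0
        n_trans = n_refl = n_trunc = n_frus = 0
        rho22_sum = 0.0
        for i in range(n_traj):
            res = run_trajectory(model, e_total, scheme, seed, traj_id=i,
                                 dt=dt, max_steps=max_steps)
            n_frus += res.frustrated_hops
            if res.truncated:
                n_trunc += 1
            elif res.exit_side == "left":
                n_refl += 1
            else:
                n_trans += 1
                rho22_sum += res.state.electronic.rho[1, 1].real
                if res.state.active == 2:
                    n_upper += 1
        p_counts = n_upper / n_traj
        p_wavefn = rho22_sum / n_trans if n_trans else 0.0

    stderr = math.sqrt(max(p_counts * (1.0 - p_counts), 0.0) / n_traj)
    return EnsembleResult(e_total, n_traj, p_counts, min(p_wavefn, 1.0),
                          stderr, n_trans, n_refl, n_trunc, n_frus,
                          seed, scheme.kind, dt)
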