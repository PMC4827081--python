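"""Compiled (numba) trajectory engines for the built-in models.

The pure-Python modules :mod:`cohsh.fssh` and :mod:`cohsh.ehrenfest` define
the algorithms; these kernels re-state them with the four benchmark
potential forms hard-coded (dispatch on ``kernel_id``) so that
paper-scale ensembles (10^4 trajectories per energy) run in seconds.
Custom models fall back to the Python engines.  A test pins the two
implementations against each other.

All kernels consume the same counter-based uniform stream as
:mod:`cohsh._rng`, so Python and compiled runs of the same seed hop
identically.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_U = np.uint64
_GOLDEN = _U(0x9E3779B97F4A7C15)
_K_TRAJ = _U(0xD1B54A32D192ED03)
_K_STEP = _U(0x8CB92BA72F3D8DD7)
_M1 = _U(0xBF58476D1CE4E5B9)
_M2 = _U(0x94D049BB133111EB)


@njit(cache=True, inline="always")
def _u01(seed, traj, step):
    z = _U(seed) * _GOLDEN + _U(traj) * _K_TRAJ + _U(step) * _K_STEP + _GOLDEN
    z ^= z >> _U(30)
    z *= _M1
    z ^= z >> _U(27)
    z *= _M2
    z ^= z >> _U(31)
    return float(z >> _U(11)) * 1.1102230246251565e-16  # 2**-53


@njit(cache=True, inline="always")
def _diabatic(mid, par, x):
    """(v11, v22, v12, dv11, dv22, dv12) for built-in model ``mid``."""
    if mid == 1:
        a, b, x0, c = par[0], par[1], par[2], par[3]
        g1 = b * np.exp(-c * (x - x0) ** 2)
        g2 = b * np.exp(-c * (x + x0) ** 2)
        return (0.0, a, g1 + g2, 0.0, 0.0,
                -2.0 * c * (x - x0) * g1 - 2.0 * c * (x + x0) * g2)
    elif mid == 2:
        a, b, e0, c, d = par[0], par[1], par[2], par[3], par[4]
        eb = np.exp(-b * x * x)
        v12 = c * np.exp(-d * x * x)
        return (0.0, -a * eb + e0, v12, 0.0, 2.0 * a * b * x * eb,
                -2.0 * d * x * v12)
    else:  # mid == 3 or 4 share the diabats
        a, b, c, d = par[0], par[1], par[2], par[3]
        ax = x if x >= 0.0 else -x
        ex = np.exp(-b * ax)
        v11 = a * (1.0 - ex) if x >= 0.0 else -a * (1.0 - ex)
        dv11 = a * b * ex
        ed = np.exp(-d * x * x)
        if mid == 3:
            v12 = c * ed
            dv12 = -2.0 * d * x * v12
        else:
            v12 = c * x * x * ed
            dv12 = c * (2.0 * x - 2.0 * d * x ** 3) * ed
        return (v11, -v11, v12, dv11, -dv11, dv12)


@njit(cache=True, inline="always")
def _adiabatic(mid, par, x):
    """(u1, u2, du1, du2, d12); degeneracies regularized one step away."""
    v11, v22, v12, dv11, dv22, dv12 = _diabatic(mid, par, x)
    dv = v11 - v22
    ddv = dv11 - dv22
    s = dv * dv + 4.0 * v12 * v12
    if s < 1e-30:
        # exact degeneracy (Model 4 at x = 0): average the analytic
        # coupling one small step to either side, surfaces touch.
        eps = 1e-6
        v11l, v22l, v12l, dv11l, dv22l, dv12l = _diabatic(mid, par, x - eps)
        v11r, v22r, v12r, dv11r, dv22r, dv12r = _diabatic(mid, par, x + eps)
        dvl = v11l - v22l
        dvr = v11r - v22r
        sl = dvl * dvl + 4.0 * v12l * v12l
        sr = dvr * dvr + 4.0 * v12r * v12r
        d12 = 0.5 * ((dv12l * dvl - v12l * (dv11l - dv22l)) / sl
                     + (dv12r * dvr - v12r * (dv11r - dv22r)) / sr)
        mean_u = 0.5 * (v11 + v22)
        mean_du = 0.5 * (dv11 + dv22)
        return mean_u, mean_u, mean_du, mean_du, d12
    gap = np.sqrt(s)
    dgap = (dv * ddv + 4.0 * v12 * dv12) / gap
    mean_u = 0.5 * (v11 + v22)
    mean_du = 0.5 * (dv11 + dv22)
    d12 = (dv12 * dv - v12 * ddv) / s
    return (mean_u - 0.5 * gap, mean_u + 0.5 * gap,
            mean_du - 0.5 * dgap, mean_du + 0.5 * dgap, d12)


@njit(cache=True, inline="always")
def _delta12(u1, u2, u_ref, e_total, modified):
    """Diagonal term for the (1,2) coherence; forbidden roots clamped."""
    if not modified:
        return u1 - u2
    t_ref = e_total - u_ref
    if t_ref < 0.0:
        t_ref = 0.0
    t1 = e_total - u1
    t2 = e_total - u2
    s1 = np.sqrt(t1) if t1 > 0.0 else 0.0
    s2 = np.sqrt(t2) if t2 > 0.0 else 0.0
    return 2.0 * np.sqrt(t_ref) * (s2 - s1)


@njit(cache=True, inline="always")
def _deriv_fssh(mid, par, mass, e_total, modified, active,
                x, p, n1, n2, cr, ci):
    u1, u2, du1, du2, d12 = _adiabatic(mid, par, x)
    v = p / mass
    if active == 1:
        force = -du1
        u_ref = u1
    else:
        force = -du2
        u_ref = u2
    delta = _delta12(u1, u2, u_ref, e_total, modified)
    vd = v * d12
    flux = 2.0 * vd * cr
    return (v, force, -flux, flux, delta * ci - vd * (n2 - n1), -delta * cr)


@njit(cache=True, inline="always")
def _deriv_mf(mid, par, mass, e_total, modified, x, p, n1, n2, cr, ci):
    u1, u2, du1, du2, d12 = _adiabatic(mid, par, x)
    v = p / mass
    force = -(n1 * du1 + n2 * du2) - 2.0 * cr * d12 * (u2 - u1)
    u_ref = n1 * u1 + n2 * u2
    delta = _delta12(u1, u2, u_ref, e_total, modified)
    vd = v * d12
    flux = 2.0 * vd * cr
    return (v, force, -flux, flux, delta * ci - vd * (n2 - n1), -delta * cr)


@njit(cache=True)
def fssh_ensemble(mid, par, mass, x_span, e_total, n_traj, dt, modified,
                  seed, max_steps):
    """Fewest-switches ensemble at one total energy.

    Returns per-trajectory arrays: exit code (+1 right, -1 left,
    0 truncated), final active surface, final rho_22, frustrated-hop
    count, and max energy-conservation drift |KE + U_active - E| observed
    between hops.
    """
    exit_code = np.zeros(n_traj, dtype=np.int8)
    final_active = np.zeros(n_traj, dtype=np.int8)
    final_rho22 = np.zeros(n_traj)
    frustrated = np.zeros(n_traj, dtype=np.int32)
    drift = np.zeros(n_traj)

    x_start = -x_span
    u1s, u2s, du1s, du2s, d12s = _adiabatic(mid, par, x_start)
    ke0 = e_total - u1s
    p_start = np.sqrt(2.0 * mass * ke0)

    for itraj in range(n_traj):
        x = x_start
        p = p_start
        active = 1
        n1 = 1.0
        n2 = 0.0
        cr = 0.0
        ci = 0.0
        nfrus = 0
        dmax = 0.0
        code = np.int8(0)
        for step in range(max_steps):
            u1, u2, du1, du2, d12 = _adiabatic(mid, par, x)
            ua = u1 if active == 1 else u2
            e_err = abs(p * p / (2.0 * mass) + ua - e_total)
            if e_err > dmax:
                dmax = e_err
            # --- fewest-switches hop attempt (before the nuclear step) ---
            na = n1 if active == 1 else n2
            if na > 1e-12:
                vd = (p / mass) * d12
                if active == 1:
                    g = dt * 2.0 * vd * cr / na
                else:
                    g = -dt * 2.0 * vd * cr / na
                if g > 1.0:
                    g = 1.0
                if g > 0.0 and _u01(seed, itraj, step) < g:
                    u_target = u2 if active == 1 else u1
                    t_new = e_total - u_target
                    if t_new > 0.0:
                        p_new = np.sqrt(2.0 * mass * t_new)
                        p = p_new if p >= 0.0 else -p_new
                        active = 2 if active == 1 else 1
                    else:
                        nfrus += 1
            # --- joint RK4 step of (x, p, rho) on the active surface ---
            a1, b1, c1, d1, e1, f1 = _deriv_fssh(
                mid, par, mass, e_total, modified, active, x, p, n1, n2, cr, ci)
            h2 = 0.5 * dt
            a2, b2, c2, d2, e2, f2 = _deriv_fssh(
                mid, par, mass, e_total, modified, active,
                x + h2 * a1, p + h2 * b1, n1 + h2 * c1, n2 + h2 * d1,
                cr + h2 * e1, ci + h2 * f1)
            a3, b3, c3, d3, e3, f3 = _deriv_fssh(
                mid, par, mass, e_total, modified, active,
                x + h2 * a2, p + h2 * b2, n1 + h2 * c2, n2 + h2 * d2,
                cr + h2 * e2, ci + h2 * f2)
            a4, b4, c4, d4, e4, f4 = _deriv_fssh(
                mid, par, mass, e_total, modified, active,
                x + dt * a3, p + dt * b3, n1 + dt * c3, n2 + dt * d3,
                cr + dt * e3, ci + dt * f3)
            w = dt / 6.0
            x += w * (a1 + 2.0 * a2 + 2.0 * a3 + a4)
            p += w * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
            n1 += w * (c1 + 2.0 * c2 + 2.0 * c3 + c4)
            n2 += w * (d1 + 2.0 * d2 + 2.0 * d3 + d4)
            cr += w * (e1 + 2.0 * e2 + 2.0 * e3 + e4)
            ci += w * (f1 + 2.0 * f2 + 2.0 * f3 + f4)
            if x > x_span and p > 0.0:
                code = np.int8(1)
                break
            if x < -x_span and p < 0.0:
                code = np.int8(-1)
                break
        exit_code[itraj] = code
        final_active[itraj] = active
        final_rho22[itraj] = n2
        frustrated[itraj] = nfrus
        drift[itraj] = dmax
    return exit_code, final_active, final_rho22, frustrated, drift


@njit(cache=True)
def ehrenfest_batch(mid, par, mass, x_span, energies, dt, modified,
                    max_steps):
    """Deterministic mean-field trajectories, one per total energy.

    Returns exit codes (+1 right / -1 left / 0 truncated), final rho_22,
    final (x, p), and the max drift of KE + Tr(rho H) from its initial
    value along each trajectory.
    """
    n = energies.shape[0]
    exit_code = np.zeros(n, dtype=np.int8)
    final_rho22 = np.zeros(n)
    final_x = np.zeros(n)
    final_p = np.zeros(n)
    drift = np.zeros(n)

    x_start = -x_span
    u1s, u2s, du1s, du2s, d12s = _adiabatic(mid, par, x_start)

    for ie in range(n):
        e_total = energies[ie]
        x = x_start
        p = np.sqrt(2.0 * mass * (e_total - u1s))
        n1 = 1.0
        n2 = 0.0
        cr = 0.0
        ci = 0.0
        dmax = 0.0
        code = np.int8(0)
        for step in range(max_steps):
            u1, u2, du1, du2, d12 = _adiabatic(mid, par, x)
            e_err = abs(p * p / (2.0 * mass) + n1 * u1 + n2 * u2 - e_total)
            if e_err > dmax:
                dmax = e_err
            a1, b1, c1, d1, e1, f1 = _deriv_mf(
                mid, par, mass, e_total, modified, x, p, n1, n2, cr, ci)
            h2 = 0.5 * dt
            a2, b2, c2, d2, e2, f2 = _deriv_mf(
                mid, par, mass, e_total, modified,
                x + h2 * a1, p + h2 * b1, n1 + h2 * c1, n2 + h2 * d1,
                cr + h2 * e1, ci + h2 * f1)
            a3, b3, c3, d3, e3, f3 = _deriv_mf(
                mid, par, mass, e_total, modified,
                x + h2 * a2, p + h2 * b2, n1 + h2 * c2, n2 + h2 * d2,
                cr + h2 * e2, ci + h2 * f2)
            a4, b4, c4, d4, e4, f4 = _deriv_mf(
                mid, par, mass, e_total, modified,
                x + dt * a3, p + dt * b3, n1 + dt * c3, n2 + dt * d3,
                cr + dt * e3, ci + dt * f3)
            w = dt / 6.0
            x += w * (a1 + 2.0 * a2 + 2.0 * a3 + a4)
            p += w * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
            n1 += w * (c1 + 2.0 * c2 + 2.0 * c3 + c4)
            n2 += w * (d1 + 2.0 * d2 + 2.0 * d3 + d4)
            cr += w * (e1 + 2.0 * e2 + 2.0 * e3 + e4)
            ci += w * (f1 + 2.0 * f2 + 2.0 * f3 + f4)
            if x > x_span and p > 0.0:
                code = np.int8(1)
                break
            if x < -x_span and p < 0.0:
                code = np.int8(-1)
                break
        exit_code[ie] = code
        final_rho22[ie] = n2
        final_x[ie] = x
        final_p[ie] = p
        drift[ie] = dmax
    return exit_code, final_rho22, final_x, final_p, drift
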