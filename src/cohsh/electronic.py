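"""Electronic density-matrix propagation along a classical trajectory.

Two-state density matrix rho (rho_11 + rho_22 = 1) driven by

    i d(rho_kj)/dt = Delta_kj rho_kj
                     - i sum_l [ xdot d_kl rho_lj - rho_kl xdot d_lj ]

with hbar = 1 and real scalar coupling d_12 = -d_21.  The diagonal phase
term Delta_kj comes in two flavours:

* original:  Delta_kj = U_k - U_j, the bare adiabatic gap;
* modified:  Delta_kj = 2 sqrt(E - U_ref) (sqrt(E - U_j) - sqrt(E - U_k)),
  i.e. velocity times the local JWKB wavenumber difference
  hbar (k_j - k_k) evaluated on a reference potential U_ref.  U_ref is the
  active adiabatic surface for surface hopping or the population-averaged
  potential for mean-field dynamics.  In the high-energy regime
  E - U >> |U_k - U_j| the two flavours coincide; at low energy the
  JWKB form restores the spatial phase an actual scattering wavefunction
  would accumulate, which is what repairs the coherence of the
  trajectory ensemble.

Square roots of classically forbidden factors (E < U_k) are clamped to
zero: Delta stays real, so norm conservation is exact in the algebra, and
the coherence against an inaccessible state simply stops accumulating
phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .adiabatic import AdiabaticPoint

__all__ = ["ElectronicState", "PhaseScheme", "gap_term_original",
           "gap_term_modified", "rhs", "rk4_step", "check_density_matrix"]

_HERM_TOL = 1e-12
_TRACE_TOL = 1e-8
_POP_SLACK = 1e-10


def check_density_matrix(rho: np.ndarray, *, trace_tol: float = _TRACE_TOL,
                         herm_tol: float = _HERM_TOL) -> None:
    """Raise ValueError if rho is not a valid 2x2 electronic density matrix."""
    rho = np.asarray(rho)
    if rho.shape != (2, 2):
        raise ValueError(f"density matrix must be 2x2, got shape {rho.shape}")
    if not np.all(np.isfinite(rho.view(float))):
        raise ValueError("density matrix contains non-finite entries")
    if np.max(np.abs(rho - rho.conj().T)) > herm_tol:
        raise ValueError("density matrix is not Hermitian")
    if abs(rho[0, 0].real + rho[1, 1].real - 1.0) > trace_tol:
        raise ValueError("density matrix trace differs from 1")
    for k in (0, 1):
        if not -_POP_SLACK <= rho[k, k].real <= 1.0 + _POP_SLACK:
            raise ValueError(f"population rho[{k},{k}] outside [0, 1]")


@dataclass
class ElectronicState:
    """2x2 complex density matrix of electronic populations/coherences."""

    rho: np.ndarray

    @classmethod
    def pure(cls, surface: int) -> "ElectronicState":
        """|surface><surface| with surface in {1, 2} (1 = lower)."""
        if surface not in (1, 2):
            raise ValueError("surface must be 1 or 2")
        rho = np.zeros((2, 2), dtype=complex)
        rho[surface - 1, surface - 1] = 1.0
        return cls(rho)

    def validate(self) -> None:
        check_density_matrix(self.rho)

    @property
    def populations(self) -> tuple[float, float]:
        return float(self.rho[0, 0].real), float(self.rho[1, 1].real)

    @property
    def coherence(self) -> complex:
        return complex(self.rho[0, 1])


@dataclass(frozen=True)
class PhaseScheme:
    """Choice of diagonal phase term for the electronic equations.

    kind: "original" (bare gap) or "modified" (JWKB wavenumber form).
    e_total: conserved total energy, required for the modified scheme.
    reference: "active" (surface hopping) or "average" (mean field);
        selects how U_ref is obtained by the dynamics driver.
    """

    kind: str = "original"
    e_total: float | None = None
    reference: str = "active"

    def __post_init__(self):
        if self.kind not in ("original", "modified"):
            raise ValueError("kind must be 'original' or 'modified'")
        if self.reference not in ("active", "average"):
            raise ValueError("reference must be 'active' or 'average'")
        if self.kind == "modified" and self.e_total is None:
            raise ValueError("modified scheme requires e_total")

    @property
    def modified(self) -> bool:
        return self.kind == "modified"


def gap_term_original(u_j: float, u_k: float) -> float:
    """Bare diagonal phase term U_k - U_j for the (k, j) coherence."""
    return u_k - u_j


def gap_term_modified(u_j: float, u_k: float, u_ref: float,
                      e_total: float) -> float:
    """JWKB-consistent diagonal phase term.

    D_kj = 2 sqrt(E - U_ref) (sqrt(E - U_j) - sqrt(E - U_k)), the product of
    the classical velocity on the reference potential and the local
    wavenumber difference.  Equals U_k - U_j in the limit
    E - U_ref >> |U_k - U_j| and exceeds it at low energy, where the actual
    spatial phase accumulates faster than the bare-gap clock.

    E < U_ref (negative kinetic energy on the reference surface) is a
    precondition violation; E = U_ref (a classical turning point) returns 0.
    Classically forbidden factors sqrt(E - U) with U > E are clamped to 0.
    """
    t_ref = e_total - u_ref
    if t_ref < 0.0:
        raise ValueError(
            f"total energy {e_total} below reference potential {u_ref}")
    s_j = np.sqrt(max(e_total - u_j, 0.0))
    s_k = np.sqrt(max(e_total - u_k, 0.0))
    return 2.0 * np.sqrt(t_ref) * (s_j - s_k)


def _delta12(point: AdiabaticPoint, scheme: PhaseScheme,
             u_ref: float | None) -> float:
    """Diagonal term for the (1,2) coherence (negative of the (2,1) term)."""
    if not scheme.modified:
        return gap_term_original(point.u2, point.u1)
    if u_ref is None:
        u_ref = point.u1 if scheme.reference == "active" else None
        if u_ref is None:
            raise ValueError("average-reference scheme needs explicit u_ref")
    # clamp infinitesimally negative kinetic energies from integrator stages
    e = scheme.e_total
    t_ref = max(e - u_ref, 0.0)
    s1 = np.sqrt(max(e - point.u1, 0.0))
    s2 = np.sqrt(max(e - point.u2, 0.0))
    return 2.0 * np.sqrt(t_ref) * (s2 - s1)


def rhs(rho: np.ndarray, point: AdiabaticPoint, velocity: float,
        scheme: PhaseScheme, *, u_ref: float | None = None,
        validate: bool = False) -> np.ndarray:
    """Time derivative of the density matrix at one trajectory point.

    ``u_ref`` overrides the reference potential for the modified scheme
    (mean-field drivers pass the population-averaged potential); by default
    the active surface is taken to be the lower state ``u1``.
    """
    if validate:
        check_density_matrix(rho)
    if not np.isfinite(velocity):
        raise ValueError("velocity must be finite")
    delta = _delta12(point, scheme, u_ref)
    vd = velocity * point.d12
    r12 = rho[0, 1]
    drho = np.empty((2, 2), dtype=complex)
    flux = 2.0 * vd * r12.real          # population flow 1 -> 2
    drho[0, 0] = -flux
    drho[1, 1] = flux
    drho[0, 1] = -1j * delta * r12 - vd * (rho[1, 1] - rho[0, 0])
    drho[1, 0] = np.conj(drho[0, 1])
    return drho


def rk4_step(rho: np.ndarray, t: float, dt: float,
             point_at: Callable[[float], AdiabaticPoint],
             velocity_at: Callable[[float], float],
             scheme: PhaseScheme, *,
             u_ref_at: Callable[[float], float] | None = None) -> np.ndarray:
    """One classical RK4 step of the electronic equations alone.

    ``point_at(t)`` / ``velocity_at(t)`` provide the nuclear path;
    adiabatic quantities are re-evaluated at the half- and full-step times
    (no interpolation).  Used for prescribed-path propagation and
    convergence studies; the dynamics drivers integrate nuclei and
    electrons jointly instead.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")

    def ref(tau):
        return None if u_ref_at is None else u_ref_at(tau)

    h = dt
    k1 = rhs(rho, point_at(t), velocity_at(t), scheme, u_ref=ref(t))
    mid = t + 0.5 * h
    p_mid = point_at(mid)
    v_mid = velocity_at(mid)
    r_mid = ref(mid)
    k2 = rhs(rho + 0.5 * h * k1, p_mid, v_mid, scheme, u_ref=r_mid)
    k3 = rhs(rho + 0.5 * h * k2, p_mid, v_mid, scheme, u_ref=r_mid)
    k4 = rhs(rho + h * k3, point_at(t + h), velocity_at(t + h), scheme,
             u_ref=ref(t + h))
    return rho + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
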