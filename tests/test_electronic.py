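import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from cohsh.adiabatic import AdiabaticPoint, adiabatize
from cohsh.electronic import (ElectronicState, PhaseScheme, check_density_matrix,
                              gap_term_modified, gap_term_original, rhs,
                              rk4_step)


def _point(u1=0.0, u2=0.03, d12=0.0, x=0.0):
    return AdiabaticPoint(x, u1, u2, 0.0, 0.0, 0.0, d12)


class TestGapTerms:
    def test_original_is_bare_gap(self):
        assert gap_term_original(0.0, 0.03) == 0.03
        assert gap_term_original(0.01, 0.01) == 0.0
        assert gap_term_original(0.03, 0.0) == -gap_term_original(0.0, 0.03)

    def test_modified_degenerate_surfaces_give_zero(self):
        assert gap_term_modified(0.02, 0.02, 0.01, 5.0) == 0.0

    def test_modified_high_energy_value(self):
        # E = 10, gap 0.03: 2 sqrt(10)(sqrt(10) - sqrt(9.97)) = 0.0300113...
        val = gap_term_modified(0.0, 0.03, 0.0, 10.0)
        assert val == pytest.approx(2 * math.sqrt(10)
                                    * (math.sqrt(10) - math.sqrt(9.97)),
                                    rel=1e-12)
        # leading deviation is delta/(4E) = 7.5e-4, inside the delta/(2E) bound
        assert abs(val - 0.03) / 0.03 < 1e-3

    def test_modified_low_energy_enhancement(self):
        # at E barely above the upper surface the phase runs ~22% fast
        val = gap_term_modified(0.0, 0.03, 0.0, 0.05)
        expect = 2 * math.sqrt(0.05) * (math.sqrt(0.05) - math.sqrt(0.02))
        assert val == pytest.approx(expect, rel=1e-12)
        assert val == pytest.approx(0.036754, abs=1e-5)
        assert (val - 0.03) / 0.03 > 0.2

    def test_modified_forbidden_branch_clamped(self):
        # upper surface classically forbidden: sqrt(E - u_k) -> 0
        val = gap_term_modified(0.0, 0.06, 0.0, 0.05)
        assert val == pytest.approx(2 * 0.05, rel=1e-12)

    def test_modified_below_reference_raises(self):
        with pytest.raises(ValueError):
            gap_term_modified(0.0, 0.03, 0.06, 0.05)

    def test_turning_point_returns_zero(self):
        assert gap_term_modified(0.05, 0.08, 0.05, 0.05) == 0.0

    @given(st.floats(0.0, 0.05), st.floats(1e-4, 0.05), st.floats(0.0, 1.0),
           st.floats(10.0, 1000.0))
    @settings(max_examples=200, deadline=None)
    def test_high_energy_bound(self, u_j, delta, frac, factor):
        """Relative deviation from the bare gap is bounded by
        delta / (2 (E - u_ref)) whenever E - u_ref >= 10 delta."""
        u_k = u_j + delta
        u_ref = u_j + frac * delta           # reference between the surfaces
        e_total = u_ref + factor * delta
        bare = gap_term_original(u_j, u_k)
        mod = gap_term_modified(u_j, u_k, u_ref, e_total)
        bound = delta / (2.0 * (e_total - u_ref))
        assert abs(mod - bare) / bare <= bound + 1e-12

    def test_monotone_approach_to_bare_gap(self):
        gaps = [abs(gap_term_modified(0.0, 0.03, 0.0, e) - 0.03)
                for e in (0.1, 0.3, 1.0, 3.0, 10.0)]
        assert all(a > b for a, b in zip(gaps, gaps[1:]))


class TestRhs:
    def test_no_coupling_freezes_populations(self):
        rho = np.array([[0.7, 0.2 + 0.1j], [0.2 - 0.1j, 0.3]])
        d = rhs(rho, _point(d12=0.0), 0.01, PhaseScheme("original"))
        assert d[0, 0] == 0 and d[1, 1] == 0
        # coherence only rotates: |rho12| stays constant
        assert np.vdot(rho[0, 1], d[0, 1]).real == pytest.approx(0.0,
                                                                 abs=1e-18)

    def test_pure_state_needs_coherence_to_transfer(self):
        rho = ElectronicState.pure(1).rho
        d = rhs(rho, _point(d12=1.0), 0.01, PhaseScheme("original"))
        assert d[1, 1] == 0.0  # second-order growth only

    @given(st.floats(0.0, 1.0), st.floats(-0.5, 0.5), st.floats(-0.5, 0.5),
           st.floats(-2.0, 2.0), st.floats(-0.02, 0.02))
    @settings(max_examples=100, deadline=None)
    def test_rhs_traceless_and_hermitian(self, pop, re12, im12, d12, v):
        mag = math.sqrt(pop * (1 - pop))
        scale = math.hypot(re12, im12) or 1.0
        coh = complex(re12, im12) * min(1.0, mag / scale)
        rho = np.array([[pop, coh], [np.conj(coh), 1 - pop]])
        for scheme in (PhaseScheme("original"),
                       PhaseScheme("modified", e_total=1.0)):
            d = rhs(rho, _point(d12=d12), v, scheme)
            assert d[0, 0] + d[1, 1] == 0.0
            assert np.allclose(d, d.conj().T, atol=0.0)

    def test_invalid_density_matrix_rejected(self):
        bad = np.array([[1.2, 0.0], [0.0, -0.2]])
        with pytest.raises(ValueError):
            rhs(bad, _point(), 0.0, PhaseScheme("original"), validate=True)
        with pytest.raises(ValueError):
            check_density_matrix(np.eye(2))


class TestRk4:
    @staticmethod
    def _const_path(point):
        return (lambda t: point), (lambda t: 0.01)

    def test_zero_rhs_leaves_state_unchanged(self):
        rho0 = np.array([[0.5, 0.5], [0.5, 0.5]], dtype=complex)
        point_at, vel_at = self._const_path(_point(u1=0.01, u2=0.01))
        rho = rk4_step(rho0, 0.0, 1.0, point_at, vel_at,
                       PhaseScheme("original"))
        assert np.array_equal(rho, rho0)

    def test_constant_gap_phase_advance(self):
        delta = 0.03
        rho0 = np.array([[0.5, 0.5], [0.5, 0.5]], dtype=complex)
        point_at, vel_at = self._const_path(_point(u2=delta))
        dt = 1.0
        rho = rho0
        for k in range(200):
            rho = rk4_step(rho, k * dt, dt, point_at, vel_at,
                           PhaseScheme("original"))
        # rho12 rotates as exp(+i delta t) (Delta_12 = u1 - u2 = -delta)
        expect = 0.5 * np.exp(1j * delta * 200 * dt)
        assert abs(rho[0, 1] - expect) < 1e-7

    def test_rk4_convergence_order(self, model2):
        """Richardson step-halving on a prescribed crossing passage."""
        e_total = 0.1
        v = math.sqrt(2 * e_total / model2.mass)
        x_of = lambda t: -6.0 + v * t  # noqa: E731
        point_at = lambda t: adiabatize(model2, x_of(t))  # noqa: E731
        vel_at = lambda t: v  # noqa: E731
        scheme = PhaseScheme("modified", e_total=e_total)
        t_end = 12.0 / v

        def propagate(dt):
            n = int(round(t_end / dt))
            rho = ElectronicState.pure(1).rho
            for k in range(n):
                rho = rk4_step(rho, k * dt, dt, point_at, vel_at, scheme)
            return rho

        coarse = propagate(4.0)
        fine = propagate(2.0)
        reference = propagate(0.25)
        e_coarse = np.max(np.abs(coarse - reference))
        e_fine = np.max(np.abs(fine - reference))
        assert math.log2(e_coarse / e_fine) >= 3.8


def test_zero_coupling_phase_matches_quadrature(gap_no_coupling):
    """With d12 = 0 the coherence phase is the quadrature of the gap term."""
    model = gap_no_coupling
    e_total = 0.1
    mass = model.mass
    x0 = -8.0

    for kind in ("original", "modified"):
        scheme = (PhaseScheme(kind) if kind == "original"
                  else PhaseScheme(kind, e_total=e_total))
        # constant-velocity path (flat lower diabat, uncoupled)
        v = math.sqrt(2 * (e_total - 0.0) / mass)
        x_of = lambda t: x0 + v * t  # noqa: E731
        point_at = lambda t: adiabatize(model, x_of(t))  # noqa: E731
        dt = 0.5
        n = int(16.0 / (v * dt))
        rho = np.array([[0.5, 0.5], [0.5, 0.5]], dtype=complex)
        for k in range(n):
            rho = rk4_step(rho, k * dt, dt, point_at, lambda t: v, scheme)
        assert rho[0, 0].real == pytest.approx(0.5, abs=1e-12)
        assert abs(rho[0, 1]) == pytest.approx(0.5, abs=1e-6)

        def delta12_at(t):
            pt = point_at(t)
            if kind == "original":
                return pt.u1 - pt.u2
            return gap_term_modified(pt.u2, pt.u1, pt.u1, e_total)

        phase, _err = quad(delta12_at, 0.0, n * dt, limit=400)
        # rho12(t) = rho12(0) exp(-i integral Delta12 dt)
        expect = 0.5 * np.exp(-1j * phase)
        phase_error = np.angle(rho[0, 1] * np.conj(expect))
        assert abs(phase_error) < 1e-6
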