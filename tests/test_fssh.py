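import math

import numpy as np
import pytest

from cohsh.adiabatic import AdiabaticPoint, adiabatize
from cohsh.electronic import ElectronicState, PhaseScheme, rhs
from cohsh.fssh import (TrajectoryState, attempt_hop, hop_probability,
                        run_trajectory, transition_probability)


def _state(rho, active=1, x=0.0, p=10.0, e_total=0.05, mass=2000.0):
    return TrajectoryState(x, p, 0.0, active, ElectronicState(rho),
                           e_total, mass)


def _point(u1=0.0, u2=0.02, d12=0.5):
    return AdiabaticPoint(0.0, u1, u2, 0.0, 0.0, 0.0, d12)


class TestHopProbability:
    def test_no_coherence_no_hop(self):
        rho = np.diag([0.6, 0.4]).astype(complex)
        assert hop_probability(_state(rho), _point(), dt=1.0) == 0.0

    def test_no_coupling_no_hop(self):
        rho = np.array([[0.6, 0.2], [0.2, 0.4]], dtype=complex)
        assert hop_probability(_state(rho), _point(d12=0.0), dt=1.0) == 0.0

    def test_starved_population_returns_zero(self):
        rho = np.array([[0.0, 0.0], [0.0, 1.0]], dtype=complex)
        assert hop_probability(_state(rho, active=1), _point(), dt=1.0) == 0.0

    def test_matches_population_flux(self):
        """g * rho_aa equals the Eq.-of-motion population flow out of the
        active state for one step."""
        rho = np.array([[0.7, 0.1 + 0.05j], [0.1 - 0.05j, 0.3]])
        st = _state(rho, active=1)
        pt = _point()
        g = hop_probability(st, pt, dt=1.0)
        drho = rhs(rho, pt, st.p / st.mass, PhaseScheme("original"))
        assert g * rho[0, 0].real == pytest.approx(-drho[0, 0].real,
                                                   rel=1e-12)

    def test_clipped_to_unit_interval(self):
        rho = np.array([[1e-6, 1e-3], [1e-3, 1.0 - 1e-6]], dtype=complex)
        g = hop_probability(_state(rho, active=1), _point(d12=50.0), dt=10.0)
        assert g == 1.0


class TestAttemptHop:
    def test_zero_probability_keeps_state(self):
        rho = np.diag([1.0, 0.0]).astype(complex)
        st = _state(rho)
        new, hopped, frustrated = attempt_hop(st, _point(), 0.0, dt=1.0)
        assert new is st and not hopped and not frustrated

    def test_accepted_hop_conserves_energy(self):
        # 1 -> 2 hop with gap 0.02: kinetic energy drops by exactly 0.02
        rho = np.array([[0.5, 0.4], [0.4, 0.5]], dtype=complex)
        st = _state(rho, active=1, p=math.sqrt(2 * 2000 * 0.05),
                    e_total=0.05)
        pt = _point(u1=0.0, u2=0.02)
        new, hopped, frustrated = attempt_hop(st, pt, 0.0, g=1.0)
        assert hopped and not frustrated
        assert new.active == 2
        ke_new = new.p ** 2 / (2 * new.mass)
        assert ke_new == pytest.approx(0.05 - 0.02, rel=1e-12)
        assert np.sign(new.p) == np.sign(st.p)

    def test_forbidden_hop_is_frustrated(self):
        rho = np.array([[0.5, 0.4], [0.4, 0.5]], dtype=complex)
        st = _state(rho, active=1, p=math.sqrt(2 * 2000 * 0.01),
                    e_total=0.01)
        pt = _point(u1=0.0, u2=0.02)  # upper surface unreachable
        new, hopped, frustrated = attempt_hop(st, pt, 0.0, g=1.0)
        assert frustrated and not hopped
        assert new.active == 1 and new.p == st.p


class TestRunTrajectory:
    def test_coupling_free_model_transmits_unchanged(self, model3):
        bare = model3.with_coupling_off()
        res = run_trajectory(bare, 0.05, "original", seed=1)
        assert res.exit_side == "right"
        assert res.state.active == 1
        assert res.state.electronic.rho[1, 1].real == 0.0
        assert res.frustrated_hops == 0

    def test_closed_entrance_channel_rejected(self, model3):
        with pytest.raises(ValueError):
            run_trajectory(model3, -0.02, "original", seed=1)

    @pytest.mark.parametrize("scheme", ["original", "modified"])
    def test_degenerate_crossing_stays_stable(self, model4, scheme):
        """Model 4's touching surfaces must not destabilize the integrator."""
        res = run_trajectory(model4, 0.03, scheme, seed=5)
        rho = res.state.electronic.rho
        assert res.exit_side in ("left", "right")
        assert np.all(np.isfinite(rho))
        assert np.trace(rho).real == pytest.approx(1.0, abs=1e-8)
        assert -1e-8 <= rho[1, 1].real <= 1 + 1e-8

    @pytest.mark.parametrize("scheme", ["original", "modified"])
    def test_energy_conserved_between_hops(self, model2, scheme):
        res = run_trajectory(model2, 0.08, scheme, seed=9)
        assert res.energy_drift <= 1e-7

    def test_kernel_and_python_engines_agree(self, model3):
        kw = dict(n_traj=60, seed=314)
        res_k = transition_probability(model3, 0.04, "modified",
                                       engine="kernel", **kw)
        res_p = transition_probability(model3, 0.04, "modified",
                                       engine="python", **kw)
        assert res_k.p_transition_counts == res_p.p_transition_counts
        assert res_k.p_transition_wavefn == pytest.approx(
            res_p.p_transition_wavefn, abs=1e-8)
        assert res_k.n_frustrated == res_p.n_frustrated


class TestEnsemble:
    def test_coupling_free_probability_zero(self, model2):
        bare = model2.with_coupling_off()
        res = transition_probability(bare, 0.06, "original", 20, seed=0)
        assert res.p_transition_counts == 0.0
        assert res.p_transition_wavefn == 0.0

    def test_probabilities_within_bounds_and_stderr(self, model3):
        res = transition_probability(model3, 0.05, "modified", 400, seed=2)
        assert 0.0 <= res.p_transition_counts <= 1.0
        assert 0.0 <= res.p_transition_wavefn <= 1.0
        p = res.p_transition_counts
        assert res.stderr == pytest.approx(math.sqrt(p * (1 - p) / 400))

    def test_independent_seeds_statistically_consistent(self, model3):
        a = transition_probability(model3, 0.05, "original", 500, seed=100)
        b = transition_probability(model3, 0.05, "original", 500, seed=7777)
        sigma = math.hypot(a.stderr, b.stderr)
        assert abs(a.p_transition_counts - b.p_transition_counts) \
            <= 4 * max(sigma, 1e-3)

    def test_same_seed_reproducible(self, model3):
        a = transition_probability(model3, 0.05, "modified", 300, seed=42)
        b = transition_probability(model3, 0.05, "modified", 300, seed=42)
        assert a.p_transition_counts == b.p_transition_counts
        assert a.p_transition_wavefn == b.p_transition_wavefn

    def test_invalid_trajectory_count(self, model3):
        with pytest.raises(ValueError):
            transition_probability(model3, 0.05, "modified", 0, seed=1)


def test_net_hop_flux_matches_population_transfer(model3):
    """Accumulated fewest-switches flux (forward minus backward) along a
    deterministic lower-surface passage equals the net population
    transferred by the electronic equations on the same path to ~2%.

    The passage through the coupling region is oscillatory, so only the
    *net* flux is comparable: the clipped one-way sum counts gross
    back-and-forth exchange.
    """
    e_total = 0.05
    mass = model3.mass
    dt = 1.0
    scheme = PhaseScheme("original")
    x = -model3.x_span
    p = math.sqrt(2 * mass * (e_total - adiabatize(model3, x).u1))
    rho = ElectronicState.pure(1).rho
    net = 0.0

    def deriv(x, p, rho):
        pt = adiabatize(model3, x)
        return p / mass, -pt.du1, rhs(rho, pt, p / mass, scheme)

    for _ in range(6000):
        pt = adiabatize(model3, x)
        up = _state(rho, active=1, x=x, p=p, e_total=e_total, mass=mass)
        down = _state(rho, active=2, x=x, p=p, e_total=e_total, mass=mass)
        net += (hop_probability(up, pt, dt) * rho[0, 0].real
                - hop_probability(down, pt, dt) * rho[1, 1].real)
        k1 = deriv(x, p, rho)
        k2 = deriv(x + 0.5 * dt * k1[0], p + 0.5 * dt * k1[1],
                   rho + 0.5 * dt * k1[2])
        k3 = deriv(x + 0.5 * dt * k2[0], p + 0.5 * dt * k2[1],
                   rho + 0.5 * dt * k2[2])
        k4 = deriv(x + dt * k3[0], p + dt * k3[1], rho + dt * k3[2])
        x += dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        p += dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        rho = rho + dt / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        if x > model3.x_span:
            break
    assert net == pytest.approx(rho[1, 1].real, rel=0.02)
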