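# Methods

Atomic units throughout: ħ = 1, energies in Hartree, lengths in Bohr,
reduced mass μ = 2000 au unless a model overrides it.

## Models

Each benchmark model is a real symmetric 2×2 diabatic matrix V(x):

| model  | V11 | V22 | V12 | defaults |
|--------|-----|-----|-----|----------|
| 1 (dual non-crossing) | 0 | A | B[e^{−C(x−x0)²}+e^{−C(x+x0)²}] | A=B=0.025, x0=3, C=0.7 |
| 2 (dual avoided crossing) | 0 | −A e^{−Bx²}+E0 | C e^{−Dx²} | A=0.1, B=0.28, E0=0.03, C=0.01, D=0.06 |
| 3 (simple avoided crossing) | sign(x)·A(1−e^{−B\|x\|}) | −V11 | C e^{−Dx²} | A=C=0.01, B=1.6, D=1 |
| 4 (Renner–Teller) | as model 3, A=0.005 | −V11 | C x² e^{−Dx²} | C=0.01, B=1.6, D=1 |

Model 1's vertical gauge (V11=0, V22=A) is a choice; dynamics depend only
on the gap.  Model 2's diabats cross at ±2.0736 Bohr; the adiabatic gap of
Model 1 peaks at ±x0.  Model 4's surfaces are exactly degenerate at x=0,
where the coupling vanishes quadratically.

The interaction half-width `x_span` is the point beyond which |V12| <
1e−10 Hartree: 10 Bohr for models 1, 3, 4 but **18 Bohr for model 2**,
whose slowly decaying coupling (D = 0.06 Bohr⁻²) is still 2.5e−5 Hartree
at |x| = 10.  Trajectories start and scattering boundaries sit at ±x_span.

Adiabatic quantities come from the analytic 2×2 eigendecomposition; the
scalar coupling is d12 = (V12′Δ − V12 Δ′)/(Δ² + 4V12²) with Δ = V11−V22,
which equals dθ/dx for the mixing angle θ = ½ atan2(2V12, Δ).  At an
exact degeneracy with zero coupling (model 4, x = 0) d12 is a 0/0 limit;
it is regularized by averaging the analytic value 1e−6 Bohr to either
side (the limit C/(2AB) is finite) and flagging the point.  This is a
package decision — the degenerate case is precisely where all trajectory
schemes here are expected to fail, and the exact solver works in the
diabatic representation and never touches d12.

## Electronic propagation

The density matrix is propagated in the adiabatic representation.  The
original diagonal term for the (k,j) coherence is U_k − U_j; the modified
term is

    D_kj = 2 √(E − U_ref) (√(E − U_j) − √(E − U_k)),

the classical velocity on the reference surface times the local JWKB
wavenumber difference.  U_ref is the active surface (FSSH) or the
population-averaged potential (Ehrenfest).  Properties relied on by the
tests: D_kj → U_k − U_j monotonically from above as E grows, with
relative deviation ≤ (U_k−U_j)/(2(E−U_ref)) once E−U_ref ≥ 10(U_k−U_j);
D is real and antisymmetric in (k,j), so norm conservation is untouched.

Degenerate/forbidden branches: √(E−U) factors with U > E are clamped to
zero (keeps D real; the coherence against a classically inaccessible
state stops accumulating phase), and E = U_ref (a turning point) gives
D = 0 rather than an error; only E < U_ref is treated as a precondition
violation.

Nuclei and electrons are integrated *jointly* by classical RK4 with
re-evaluation of all adiabatic quantities at the stage positions (the
potentials are analytic; no interpolation).  The shared default time step
is dt = 1.0 au, validated by step-halving: halving dt moves transition
probabilities by < 1e−3 on the benchmark scans (a convergence test pins
this), and the observed order of the electronic propagator is ≥ 3.8.

## Surface hopping

Standard fewest switches with one uniform draw per step, attempted before
the nuclear step: g = max(0, 2 dt ẋ d12 Re ρ_other,active / ρ_aa),
clipped to [0,1].  Accepted hops rescale |p| along x (the only direction
in 1D) to conserve E exactly; hops with E below the target surface are
frustrated — the trajectory keeps its surface and momentum (no velocity
reversal; counted and reported).  Trajectories start at x = −x_span on
the lower surface with ρ = |1⟩⟨1| and p = +√(2μ(E−U1)), and end when they
leave [−x_span, x_span] moving outward, or after a step budget of six
box-crossings at the slowest open-channel speed (truncations are flagged;
the budget is generous because a hopped trajectory can crawl on the upper
surface far slower than it entered).

Two ensemble estimators are reported: the transmitted-on-the-upper-
surface fraction (counts) and the mean final ρ22 over transmitted
trajectories (wavefunction).  They agree within statistics; the
wavefunction estimator is smooth in E and is therefore used for the
oscillation (extrema) diagnostics, where the count estimator's shot noise
and its exact-zero plateaus at P ≈ 0 defeat a raw three-point test.

Hop randomness comes from a counter-based splitmix64 hash of
(seed, trajectory, step), so ensembles are reproducible, order-
independent, and identical between the pure-Python reference engine and
the compiled numba kernels (a test pins the two engines against each
other trajectory-for-trajectory).

## Ehrenfest dynamics

One deterministic trajectory per energy on the mean-field potential
U_avg = ρ11 U1 + ρ22 U2, with force

    F = −ρ11 U1′ − ρ22 U2′ − 2 Re ρ12 d12 (U2 − U1).

The sign of the coherence term is fixed by the Hellmann–Feynman
off-diagonal element and verified by the conservation of
p²/2μ + Tr(ρH_el), which holds to ~1e−13 Hartree per trajectory in the
tests (contract: ≤ 1e−7).  The modified scheme changes only the
electronic diagonal term (U_ref = U_avg, and E − U_avg is exactly the
kinetic energy, so the JWKB factors never go complex); the nuclear force
is unchanged.  Trajectories that reflect or trap on the mean-field
surface are flagged rather than silently counted, since the observable is
defined for transmission.

## Exact reference

The time-independent two-channel equation −ψ″/2μ + V(x)ψ = Eψ is solved
in the diabatic representation (everywhere smooth; model 4's d12
singularity never enters) on [−x_span, x_span].  The fourth-order Numerov
stencil is assembled into one banded linear system with radiation
boundary conditions built from the stencil's own discrete dispersion
relation cos(k̃h) = (1 − 5h²k²/12)/(1 + h²k²/12) (decaying exponentials
for closed channels), and solved by a banded LU per energy.  The default
step h = x_span/20000 leaves the observable grid-converged to ~1e−11 and
a unitarity defect (summed outgoing flux vs 1, with physical k flux
factors) of ~1e−9 across all scans; probabilities are independent of
x_span once couplings have decayed (ΔP < 1e−6 for span 10→14 on the test
cases).  Asymptotic channel energies are taken per side, because models 3
and 4 have antisymmetric diabats whose adiabatic order swaps across the
crossing.  Below the upper asymptote the lower→upper observable is
undefined and scans mark the point (NaN) while still solving with
closed-channel asymptotics.  The test suite cross-checks this solver at
ten spot energies against an independent adaptive-RK transfer-matrix
integration (agreement ~1e−8, asserted at 1e−6).

## Energy scans and comparison metrics

The quoted per-model scan windows span the oscillatory regime of P(E)
from just above the upper asymptote: model 1 [0.028, 0.22], model 2
[0.035, 0.35], model 3 [0.012, 0.07], model 4 [0.007, 0.05] Hartree
(40-point grids by default; configurable).  FSSH scans derive a
decorrelated stream per energy from the base seed.  Comparison reports
contain RMS and max deviation from the exact curve (count-based column),
local extrema from a three-point test, and an extremum-matching
diagnostic (each exact extremum matched to a same-kind method extremum
within one grid spacing).

At the default comparison scale (1000 trajectories per energy) the
binomial noise floor is ~0.5–1.5% of probability; the modified-scheme
FSSH/Ehrenfest curves sit at or below that floor relative to exact
(count RMS ~0.01/~0.0005), while the original-scheme curves miss by
~0.06–0.24 RMS on models 1–2 and misplace the oscillations on model 3.
No ordering is asserted for model 4: with exactly degenerate surfaces
both schemes fail by construction, and the package only verifies that the
trajectory integrators stay stable and the exact solver remains unitary
there.

## Scope and limitations

* Two electronic states, one nuclear dimension, real symmetric diabatic
  couplings; no Wigner sampling of initial conditions (the benchmark
  observable is defined for a fixed incoming energy).
* The synthetic benchmark potentials exercise non-crossing, avoided-
  crossing and degenerate-crossing topologies, but not multidimensional
  coupling-vector directionality, conical-intersection geometric phase,
  or thermal/detailed-balance behaviour — conclusions from these tests
  transfer to real molecules only at the level of the electronic-phase
  mechanism.
* The high-energy agreement between original and modified schemes is
  pointwise O(δ/2(E−U)) in the gap term but only O(E^{−3/2})·(path
  length) in the accumulated phase, so "high energy" for final
  populations means E of order hundreds of times the asymptotic gap; the
  equivalence test uses E up to 12 Hartree on the shrunk-gap model.
* Frustrated-hop treatment (no velocity reversal) and the time step are
  exposed in the API; alternative conventions change FSSH results at low
  energy.
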