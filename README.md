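# cohsh — coherence-corrected trajectory-based nonadiabatic dynamics

Mixed quantum–classical trajectory methods — Tully's fewest-switches
surface hopping (FSSH) and the semiclassical Ehrenfest mean-field method —
propagate the electronic density matrix ρ along a classical nuclear path
with the coupled equations (ħ = 1)

    i dρ_kj/dt = (U_k − U_j) ρ_kj − i Σ_l [ ẋ d_kl ρ_lj − ρ_kl ẋ d_lj ],

where U_j(x) are adiabatic potential surfaces and d_kl(x) the scalar
nonadiabatic couplings.  Both methods are *overcoherent*: after a
trajectory leaves a coupling region, ρ_12 keeps beating with the bare-gap
phase exp(−i∫(U_2−U_1)dt), which is not the phase the two branches of an
actual scattering wavefunction accumulate.  The resulting interference
(Stückelberg) oscillations of the transition probability come out wrong.

`cohsh` implements the simple cure studied here: replace the diagonal
phase term by the JWKB wavenumber-difference form

    D_kj = 2 √(E − U) ( √(E − U_j) − √(E − U_k) ),

i.e. (classical velocity on the reference surface U) × ħ(k_j − k_k) with
k_j the local JWKB wavenumber.  U is the active surface for FSSH and the
population-averaged potential U = Σ_j ρ_jj U_j for Ehrenfest.  D_kj → U_k
− U_j in the high-energy limit E − U ≫ |U_k − U_j|, so nothing else in
either algorithm changes.  The package is aimed at method developers and
students of nonadiabatic dynamics who want a compact, fully testable 1D
laboratory for decoherence corrections.

## What is in the box

* **Four benchmark diabatic two-state models** (atomic units, reduced mass
  2000 au): dual Rosen–Zener–Demkov non-crossing, dual
  Landau–Zener–Stückelberg avoided crossings (diabats cross at ±2.07
  Bohr), a simple avoided crossing, and a Renner–Teller model whose
  coupling vanishes as x² at an exact surface degeneracy.  A generic
  `DiabaticModel` accepts custom callables or tabulated grids.
* **FSSH** and **Ehrenfest** drivers with either the original or the
  JWKB-modified electronic equations (joint RK4, exact energy-conserving
  hops, frustrated hops kept without velocity reversal), with compiled
  (numba) ensemble kernels and counter-based reproducible hop streams.
* **An exact quantum reference**: time-independent two-channel
  close-coupling scattering solved with a Numerov boundary-value scheme
  (unitarity defect ~1e−9), giving the overall transition probability
  lower surface (x→−∞) → upper surface (x→+∞).
* **Experiment orchestration**: energy scans, RMS/extrema comparison
  reports, and two-panel figure-style plots, plus a `cohsh` CLI.

## Worked example

```python
import cohsh

model = cohsh.get_model("model2")        # dual avoided crossings
E = 0.1                                   # total energy, Hartree

exact = cohsh.solve_close_coupling(model, E)
print(f"exact      P = {exact.p_lower_to_upper:.4f}")

for scheme in ("original", "modified"):
    mf = cohsh.run_mean_field(model, E, scheme)
    hop = cohsh.transition_probability(model, E, scheme,
                                       n_traj=2000, seed=11)
    print(f"{scheme:9s}  Ehrenfest P = {mf.p_transition:.4f}   "
          f"FSSH P = {hop.p_transition_counts:.4f} "
          f"± {hop.stderr:.4f}")
```

prints

```
exact      P = 0.1279
original   Ehrenfest P = 0.3576   FSSH P = 0.5900 ± 0.0110
modified   Ehrenfest P = 0.1284   FSSH P = 0.1245 ± 0.0074
```

The original equations overshoot the transition probability by factors of
3–5 at this energy (each method differently); with the modified diagonal
term both trajectory methods land on the exact result within statistics.
The full figure-style comparison for any model is one command:

```
cohsh figure --model model2 --ntraj 1000 --out model2.png
```

## Layout

```
src/cohsh/models.py      benchmark + custom diabatic models
src/cohsh/adiabatic.py   diabatic→adiabatic transform, crossings, d12
src/cohsh/electronic.py  density-matrix propagation, gap terms, RK4
src/cohsh/fssh.py        surface hopping (reference engine + ensembles)
src/cohsh/ehrenfest.py   mean-field dynamics
src/cohsh/exact.py       close-coupling scattering reference
src/cohsh/experiments.py scans, comparison metrics, figures
src/cohsh/cli.py         command-line interface
docs/methods.md          models, algorithms, numerical choices
```
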