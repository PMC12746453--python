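# Methods

This note records the models, algorithms, numerical choices and known
limitations of `eoexcite`, in the order the pipeline runs them.

## The NaI model

The bundled molecular model is the classic two-state diabatic Hamiltonian
of NaI in the Faist–Levine form: an ionic diabat

V₁(R) = (A₂ + (B₂/R)⁸)·e^(−R/ρ) − e²/R − e²(λ₊+λ₋)/2R⁴ − C₂/R⁶ − 2e²λ₊λ₋/R⁷ + ΔE₀

(Born–Mayer repulsion, Coulomb attraction, induction/dispersion terms,
offset by IP(Na) − EA(I) = 2.075 eV), a repulsive covalent diabat
V₂(R) = A₁·e^(−β₁(R−R₀)), and a Gaussian coupling
V₁₂(R) = A₁₂·e^(−β₁₂(R−Rₓ)²) localized at the crossing (Rₓ = 6.93 Å,
2|V₁₂| ≈ 0.11 eV).  The parameters ship as a documented YAML-able set
(`models.NAI_DEFAULT_PARAMS`, standard literature values); the model object
is data-driven so an alternative parameterization can be dropped in without
code changes.  With these values the lower adiabat has its minimum at
R ≈ 5.06 bohr with a vertical gap of ≈3.87 eV, and the first absorption band
peaks near 3.9 eV — bracketing the three study carrier energies (3.68, 3.89,
4.15 eV).

The diabatic transition dipole is a constant, μ₁₂ = 0.05 au by default.
Its magnitude is not critical: every selection probability in the package
is normalized to an ensemble maximum, so a global rescaling of μ cancels
(this is asserted by tests).  The default is chosen so that the study field
strength E₀ = 0.001 au transfers ≲10⁻³ of the population — comfortably
inside the weak-field regime the scheme assumes; permanent dipoles are off
by default (the dynamic Stark effect is negligible at these intensities)
but the ionic charge-separation dipole −R can be switched on.

The adiabatic transform fixes eigenvector signs by making the
largest-magnitude component positive (ties resolved toward the first
diabat), which makes overlaps between consecutive geometries reproducible.

## Pulses

Pulses are Gaussian-envelope carriers
E(t) = E₀·e^(−4ln2·(t−t_c)²/FWHM²)·cos(ω₀(t−t_c)+θ)·**e**, with FWHM the
*field-envelope* width.  User-facing durations are intensity FWHMs
(FWHM_field = √2·FWHM_int); the τ of the e^(−t²/2τ²) convention used by the
analytic two-level model is FWHM_int/(2√ln2), and all three conventions are
exposed on the pulse object so no call site converts by hand.  Sampling
aligns t_c on the grid and, on request, makes the pre-center step count a
multiple of the storage stride so that stride-decimated times stay on the
nuclear-step grid.  The envelope cutoff for "field effectively zero" is
10⁻⁸·E₀.  Spectra are zero-padded FFTs; the spectral FWHM is read off by
linear interpolation of the half-maximum crossings, and a zero-frequency
fraction above 10⁻⁴ of the peak is flagged (fields built from Eq.-style
carrier×envelope forms with ≥10 cycles are clean; tabulated fields from
other sources may not be).

## Grid quantum dynamics (the reference)

Second-order split-operator propagation of the two-component wavepacket on
a uniform grid (defaults 1024 points on 3–40 bohr, 0.1 fs step): kinetic
half-steps spectrally, potential steps pointwise in the diabatic
representation with the dipole–field term −μ(R)·(ê·E(t)) evaluated at each
half-step's midpoint (the pointwise 2×2 exponentials are closed-form Pauli
rotations, no per-point diagonalization).  No absorbing boundary is used;
density above 10⁻⁶ in the outermost cells triggers a warning instead, which
is appropriate for the ≤1 ps horizons used here.  The vibrational ground
state comes from imaginary-time relaxation of the same Hamiltonian with the
step annealed (10 → 2.5 au) to remove the Trotter bias from the converged
state; convergence is an energy change below 10⁻¹² hartree per step.
Halving the step and quadrupling the grid moves ⟨R⟩_S1 and ⟨ΔR⟩_S1 by
≲0.002 Å over 500 fs, well under the 0.01 Å convergence budget.
S1-projected observables rotate the amplitudes pointwise to the adiabatic
basis; times with zero projected norm are flagged invalid rather than
silently averaged.

## Wigner sampling

The ground state is Wigner-transformed numerically,
W(R,P) = π⁻¹∫dy ψ*(R+y)ψ(R−y)e^(2iPy), on the support subgrid; the
momentum grid is chosen so the discrete marginals are *exactly* the
position/momentum densities.  Tiny negative cells (absent for the
near-Gaussian ground state, logged when clipped) are zeroed; samples are
drawn cell-categorically with uniform in-cell jitter and stored as
(R, v = P/m) pairs.  The jitter adds ≤1% to the variance at the default
grid — below Monte-Carlo noise at n = 10⁴.  The sampler is seeded and
reproducible; 10,000 samples is the study ensemble size.

## Electron-only dynamics

Per initial condition the electronic coefficients are advanced by
short-time exponentials of H(t) = diag(E) + H_coupling − μ·E(t), with the
field taken at the step midpoint (0.0625 fs step; every 8th step stored,
so stored times — and hence start times — sit on the 0.5 fs nuclear grid).
The general N-state path exponentiates per step; the two-state ensemble
driver uses the closed-form Pauli rotation vectorized over all 10⁴ traces
(seconds per pulse).  Static dipoles and excited–excited transition dipoles
are excludable by flags.  Orientational averaging (random molecular axes,
uniform on the sphere) is available but off by default, matching the
axis-aligned study setup.  Against the analytic weak-field two-level
solution the propagator agrees to ≲0.2% at the study step size.

## Renormalized selection

P_tot,k accumulates the per-step leave probability
max(0, 1 − |c_β(t+Δt)|²/|c_β(t)|²); its ensemble maximum P_max rescales all
excited populations (and the ground population via
(|c_β|² − (1−P_max))/P_max, the closed form being exact to machine
precision for the difference-scaling identity).  Hopping on the
renormalized populations uses the global-flux prescription; for an active
excited state the 1/P_max factors cancel and the plain formula re-emerges.
The stochastic sweep draws one uniform number in (0, 1] per stored step per
trace from a generator keyed by (seed, k) — each initial condition owns an
independent, reproducible stream, and a draw happens even at all-zero
probability steps so the stream does not shift when populations change.
Multiple hops are allowed; the *last* hop fixes (α_k(0), t′_k), a last hop
back to β rejects the trace (this is what removes transiently populated
off-resonance states), and three-plus-hop traces are counted and warned
about above 1%.  Hop times are assigned to the later of the two stored
steps of the deciding interval, relative to the pulse center.

The "vertical" comparison scheme selects states inside an energy window
with probability f_osc/ΔE² (constant-intensity assumption; f_osc/ΔE
available) normalized to the global in-window maximum, all at t′ = 0.

## Surface hopping

Nuclei: velocity Verlet on the active adiabatic surface (0.5 fs step,
forces from central differences of the adiabatic energies, h = 10⁻³ bohr);
total energy drifts <10⁻⁵ hartree over 2000 fs.  Electrons: the analytic
models provide an exact global diabatic basis, so "local diabatization"
takes its cleanest form — the coefficients are propagated in the diabatic
frame (25 substeps of 0.02 fs per nuclear step, linear interpolation of R,
closed-form exponentials) and rotated to the adiabatic frame at the step
boundaries; the result is manifestly independent of adiabatic sign
conventions.  Hopping uses the global-flux probabilities from the adiabatic
populations at consecutive nuclear steps — the one printed prescription in
scope — rather than the propagator-internal probabilities the original
driver uses; the package treats this as its single hopping formula
everywhere.  Accepted hops rescale the (1D) velocity along itself to
conserve total energy; frustrated hops change nothing (no velocity
reversal, logged per trajectory).  The energy-based decoherence correction
(τ_α = (1 + C/E_kin)/|E_α−E_active|, C = 0.1 hartree) damps inactive
amplitudes each nuclear step *after* the hop decision by default; the order
is switchable since the bookkeeping convention is not uniquely fixed.
Trajectories leaving the model domain (dissociation) terminate with a
status and are excluded from later averages.  Per-trajectory randomness is
keyed by (seed, geometry id), so a trajectory is bitwise reproducible
regardless of the sub-ensemble it runs in.

Time-shifted analysis adds t′_k to each trajectory's clock (start times are
multiples of the recording step by construction) and reports ⟨R⟩, ⟨ΔR⟩ over
alive trajectories in the upper state plus the upper-state fraction.

## The analytic two-level oracle

First-order perturbation theory + rotating-wave approximation for the
Gaussian pulse gives c_α(t) ∝ e^(−τ²Ω²/2)(1 + erf(t/√2τ − iτΩ/√2)).  All
complex error functions are evaluated through the Faddeeva function with
the lower-half-plane reflection applied analytically, so the evaluation is
overflow-free for arbitrary τ|Ω| and t.  The excitation *rate* is
implemented as the exact time derivative of |c_α|² (which carries the
conjugate carrier phase relative to a naive transcription); it is even in
the detuning and integrates to |c_α(∞)|² pointwise-consistently, which the
tests assert.  Its clamped-positive mass in reduced coordinates (t/τ, τΩ)
defines the teardrop-shaped region used to validate the selection scatter:
≥95% of accepted (detuning, start-time) pairs must fall inside the 99%
region.

## Synthetic data and what the tests do not show

All study inputs are model-generated: the NaI model, harmonic fixtures with
closed-form ground states (the oracle for relaxation, Wigner widths and
uncoupled dynamics), and seeded Wigner ensembles.  The generator therefore
emulates a cold (0 K), one-dimensional, two-state molecule with a constant
diabatic transition dipole and an analytically known Hamiltonian.  Passing
tests consequently say nothing about: ab initio electronic structure noise,
polyatomic (multi-mode) vibronic coupling, geometry-dependent transition
dipoles, finite temperature, or pulses beyond the electric-dipole /
plane-wave description (magnetic and quadrupole couplings are out of
scope).  The frozen-nuclei assumption itself is probed only indirectly —
through the degradation of the 500 fs-pulse ensembles relative to the
quantum reference.

## Problem sizes used in validation

The shipped validation runs are desk-scale by design: 10⁴ electron-only
traces per pulse, surface-hopping swarms capped at 250 trajectories and
700 fs for the width comparisons (the first excited-state oscillation,
where the schemes differ most), 500 fs horizons for the grid-convergence
check, and five seed replicates for the window-count statistics.  These
sizes put all stochastic checks well inside their binomial/Monte-Carlo
tolerances.

## Known limitations

- Two-state bundled models only (the propagators are N-state; the
  selection machinery is N-state).
- The hopping-probability formula in the TSH driver is global-flux
  throughout; no fewest-switches-coefficient variant is provided.
- No chirped pulses, no vector-potential-derived fields (the
  zero-frequency diagnostic covers the associated risk for tabulated
  fields), no finite-temperature Wigner sampling.
- The sudden-scheme counts depend on the exact NaI parameterization; the
  shipped literature defaults reproduce window-count ratios to ~2% but
  absolute counts only to ~10%.
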