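# Methods

## Vibrational model

A single localized vibrational coordinate `Q` (here the terminal-alkyne
C≡C stretch) is treated on a uniform grid of `P` points spaced by `ΔQ`.
The Hamiltonian in the grid-point basis is `H_ij = T_ij + V(Q_i) δ_ij`
with the sinc-function DVR kinetic matrix

    T_ij = ħ² / (2 m ΔQ²) · (−1)^(i−j) · { π²/3        i = j
                                          { 2/(i−j)²    i ≠ j.

This closed form is the infinite-range Colbert–Miller result for a uniform
grid; it is adopted because it is the canonical sinc-basis kinetic
operator. Diagonalization gives all `P` states; the fundamental is
`scaling · (E₁ − E₀)`, where the multiplicative scaling factor absorbs the
systematic error of the electronic-structure method that produced the
potential (0.989 for TPSS-D3, 0.966 for B3LYP-D3, 0.931 for PBEh-3c; 1.0
by default). Because the factor is multiplicative, applying it before or
after any frequency subtraction is equivalent.

Assumptions: the coordinate is one-dimensional (no mode–mode or
rotational coupling), the reduced mass is an external input from the
localized-mode construction, and the potential is supplied as a tabulated
curve — no electronic structure is computed here.

**Grid defaults.** `P = 20` throughout. The grid span is the caller's
choice; the synthetic oscillator fixtures use 1.6× the classical turning
point of the `n = 3` harmonic state (≈ ±0.22 Å for 2130 cm⁻¹ at 6 amu),
a rule that keeps the two lowest states fully resolved (harmonic and Morse
fundamentals reproduce their closed forms to ~10⁻⁷ relative) while the
spacing stays fine enough for the sinc basis. Internally everything is in
atomic units; the API speaks Å, amu and cm⁻¹, with every conversion
constant centralized in `specmap.units`.

## Frequency decomposition

Given component curves `ΔE_n(Q)` from an energy-decomposition analysis
(electrostatics, Pauli repulsion, dispersion, polarization, charge
transfer — names are free strings, and grouped removal such as the frozen
term ELEC+PAULI+DISP is supported), the shift attributed to component *m*
is `Δω_m = ω_FULL − ω_{m-REM}`, where `ω_{m-REM}` solves the Hamiltonian
with that curve deleted. Two properties are deliberate: `Δω_m` is
invariant to adding a constant to a component (only shape along `Q`
matters, and for quadratic components only curvature), and one-at-a-time
shifts need not sum to `ω_FULL − ω_ISO` — removal is non-additive, which
is physical, not an implementation artifact.

## Map features and sign conventions

The electric field of the solvent at the terminal hydrogen uses
damped-shifted-force electrostatics: the pair kernel
`f(r) = erfc(αr)/r² + 2α e^(−α²r²)/(√π r)` minus its value at the cutoff,
so every pair field goes continuously to zero at `r_c` without lattice
sums. Defaults: `r_c = 14 Å` (the simulation cutoff) and `α = 0.2 Å⁻¹`,
a standard DSF damping; both are configurable, and a damped-shifted-
*potential* variant (no kernel shift) is available behind a flag since
published descriptions often leave the variant unstated.

Derivatives with respect to the C–H bond length use three-point centered
differences with 0.1 Å spacing, the field being fully re-summed at each
displaced point. The projection axis points **from the hydrogen toward
its carbon**. This choice is pinned by the published coefficient signs:
with it, an electron-rich (negative) site facing the hydrogen gives
negative f0/f1 and, contracted with the published coefficients
(a₀ = −1.51×10², a₁ = +1.96×10³, a₂ = −1.06×10³ in atomic units per
cm⁻¹), a net red shift — reproducing both the sign pattern of the
published per-variable contributions and the central observation that
nitrogen association lowers the frequency. The opposite convention
inverts all three field contributions.

Repulsive Lennard-Jones sums use each solvent atom's own `σ, ε` with no
combining rules and skip donor-flagged (nitrogen) atoms, whose influence
the field variables already carry; the flag generalizes "non-nitrogen" to
arbitrary solvents. The r⁻¹² kernel makes cutoff truncation negligible, so
the LJ sums reuse the electrostatic cutoff. All solute atoms are excluded
from both sums: the map models the solvent-induced shift only.

## Map model and fitting

`ω_MAP = ω_g + Δω(θ_RCC, θ_HCC) + Δω_TEA + Δω_QM1→QM∞`, with
`Δω_TEA` the six-term multilinear form. The model deliberately sets all
other intramolecular contributions (`Δω_R`) to zero; this is the known
cause of under-dispersed predicted linewidths, since classical MD samples
those degrees of freedom more broadly than their quantum ground states
allow. The angle surface is a smooth bivariate spline in the two bend
angles (degrees), anchored to zero at the linear geometry (180°, 180°) and
clamped to its sampled rectangle with a warning outside.

Fitting is ordinary least squares **without an intercept** — the constant
part of the frequency lives in `ω_g` and the QM-region correction, not in
the regression. Two uncertainty estimates are reported side by side:

* `ci_resample`: the 95% t-interval of the mean coefficient over 25 refits
  on random 3/4 subsets of the data. This is the training-set-sensitivity
  recipe under which the packaged coefficients' final digits are quoted.
  Because the subsets overlap heavily, it is *not* an interval for the
  generating coefficient — its half-width is roughly a quarter of the
  coefficient's sampling standard error.
* `ci_ols`: the classical 95% t-interval from the single training-set fit.
  Under i.i.d. Gaussian residuals this is exact, and it is the interval
  whose empirical coverage the test suite verifies (≥ 90% over 200
  Monte-Carlo refits at the reference noise of 2.4 cm⁻¹, n = 1500).

The QM-region convergence law `ω = c − b e^(−N/a)` is fit by nonlinear
least squares; the constant added to single-QM-molecule frequencies is
`c − ω(N=1) = b e^(−1/a)`.

## Solvation structure

Cylindrical coordinates place the origin at the R-group carbon with the z
axis toward the hydrogen-bearing carbon; minimum-image displacements are
taken before projection (orthorhombic boxes). The distribution on a square
`Δr = Δz` grid divides mean bin counts by the *exact* annular volume
`π(2rΔr² + Δr³)` (r the lower bin edge) times the species bulk density, so
`integrate_region` inverts the normalization exactly and full-domain
integration returns the raw mean count. Default bin width 0.25 Å —
published maps of this quantity resolve sub-ångström structure.

Association counts donors inside z ∈ [3, 6] Å, r ∈ [0, 3] Å (the box
bracketing the first nitrogen peak, which starts just beyond the hydrogen
at z ≈ 2.28 Å); a frame with ≥ 1 donor is "nitrogen associated", with 0
"carbon associated" — the rare two-donor frames count as associated. The
count autocorrelation (FFT, unbiased lag normalization) is fit to
`Σ₁³ A_i e^(−t/τ_i)` with non-negative amplitudes by multi-start bounded
least squares; multi-exponential fits are ill-conditioned, so eight
log-spaced starts are tried and the lowest residual wins. The fit window
ends at three times the lag where the ACF first falls below 0.02, and time
constants are capped at twice that window: a time scale longer than the
window is unidentifiable, and without the cap the pure-noise ACF tail can
absorb a spurious slow component that inflates the integral. The
correlation time is the integral of the fit, `Σ A_i τ_i`; `max τ_i` is the
longest persistence time.

## Lineshape

`F(t) = ⟨α₀₁(t₀+t) α₀₁(t₀) e^{i∫δω dτ}⟩ e^(−t/2T₁)` averaged over all
sliding origins with stride one frame; the phase integral is a cumulative
trapezoid of `δω = ω − ⟨ω⟩` (second-order accurate at no cost) in rad/ps.
T₁ = 5 ps by default (experimental estimate of the population lifetime).
The one-sided transform uses the `e^{−iωt}` kernel so that a component
fluctuating at `+δ` appears at `+δ` — the convention is pinned by two
oracles: a constant trajectory must give a Lorentzian of FWHM
`1/(2πcT₁)` ≈ 1.06 cm⁻¹ at its own frequency, and an asymmetric two-state
trajectory must weight its peaks like the state populations (a mirrored
kernel passes the first test and fails the second). Zero padding (default
4×) only refines the frequency grid; the half-cosine apodization flag
(default off) trades truncation ringing for slight broadening. Negative
excursions of the real part are stored as computed and clipped only while
locating half-maximum crossings; the peak is refined by parabolic
interpolation. `max_lag` is capped at a fifth of the trajectory so the
origin average retains statistics; it is the main sensitivity knob and is
always explicit in examples and tests.

The Condon diagnostic reports the Pearson correlation between transition
polarizability and frequency with a bootstrap 95% CI; "Condon valid" means
the CI covers zero.

## Synthetic fixtures: what they emulate, and what they do not

Every generator returns its ground-truth parameters, so tests are
parameter-recovery tests rather than golden files; identical seeds give
identical artifacts.

* Oscillator grids carry analytic fundamentals (harmonic, Morse via
  `ω_e = a√(2D/m)`, `ω_eχ_e = a²/2m`); decomposed fixtures use quadratic
  components with the physical curvature signs (Pauli stiffens, ELEC/CT
  soften) plus random linear parts that must not shift frequencies.
* Solvated frames place the probe's three sites at 0, 1.215 and 2.276 Å
  along the axis. The donor is a four-site amine coarse model: one
  nitrogen-like site with charge −0.63 e flanked by three +0.21 e alkyl
  sites at 1.47 Å, tetrahedrally splayed 70.5° from the lone-pair axis, so
  the cluster is neutral and its dipole faces the probe. Associated frames
  put the nitrogen 2.1 ± 0.25 Å from the hydrogen (inside the association
  region); free frames put the cluster 7–12 Å away. Occupancy follows a
  persistent two-state Markov chain with set stationary probability
  (default 0.6, matching the observed roughly-half association) and
  residence time. A bath of neutral LJ sites gives nonzero repulsive
  features. What this does **not** emulate: real force-field charge
  detail, solvent packing correlations, or conformational flexibility —
  passing tests demonstrate correct bookkeeping and the correct *sign
  structure*, not force-field realism.
* Frequency trajectories use the exact OU one-step update
  `x' = xρ + Δ√(1−ρ²)ξ, ρ = e^(−dt/τc)` (not Euler), so variance and
  correlation time are exact at any step and the Kubo closed form applies
  without discretization bias; the telegraph generator uses the exact
  two-state propagator, giving a single-exponential ACF with known
  integral.

## Problem sizes and numerical tolerances

Test and acceptance runs use desk-scale sizes chosen so each estimate's
sampling error sits well inside the asserted tolerance: 150–200 frames for
ideal-gas CDF checks (far-field g within 3 standard errors of 1),
1200–2000 rows for map fits, 200 Monte-Carlo repetitions for interval
coverage, 2×10⁵-step trajectories for the motional-narrowing limit (the
slowest check, a few seconds), and 10⁵-step telegraph series for
correlation times, where the estimator's intrinsic spread across seeds is
~5–10% and tests therefore average a few seeds. Exactness claims
(brute-force feature agreement at 10⁻¹⁰ relative, exact region-integral
inversion, exact triexponential recovery from noiseless input) are
asserted at machine-precision-adjacent tolerances.

## Known limitations

* Orthorhombic boxes only; minimum-image truncation, no Ewald/PME.
* The map carries no `Δω_R`, so predicted linewidths are systematically
  narrow relative to experiment; this is a property of the model, faithfully
  reproduced.
* Rigid-motion invariance of features holds exactly only when no
  interaction crosses a periodic image (the periodic lattice itself is not
  rotation invariant).
* The triexponential correlation time is reliable only when the series is
  much longer than the slowest real time scale; the windowing described
  above protects against tail noise but cannot create missing information.
* `fit_map` with `train_fraction = 1` reports NaN test statistics rather
  than refusing to fit.
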