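# specmap

Spectroscopic-map modeling for terminal-alkyne vibrational probes.

The terminal alkyne C≡C stretch scatters strongly in the Raman-transparent
window (1800–2600 cm⁻¹) of biomolecules, which makes it an attractive
vibrational probe — provided the environmental factors that move its
frequency are understood quantitatively. In amine solvents such as
triethylamine the probe's Raman band is anomalously broad and asymmetric
because the alkyne hydrogen alternates between facing an electron-rich
nitrogen (red-shifted) and facing alkyl groups (near gas phase). `specmap`
implements the full modeling chain that connects classical MD snapshots of
such systems to their Raman lineshape:

1. **sinc-DVR vibrational solver** (`specmap.dvr`): the 1D grid Hamiltonian
   `H_ij = T_ij + V(Q_i) δ_ij` along a localized vibrational coordinate,
   with the sinc-basis (Colbert–Miller) kinetic matrix
   `T_ij = ħ²/(2mΔQ²)(−1)^(i−j)[π²/3 or 2/(i−j)²]`; the anharmonic
   fundamental is `E₁ − E₀`, and DVR matrix elements
   `⟨Ψ₀|α̂(Q)|Ψ₁⟩` give transition polarizabilities.
2. **Frequency decomposition (ALMO-FDA)** (`specmap.fda`): for a potential
   decomposed by energy-decomposition analysis into
   `V_ISO + ΔE_ELEC + ΔE_PAULI + ΔE_DISP + ΔE_POL + ΔE_CT`, the shift
   attributable to component *m* is `Δω_m = ω_FULL − ω_{m-REM}` obtained by
   deleting that curve and re-solving.
3. **Map features** (`specmap.features`): per snapshot, the damped-shifted-
   force (DSF) electric field of the solvent projected on the C–H bond at
   the terminal hydrogen, its first two bond-length derivatives (3-point
   finite differences, 0.1 Å spacing), and the repulsive Lennard-Jones sums
   `Σ 4ε_m(σ_m/r)¹²` at H, C_H and C_R over non-nitrogen solvent atoms.
4. **The spectroscopic map** (`specmap.mapping`):
   `ω_MAP = ω_g + Δω(θ_RCC, θ_HCC) + Δω_TEA + Δω_QM1→QM∞` with
   `Δω_TEA = Σ_k a_k f_k + Σ_i b_i u_i`, a six-coefficient multilinear
   form. The published coefficients, gas-phase frequencies (2138.39 cm⁻¹
   for propargyl acetate, 2110.65 cm⁻¹ for 4-ethynylbenzyl alcohol) and
   QM-region corrections (3.3 / 4.0 cm⁻¹) ship as packaged data; fitting,
   resampled and classical coefficient intervals, the bivariate-spline
   angle surface and the `ω = c − b·e^(−N/a)` QM-region extrapolation are
   included.
5. **Solvation structure and kinetics** (`specmap.solvation`): cylindrical
   distribution functions `g(r, z) = ⟨N(r,z)⟩ / (π(2rΔr² + Δr³)ρ)` about
   the triple-bond axis, donor counts in the association region
   (z ∈ [3, 6] Å, r ∈ [0, 3] Å), and association correlation times from
   triexponential fits of the count autocorrelation.
6. **Raman lineshapes** (`specmap.raman`): the fluctuating-frequency
   approximation
   `I(ω) ∝ Re ∫₀^∞ dt e^{iωt} ⟨α₀₁(t)α₀₁(0) e^{i∫δω dτ}⟩ e^{−t/2T₁}`
   with T₁ = 5 ps, plus peak/FWHM extraction and a Condon-approximation
   diagnostic.

Synthetic fixtures for every stage — analytic oscillators, decomposed
potentials, solvated frames with a nitrogen-like donor cluster, exactly
discretized Ornstein–Uhlenbeck and telegraph processes — live in
`specmap.synthetic`, so the whole pipeline runs and is tested without any
external data.

## Worked example

`examples/03_map_features_and_eval.py` generates 400 snapshots of a linear
alkyne probe whose amine-like donor alternates in and out of contact,
extracts the six map variables per frame, and evaluates the published map:

```
400 frames, donor occupancy 0.55
solvent shift, associated frames:  -7.00 +/- 2.39 cm^-1
solvent shift, free frames      :  -0.09 +/- 0.33 cm^-1
map frequency means             : 2134.69 (associated) vs 2141.60 (free) cm^-1
```

The nitrogen-associated population sits ≈7 cm⁻¹ below the free population
with little overlap — the two-population structure that makes the
experimental band bimodal. The other examples cover the DVR solver
(`01`, Morse fundamental vs. closed form to 6×10⁻⁸), component shifts
(`02`), solvation structure and kinetics (`04`), and the three lineshape
regimes (`05`: static Lorentzian 1.061 cm⁻¹ vs. the 1/(2πcT₁) = 1.062 cm⁻¹
lifetime limit, slow-modulation Gaussian, motional narrowing).

A thin CLI mirrors the library:

```bash
specmap fixtures --kind morse_pes --out grid.csv
specmap dvr --pes grid.csv --mass 6.0 --scale 0.989
specmap raman --traj freqs.csv --t1 5 --max-lag 10 --out spectrum.csv
```

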