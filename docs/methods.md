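# Methods

Numerical methods, estimator choices, and the known biases of each
pipeline. Units: time in fs (dynamics) or ps (kinetics/TA), energies in
rad/fs internally (ħ = 1) with conversions at the I/O boundary
(`pdpxtal.units`), barriers in kJ/mol with R = 8.31446 J mol⁻¹ K⁻¹.

## Vibronic quantum dynamics (`pdpxtal.quantum`)

**Model.** Two electronic surfaces (S0, S1) sharing one harmonic
vibrational mode; the S1 surface is displaced by a dimensionless
displacement *d* along the mode. Vibronic couplings use analytic
Franck–Condon factors of displaced harmonic oscillators. Pulses are
Gaussian envelopes in the rotating-wave approximation with a carrier
detuning; the pulse *area* (time-integrated Rabi energy) is the
calibrated quantity.

**Propagation.** Liouville–von Neumann equation with Lindblad
dissipators for S1 population decay, vibrational dephasing, and
electronic dephasing, integrated with an adaptive Runge–Kutta scheme
(`scipy.integrate.solve_ivp`, tight tolerances). Invariants verified by
tests: trace conservation, Hermiticity, positivity, a Rabi π-pulse
oracle, and agreement with a time-ordered matrix-exponential reference
on small systems.

**Calibrated study configuration** (`coherent_control_study`). A
120 cm⁻¹ mode with displacement 3.5 (Stokes shift d²ω = 2940 cm⁻¹ well
outside the dephasing linewidth), n_vib = 40, T = 0; 100-fs pump detuned
half the Stokes shift above the vertical transition (12% S1 population),
200-fs dump at 515 nm detuned half the Stokes shift below, area 3π
(depletion optimum). The pump amplitude and dump area are frozen outputs
of the provided calibration routines (`calibrate_pump_population`,
`calibrate_dump_depletion`) so study runs are deterministic and fast.
With these parameters a 350-fs dump roughly doubles the peak S0
vibrational coherence relative to pump-only, while a 2-ps dump (after
vibrational dephasing) gives no amplification and transfers almost no
wave-packet momentum. Note that any dump generates some S0 coherence
directly from the (incoherent) S1 population, so the momentum
*inherited from the moving excited-state packet* must be isolated by
differencing against a decohered control — the same pre-dump state with
the S1 vibrational coherences zeroed. The inherited late/early contrast
is bounded by the surviving-coherence factor exp(−Δτ/T₂) ≈ 0.19 for
these delays; the measured value matches it.

**Wigner transform.** Exact expansion of the vibrational block in
harmonic-oscillator Wigner cross-terms (Laguerre form). Marginals equal
the position/momentum densities; a strict mode raises
`GridTruncationError` when density leaks past the grid edge.

## Difference maps and extrapolation (`pdpxtal.xtal`)

**Structure factors.** Two backends, automatically selected: direct
summation over symmetry images (exact; small models) and a
density-grid FFT (gemmi `DensityCalculatorX`, oversampling rate 4) for
large models; they agree to ~1e-5 relative on amplitudes for B ≥ 4.
Both set up symmetry images explicitly — without that step a
P2₁2₁2₁-indexed model silently degrades to P1.

**Q-weighting.** Difference amplitudes ΔF = F_light − F_dark are
weighted by w = [1 + σ²/⟨σ²⟩ + α·ΔF²/⟨ΔF²⟩]⁻¹. The raw `delta_F` column
travels with the weighted set; extrapolation scans use the *unweighted*
differences (α effectively 0), because the ΔF² shrinkage term rescales
even noise-free differences and biases PT = 200/N_EXT low.

**Extrapolation.** F_EXT = |F_dark,calc + n·ΔF| with dark phases; sign
flips are kept as 180° phase rotations so the complex coefficient stays
linear in n. The N_EXT scan therefore needs only two map syntheses: all
other maps on the grid are linear combinations of the n = 0 and n = 1
maps.

**Characteristic N_EXT.** Negative density below a threshold is
integrated within a radius of the region atoms across the n grid; the
onset of buildup is located by a continuous two-segment piecewise-linear
least-squares fit (a derivative-threshold estimator is available as an
alternative). PT = 200/N_EXT in percent. Two deliberate deviations from
the common recipe, both validated on synthetic crystals:

- *Fixed threshold from the dark map* (−level·rms(dark), default
  level 3) rather than per-map rms: extrapolation raises each map's rms
  with n, so a per-map relative cut deepens along the scan and masks the
  onset being measured.
- *Tight integration radius* (1.2 Å in the demo workflow, not the
  conventional ~7 Å): a wide region admits over-extrapolation ghosts in
  bulk solvent that cross the threshold well before the vacated atomic
  sites do.

**Known biases** (quantified on the toy crystal): the detection
threshold lags the true zero crossing by ≈ level·rms/ρ_peak (late bias,
smaller for sharper atoms and larger cells), while the dark-phase
projection keeps slightly more than half of any difference feature
centred on a dark atom (early bias ≈ 2·Z_moved/(Z̄·√N_atoms_per_cell)).
The default 200-atom toy crystal sits where both terms are a few
percent; few-atom unit cells make the 2/f onset rule fail badly, which
is why the synthetic generator defaults to a protein-like regime.

**Geometry.** Pairwise distances use the nearest symmetry image, so
contacts across cell boundaries report physical distances; displacement
reports match like-labelled atoms between two models.

## Kinetics and thermodynamics (`pdpxtal.kinetics`)

**Arrhenius.** 1/τ = A1 + A2·exp(−Ea/RT), weighted nonlinear least
squares in rate space over (ln A1, ln A2, Ea) with deterministic
multi-start. Ea is flagged non-identifiable when the exponential channel
is negligible or does not vary across the fitted range. On the default
synthetic truth (Ea = 91 kJ/mol, 8 points over 284–323 K, 5% noise) the
mean recovered Ea is unbiased and ≥ 90% of replicates land within
±5 kJ/mol.

**Convex Arrhenius.** Two Boltzmann-weighted channels of a double well:
k(T) = w₁k₁e^(−E₁/RT) + w₂k₂e^(−E₂/RT), w₁ = [1+e^(−ΔG/RT)]⁻¹, giving a
downward-curved ln k vs 1/T plot. An AIC guard falls back to the simple
fit when the data carry no curvature. Note the 5-parameter model is
only weakly identifiable from rate data: distinct parameter sets
reproduce the same curve to <0.1%, so fits are validated by curve
reproduction and model selection, not by parameter recovery.

**Flash yield.** Y(F) = φ(1−e^(−σ_lin F))e^(−σ_nl F), log-parameterized
positive fit; the closed-form optimal fluence ln(1+σ_lin/σ_nl)/σ_lin is
verified against a dense grid search.

**Action trace.** Yield suppression = 1 − depth·Φ(δ/σ_cc)·e^(−δ/τ_ES)
(decay for positive delays), with σ_cc the pump–dump cross-correlation
width.

## Transient absorption (`pdpxtal.ta`)

**IRF convolution.** The step-exponential ⊗ Gaussian closed form is
evaluated piecewise: the scaled-complementary-error-function (erfcx)
branch for non-negative argument (avoids Gaussian underflow) and the
plain exp·erfc product for negative argument (where erfcx overflows).
Verified against numerical quadrature to 1e-8 and stable out to delays
of 10⁴ lifetimes.

**Sequential global fit.** Concentrations of the A→B→… chain are
Bateman superpositions of IRF-convolved exponentials. The global fit
uses variable projection: the nonlinear search runs over (log τ, t₀,
IRF width) while the evolution-associated difference spectra (EADS) are
solved by linear least squares (NaN-aware, so chirp-corrected edges are
handled) at every step. Fitting more compartments than the data support
is structurally unidentifiable (the extra compartment is absorbed by
the EADS); such fits still reproduce the data and contain the true time
constant, and near-duplicate time constants are flagged `degenerate`.

**Chirp.** Group delay as a ≤2nd-order polynomial in wavelength;
correction shifts each wavelength column by interpolation, NaN outside
the measured range.

## Synthetic data (`pdpxtal.synth`)

Every generator is deterministic under a fixed seed and returns its
ground truth alongside the data: toy crystals (coherent mixed-state
amplitudes |(1−f)F_dark + f·F_perturbed| plus optional relative
Gaussian amplitude noise), TA surfaces (sequential chain × Gaussian-band
EADS, optional chirp and absolute noise), band traces, and
Arrhenius/convex/flash-yield/action-trace series. The default Arrhenius
truth is A1 = 2×10⁻⁵ s⁻¹, Ea = 91 kJ/mol, with A2 set by a 2600-s
recovery time at 293 K.
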