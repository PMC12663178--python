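# Methods

## Physical picture and model

A single microbubble, nucleated on a magnetic bead at the center of the
field of view, expands to a maximum radius R_max and collapses within
microseconds. The collapse porates the membranes of surface-attached
*E. coli*; propidium iodide (PI, divalent cation, membrane-impermeant) then
enters through the pores over a timescale of minutes and reports damage as
DNA-bound fluorescence. Distances are expressed as γ = l_cell / R_max
measured from the cavitation center (the image center); the analysis region
is γ ≤ 3 (inclusive).

Three nested descriptions are implemented:

1. **Per-cell kinetics.** Each trace is fitted with
   I(t) = I_final (1 − e^(−kt)), nonlinear least squares with initial guess
   (max of the trace, 0.01 1/s) and bounds I_final ≥ 0, k > 0. Time is
   measured from the cavitation event; the first frame sits at the
   acquisition delay (default 3 s), since the model is anchored at the
   collapse, not at the start of imaging. The initial uptake rate is the
   analytic derivative k·I_final rather than a finite difference on noisy
   early frames. Cohort statistics use a *single-pass* 3σ exclusion: the
   mean and SD are computed once, values beyond 3σ are removed, and the
   retained set is summarised. When the retained spread is exactly zero no
   value is excluded.

2. **Radial plateau law.** I_final(γ) = a + b/γ, linear in 1/γ and solved
   in closed form by unweighted OLS. The 1/γ form follows from collapse
   energy spreading over 2-D annuli (work p·δA over an annulus of area
   2πγδγ gives pressure ∝ 1/γ).

3. **Modified Goldman transport.** Dimensionless outside/inside
   concentrations c₁ + c₂ = 1 with c₁(γ,0) = 1. In dimensionless time
   t̃ = t/T_obs,

       dc₁/dt̃ = α (P/p₀)(γ,t̃) (c₂α_m − c₁)/(1 − α_m),

   with α = p₀T_obs φ/κ, φ = z·e₀·ΔΦ_m/(k_B T), α_m = e^(−φ), and the
   permeability field P(γ,t) = k·k₁·I_final(γ)·e^(−kt) (pore resealing as
   exponential decay with the fitted k). Because α_m ≈ 10⁻⁴ the system has
   the closed form c₁ = exp[(φk₁/κ)·I_final·(e^(−θt̃) − 1)], θ = k·T_obs,
   whose first-order expansion matches the measured saturation curve and
   licenses the intensity–concentration calibration I = c₂·c₀·k₂ with
   k₂ = κ/(φk₁c₀).

## Parameters, units, defaults

All transport computation is SI; fluorescence stays in camera AU.

| parameter | default | unit | meaning |
| --- | --- | --- | --- |
| density | 0.28 | cells/µm² | lawn density on the cover glass |
| FOV | 223.5 (1024 px) | µm | field of view; pixel 0.2183 µm |
| R_max | 29.7 | µm | maximum bubble radius |
| dt, frames, delay | 0.5, 1300, 3 | s, –, s | acquisition timing |
| k_mean ± k_sd | 0.0046 ± 0.0018 | 1/s | cohort uptake-rate distribution |
| a, b | 321, 228 | AU | plateau law coefficients |
| noise_sd | 20 | AU | additive ROI measurement noise (see below) |
| c₀ | 6×10⁻⁵ (60 nM) | mol/m³ | initial PI concentration |
| ΔΦ_m, z, T | 0.125, 2, 300 | V, –, K | membrane potential, PI valence, temperature |
| D, L | 10⁻¹², 50×10⁻⁹ | m²/s, m | PI diffusivity, pore path length → p₀ = D/L = 2×10⁻⁵ m/s |
| cell a × r_e | 2 × 0.5 | µm | cylinder geometry; ρ = 0.275/µm², β = 0.41, h₀ = 2 µm |
| T_obs | 600 | s | observation window |
| k₁ | 0.011 | m/AU | permeability–intensity factor |
| I₁₀₀ | 2500 | AU | plateau read as 100% membrane damage |
| bead thresholds | 5 µm², 15,000 AU | – | conjunctive autofluorescent-bead exclusion |

Derived at defaults: φ = 9.67, α_m = 6.3×10⁻⁵, κ = 7.26×10⁻⁷ m
(from the cylinder-geometry formula a·r_e(1/(πr_e²) − ρ)/(2ρ(r_e + a))),
θ = k·T_obs = 2.76.

`GoldmanParams` accepts `kappa_override` and `phi_override` for users who
want to impose externally supplied scalars instead of the formula values;
the formulas are authoritative by default.

## Damage-fraction normalisation

The raw Goldman estimate S_p = (k·k₁/p₀)·I_final(γ)·e^(−kt) equals the
relative permeability P/p₀ (pore density n and pore radius r_p enter only
through nπr_p² = P/p₀ and are not separately identifiable). Evaluated with
the default constants the raw value exceeds one, so the reported fraction is
normalised so that a plateau of I₁₀₀ = 2500 AU at t = 0 maps to S_p = 1 —
the calibration that reads 2500 AU as a totally damaged cell — and capped to
[0, 1]. The unnormalised value remains available (`raw=True`).

## What the generator emulates — and what it does not

The generator draws a Poisson(density × FOV²) count of uniformly placed
cells, computes γ from position (clamped below at 0.05; the closest
analysable cells sit near γ ≈ 0.14), assigns plateaus exactly on the radial
law and rates Normal(k_mean, k_sd) truncated by redraw at 10⁻⁵ 1/s, and adds
i.i.d. Gaussian noise (sd 20 AU, floored at zero) to the saturation curves.
The 20 AU default is a generator choice — measurement noise of the real
camera was never characterised — sized so that single-trace fits are
noticeably noisy but the cohort remains informative. Optionally cells inside
a detachment annulus (γ < γ_detach) can be removed to emulate the ring of
detached cells around the collapse site; this is off by default.

Not emulated: photobleaching, EM-gain/camera noise statistics, spatially
correlated background, bubble-dynamics physics, cell-to-cell contact
effects, or deviation of the true plateau field from the exact 1/γ law.
Passing recovery tests therefore demonstrates the *estimators* are unbiased
and correctly implemented under the stated statistical model — not that the
model captures every feature of real micrographs.

Rendered stacks paint each cell as a 2 × 1 µm rod (random orientation) whose
pixels all carry the trace value, so the ROI **mean** — the default
extraction statistic, matching common ROI-manager practice — reproduces the
trace exactly up to rasterisation; overlapping footprints sum. Beads are
discs of constant 20,000 AU in every frame (they autofluoresce
throughout), above the 15,000 AU masking threshold.

## Extraction choices

* Registration is translation-only phase correlation against the final
  frame (the frame with maximal content), integer-pixel by default, shifts
  capped at 10 px; content-free frames pass through with zero shift and a
  warning.
* Background subtraction clips at zero: cameras report no negative
  background-subtracted counts.
* Bead exclusion is conjunctive — a connected component is removed only if
  both the area and the intensity thresholds are exceeded; cells partially
  overlapping the bead mask keep their non-bead pixels, cells fully inside
  it are dropped and logged.
* Cell positions are intensity-weighted centroids (weights from the final
  frame, geometric fallback for unstained cells) at pixel centers, in µm;
  γ is therefore independent of pixel size.
* The labeled cell mask is an *input* (brightfield-derived); automatic
  segmentation is out of scope, mirroring manually drawn ROIs.

## Numerical choices

* Saturation fits: trust-region reflective least squares with analytic
  Jacobian; non-convergence, all-zero traces and nonfinite solutions are
  flagged `converged=False` and excluded from every population summary.
  A constant nonzero trace legitimately drives k to the large-rate regime
  and is caught the same way.
* R² is returned as NaN (flagged, not raised) when the observed trace has
  zero variance.
* The Goldman ODE runs per-γ decoupled as one vector system (LSODA,
  rtol 10⁻⁸, atol 10⁻¹⁰) in dimensionless time. The default continuity
  closure substitutes c₂ = 1 − c₁ into the flux term, which honours the
  normalisation c₁ + c₂ = 1 exactly — the closure under which the closed
  form is derived. An alternative bookkeeping in which the inside
  compartment gains (β−1)/β times the outside loss is available
  (`continuity="volume_fraction"`); for β = 0.41 it does not conserve
  c₁ + c₂ and is provided for comparison only.
* Solver verification compares the ODE integration (with the Nernst
  back-term α_m set to zero) against the closed form on 50 × 200 grids at
  exponent scales where both solutions have resolvable dynamics. At the
  formula-derived default constants the exponent prefactor is so large that
  c₁ underflows to zero within the first time step, which makes a relative
  comparison meaningless; the verification regime is a property of the
  check, not of the model.
* The linearised c₂ warns (does not raise) when its expansion parameter
  exceeds 0.1; the deviation from the exact expression is bounded by the
  second-order Taylor remainder x²/2.

## Known limitations

* The plateau law diverges as γ → 0; the γ clamp (0.05) and the capped
  damage fraction bound its consequences but very-near-field values are
  extrapolations.
* Radial symmetry is assumed throughout; asymmetric collapse, heterogeneous
  membrane responses and stochastic pore dynamics are not modelled.
* The k₁, I₁₀₀ calibration pair is phenomenological; S_p is meaningful
  relative to the 2500 AU ≙ 100% anchor, not as an absolute pore census.
* Fitting 5,000 × 1300-frame cohorts takes ~10 s; the default field-map
  grids (60 × 121) render in well under a second. Problem sizes in the test
  suite (20-cell rendered stacks, 30-frame stacks) are chosen to exercise
  every code path while keeping the suite fast.
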