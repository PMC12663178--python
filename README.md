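# piuptake

Spatiotemporal analysis of propidium-iodide (PI) uptake by surface-attached
*Escherichia coli* after a **single microbubble cavitation event**.

When a microbubble collapses near a lawn of bacteria, the mechanical stress
transiently porates nearby cell membranes. PI — normally membrane-impermeant —
enters through the pores, binds DNA, and the resulting fluorescence reports
both *how much* each cell was damaged and *how fast* the dye gets in. This
package turns a time-lapse fluorescence stack (or a per-cell trace table)
into quantitative maps of membrane permeability and damage around the
collapse site. It is aimed at researchers in sonoporation, cavitation-based
drug delivery and microbial inactivation who want per-cell kinetics rather
than endpoint staining counts.

## The model

Each cell sits at a normalised distance γ = l_cell / R_max from the
cavitation center (R_max is the bubble's maximum radius). Its fluorescence
follows first-order saturation kinetics,

    I(γ, t) = I_final(γ) · (1 − e^(−k t)),        ∂I/∂t |_(t=0) = k · I_final,

with a per-cell rate constant k (1/s) and a plateau that decays with
distance as an inverse law,

    I_final(γ) = a + b/γ    (AU),

as expected when the collapse energy spreads over 2-D annuli. A modified
Goldman flux model links the measured intensity to membrane transport: the
permeability field

    P(γ, t) = k·k₁·I_final(γ)·e^(−k t)

is maximal at the moment of collapse and decays as pores reseal, the pore
area fraction of the membrane is S_p = P/p₀ (p₀ = D/L is the characteristic
permeability of a fully porated membrane), and the dimensionless outside/
inside dye concentrations c₁, c₂ obey a two-compartment ODE driven by the
transmembrane potential, with the closed-form solution

    c₁(γ, t̃) = exp[(φ k₁/κ) · I_final(γ) · (e^(−θ t̃) − 1)],  c₂ = 1 − c₁,

whose small-prefactor linearisation reproduces the measured saturation
time course — the justification for reading fluorescence as internal
concentration.

Because no raw microscopy is distributed, the package ships a first-class
synthetic-data generator that emulates the experimental conditions (cell
density 0.28 /µm², 223.5 µm field of view, R_max = 29.7 µm, 1300 frames at
0.5 s starting 3 s after collapse, autofluorescent beads) so the entire
pipeline is testable end to end.

## Worked example

```python
from piuptake import (PipelineConfig, RadialIntensityLaw, fit_traces,
                      population_k_stats, GoldmanParams, derive_constants,
                      damage_fraction)
from piuptake.pipeline import simulate_cohort

cfg = PipelineConfig(seed=1)                       # experimental defaults
truth, traces = simulate_cohort(cfg, n_cells=1000)  # γ ≤ 3 cohort
fits = fit_traces(traces.intensities, traces.time_s,
                  gamma=truth["gamma"].to_numpy())
stats = population_k_stats(fits)                   # 3σ outlier exclusion
sub = fits[fits["converged"]]
law = RadialIntensityLaw().fit(sub["gamma"], sub["I_final"])

params = GoldmanParams()
consts = derive_constants(params, stats.mean_k)
s0 = damage_fraction(1.0, 0.0, stats.mean_k, params.k1, law, consts.p0)
```

This prints (via the session's formatting):

```
cells fitted: 1000/1000
mean k = 0.00467 1/s, sd = 0.00172 1/s
tau_char = 214.0 s (0 outliers excluded)
radial law: I_final(gamma) = 320.0 + 228.4/gamma (R^2 = 0.989)
p0 = 2.0e-05 m/s, phi = 9.67, kappa = 7.26e-07 m
damage fraction at gamma=1: 21.9% at collapse -> 1.3% after 600 s
```

Reading: the cohort's uptake rate constant averages 0.00467 1/s, i.e. a
characteristic saturation time of ~214 s — PI keeps entering for minutes
after a microsecond-scale mechanical event, because pores reseal slowly.
The fitted plateau law recovers the generating coefficients (a ≈ 320 AU,
b ≈ 228 AU), and at the projected bubble radius (γ = 1) about a fifth of
the membrane area is porated immediately after collapse, resealing to ~1%
within the 600 s observation window.

The same analysis is available from the shell:

```bash
piuptake simulate --seed 1 --out runs/demo        # synthetic end-to-end run
piuptake extract  --stack stack.tif --mask labels.tif --out traces.csv
piuptake fit      --traces traces.csv --out fits.csv --summary summary.json
piuptake model    --summary summary.json --out fields/
piuptake run      --config cfg.yaml --out runs/full
```

Every run directory contains the resolved `config.yaml`, `traces.csv`,
`fits.csv`, `summary.json`, the spatiotemporal `fields.csv`
(γ, t, I, P/p₀, S_p, c₁, c₂ in long format) and figures.

## Layout

| module | contents |
| --- | --- |
| `piuptake.synthetic` | cell fields, ground truth, trace simulation, stack rendering |
| `piuptake.extraction` | registration, background subtraction, bead masking, ROI traces, γ |
| `piuptake.kinetics` | `SaturationCurve` and `RadialIntensityLaw` estimators, cohort statistics |
| `piuptake.goldman` | derived constants, permeability/damage fields, ODE + closed-form solvers |
| `piuptake.pipeline` / `piuptake.cli` | staged runs, exports, figures, `piuptake` command |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
numerical choices.
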