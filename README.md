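# bivalentfit

Estimation of bivalent-analyte (1:2) binding kinetics from surface
plasmon resonance (SPR) titration sensorgrams.

When an IgG antibody in solution binds an antigen immobilised on a
sensor chip, its second arm can capture a second antigen — an avidity
effect the 1:1 Langmuir model cannot describe. `bivalentfit` implements
the sequential two-step kinetic scheme

```
A  + L  ⇌  AL1        (ka1, kd1)
AL1 + L ⇌  AL2        (ka2, kd2)
```

with ligand species carried in response units (RU) and the analyte
concentration [A] in molar units, so ka1 is in M⁻¹s⁻¹ and ka2 in
RU⁻¹s⁻¹. During the association phase the model ODEs are

```
d[L]/dt   = −(2·ka1·[A][L] − kd1·[AL1]) − (ka2·[AL1][L] − 2·kd2·[AL2])
d[AL1]/dt =  (2·ka1·[A][L] − kd1·[AL1]) − (ka2·[AL1][L] − 2·kd2·[AL2])
d[AL2]/dt =   ka2·[AL1][L] − 2·kd2·[AL2]
```

(the factors of two are the two-equivalent-arm statistical factors);
during dissociation rebinding is neglected (ka1 = ka2 = 0), which makes
the system linear with an exact solution. The measured signal is
AL1 + AL2. Non-regenerative kinetic titrations are handled by
back-extrapolation: each cycle is integrated from an adjusted start
t₀ = t₀* − t* with a bare surface, where the initial-time adjustment
t*ⱼ is a fitted per-cycle parameter alongside Rmaxⱼ.

The package provides:

- **Global fitting** — all M concentrations share the four rate
  constants; 4 + 2·M parameters (14 when M = 5) are estimated by
  bounded trust-region least squares (Levenberg–Marquardt-type, all
  parameters ≥ 0), started from a Cartesian grid of initial guesses
  (3 values per rate constant → 81 starts by default) because the SSE
  surface has local minima.
- **Practical identifiability** — per-parameter profile likelihoods
  `PLL_j(c) = min {NLL(p) : p_j = c}` with the χ² threshold
  `min NLL + χ²(α, df)/2`; a profile that stays below the threshold out
  to a grid boundary on one side (the "L-shape") marks the parameter
  practically non-identifiable.
- **Simulation-guided experimental design** — generate noisy synthetic
  titrations under candidate designs, run the full fit-and-profile loop
  per replicate, and compare designs by identifiability verdicts and
  replicate dispersion (CV). The bundled scenario pair contrasts the
  standard 600 s dissociation window with an extended 1780 s one: the
  slow second dissociation step (kd2 ≈ 1e−5 s⁻¹) is only identifiable
  under the latter.

## Worked example

Simulate a noisy extended-dissociation titration with the bundled
simulation-study parameters (ka1 = 2.00e3, kd1 = 4.00e−3,
ka2 = 5.00e−5, kd2 = 1.00e−5, Rmax = 600 RU, σ = 6 RU) and fit it:

```python
import bivalentfit as bf
from bivalentfit.design import QUICK_GRID

scenario = bf.extended_scenario(sigma=6.0, seed=1)
series = bf.generate_noisy_titration(scenario, 0)

cfg = bf.FitConfig(sigma=6.0, grid=QUICK_GRID)   # 16-start quick grid
model = bf.BivalentKineticsModel(series, cfg)
res = model.fit()                                 # grid-search global fit
print(res.summary())
print(res.profile("kd2").verdict)
```

Output:

```
Bivalent Analyte Kinetics — Global Fit
======================================================
No. cycles (M):             5
No. observations:           5205
No. parameters:             14
SSE (RU^2):                 186421
Residual SD (RU):           5.993
Converged:                  True
Grid starts:                16  (reached global: 10)
------------------------------------------------------
parameter         estimate       std err
ka1                   2121        0.8102  M^-1 s^-1
kd1               0.003944      0.000101  s^-1
ka2              5.384e-05     9.886e-07  RU^-1 s^-1
kd2              9.969e-06     8.688e-07  s^-1
rmax_1               580.7         1.181  RU
tstar_1              266.3         1.114  s
...
======================================================
identifiable
```

The recovered rate constants sit within a few percent of the generating
values, the residual SD (5.99 RU) recovers the injected noise level
(6 RU), and kd2 is identifiable under the extended design. With the
standard 600 s design the same call classifies kd2 as
practically-non-identifiable, and its estimate frequently collapses to
the zero lower bound.

Command-line equivalents: `bivalentfit simulate`, `bivalentfit fit`,
`bivalentfit profile`, `bivalentfit design-eval` (see `--help`); every
run writes a `manifest.json` (config, seed, input digests) for exact
reproduction.

## Data formats

Sensorgrams are long-format CSV with columns
`cycle, concentration_M, time_s, response_RU, phase`
(phase ∈ {association, dissociation}), one file per replicate; reading
sorts by cycle and time and validates phase contiguity and time
monotonicity. Run and scenario configuration are YAML
(`FitConfig.from_yaml`, `bivalentfit simulate --config`). Reference and
buffer subtraction are assumed done upstream in the vendor software.
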