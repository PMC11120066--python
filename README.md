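# brachysafe

External ambient dose equivalent rate — H\*(10) — prediction and
radiation-safety assessment around patients with permanently implanted
I-125 brachytherapy seeds.

The package contains:

- **`brachysafe.physics`** — embedded physical data (I-125 photon lines,
  water/air interaction coefficients for 5–60 keV, fluence→H\*(10) and
  air-kerma→H\*(10) conversion coefficients for 10–60 keV, decay data) with
  strict no-extrapolation interpolation.
- **`brachysafe.transport`** — a desk-scale analog Monte Carlo photon
  transport of I-125 emissions through a Mylar-window water phantom
  (35 × 35 × 37 cm³), tallying H\*(10) at point detectors 0/30/100 cm from
  the phantom surface with a next-event (point-detector) estimator.
  Klein–Nishina incoherent scattering, isotropic-angle coherent scattering
  (toggleable), implicit capture with Russian roulette.
- **`brachysafe.expmodel`** — normalization of depth-dose series to the
  1 cm source position and `A·exp(−b·z)` fitting (nonlinear least squares on
  the linear scale, log-linear initialization), plus the registry of
  published coefficients per detector distance:
  `(0 cm: 1.7811, 0.5841)`, `(30 cm: 1.4360, 0.3555)`,
  `(100 cm: 1.4026, 0.3273)`.
- **`brachysafe.assess`** — the predictive model proper
  (`Sk·Λ·CF·A·exp(−b·z)` in µSv/h), four-direction patient predictions with
  decay correction, far-field estimates (inverse square + 2 cm
  water-equivalent half-value layer), cumulative-dose integration, release
  checks (5 mSv/y caregivers, 1 mSv/y public, inclusive boundary) and
  uncertainty-budget arithmetic.
- **`brachysafe.cohort`** — synthetic cohort generation (truncated-normal
  water-equivalent thicknesses and implant strengths) and phantom/patient
  measurement emulation (0.20 µSv/h background, 2% statistical noise,
  detector range clipping, weekly decay).
- **`brachysafe.validate`** — percent-difference summaries and a
  from-scratch two-tailed Mann–Whitney U test (exact by enumeration /
  count recursion, or normal approximation with tie and continuity
  corrections).
- **`brachysafe.cli`** — the `brachysafe` command tying the pipeline
  together.

## CLI

```sh
# Monte Carlo depth-dose series at 0/30/100 cm, depths 1–20 cm
brachysafe simulate --depths 1:20 --distances 0,30,100 \
    --n-histories 100000 --seed 1 --out series.csv

# fit the normalized exponential models
brachysafe fit --in series.csv --out models.json

# synthetic 21-patient cohort, predictions, validation, release assessment
brachysafe synth --n 21 --seed 1 --out patients.csv
brachysafe predict --patients patients.csv --model paper --out predictions.csv
brachysafe validate --predictions predictions.csv --seed 2 --out report.json
brachysafe assess --predictions predictions.csv --category caregiver \
    --daily-hours 6 --occupancy 0.25 --out assessment.json
```

`--model fitted:models.json` swaps the published coefficients for your own
fit. Every stochastic stage takes `--seed`; output CSV headers carry the
seed, config hash and package version in a `#` comment so data rows are
reproducible byte-for-byte.

## Modeling notes

- The implant is modeled as an isotropic point source; seed capsule
  internals, the thin Mylar window and the source tube are treated as
  water, and air attenuation outside the phantom is neglected (all sub-1%
  at ~28 keV).
- The survey-meter reading position includes a 4.5 cm effective-centre
  standoff behind the instrument's front face
  (`transport.DETECTOR_STANDOFF_CM`): a reading "at 0 cm" has its
  sensitive volume several cm from the contact plane, which is what the
  published surface depth-curve shape reflects. Pass `standoff_cm=0` for
  bare geometric points.
- The absolute scale of the predictive equations multiplies the TG-43
  source term `Sk·Λ` (dose rate at 1 cm in water) by curves normalized at
  the 1 cm source depth; the equations are implemented verbatim as
  published, and their absolute rates should be interpreted accordingly.
- Photons below 10 keV (the conversion-grid floor) deposit no H\*(10);
  transport continues to a 5 keV cutoff.
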