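# idealdrf

Tools for the **IDEAL classification** of distal radius fractures and for
the observer-agreement studies used to validate classification systems.

Distal radius fractures are among the most common skeletal injuries, and
several competing radiographic classification systems (Frykman, Fernandez,
AO) are in clinical use — all with modest reproducibility. The IDEAL
score takes a different approach: five dichotomous items chosen for their
treatment and prognosis relevance —

| Item | 0 points | 1 point |
|------|----------|---------|
| **I**ncongruity | none | articular step/gap ≥ 2 mm |
| **D**isplacement | none/minimal | requires reduction (shortening > 3 mm, volar tilt loss > 10°, or radial inclination loss > 5°) |
| **E**nergy | low (fall from standing height) | high |
| **A**ge | < 60 years | ≥ 60 years |
| **L**esions | absent | associated lesions present |

The total score 0–5 maps to three fracture types: **I** (0–1, stable →
conservative treatment, good prognosis), **II** (2–3, potentially
unstable → pins/external fixation/plating, intermediate), **III** (4–5,
complex → associated methods/bone graft, poor).

The package is aimed at clinical researchers running (or simulating)
classification-reproducibility studies. Besides the scoring rule it
provides:

- **Agreement statistics** — Cohen's κ = (p_o − p_e)/(1 − p_e) for two
  raters with the Fleiss–Cohen–Everitt large-sample standard error, and
  Fleiss's multi-rater κ with the Fleiss–Nee–Landis standard error;
  intraobserver (sessions-as-raters), interobserver (observers per
  session), mean pairwise κ, session-drift checks, interpretation bands
  (< 0.5 unsatisfactory, 0.5–0.75 satisfactory, > 0.75 excellent), and
  cross-system F-test comparisons.
- **Sample-size planning** — the expected-CI-width method for agreement
  studies under the common-correlation binary model.
- **A rating simulator** — synthetic fracture cases with ground truth,
  observers with measurement noise and per-system confusion matrices,
  within-observer session correlation and optional learning effects, all
  with closed-form expected kappas for validation.
- **A study pipeline** — one call from a long-format rating CSV to the
  standard report tables (intraobserver, interobserver, comparisons).

## Worked example

```python
from idealdrf import CaseContext, RadiographicFindings, classify

findings = RadiographicFindings(articular_step_mm=2.5,
                                radial_shortening_mm=4.0,
                                volar_tilt_loss_deg=12.0)
context = CaseContext(age_years=72, energy="high", lesions_present=False)
print(classify(findings, context))
```

prints component scores `I=1 D=1 E=1 A=1 L=0`, `total=4`, and
`Type III (Complex) — treatment: Associated methods/bone graft; prognosis: Poor`:
an intra-articular, displaced, high-energy fracture in an elderly patient
is a complex injury with a poor outlook regardless of treatment.

A full simulated reproducibility study (`python
examples/full_study_pipeline.py`) prints, among other tables:

```
Interobserver reproducibility per session:
session  IDEAL  Frykman  Fernandez    AO
     T1  0.797    0.698      0.704 0.688
     T2  0.762    0.671      0.657 0.741
     T3  0.736    0.686      0.695 0.737
   Mean  0.765    0.685      0.685 0.722
```

Each cell is a Fleiss κ across the six simulated observers at one
session; the Mean row is the per-system arithmetic mean rounded half-even
to 3 decimals. Sample-size planning:

```sh
$ ideal samplesize --kappa 0.70 --conf 0.90 --width 0.333
required subjects: 50 (expected 90% CI width 0.332 <= 0.333)
```

i.e. 50 subjects suffice for an anticipated κ of 0.70 if an expected 90%
CI of about ±0.17 is acceptable.

The `examples/` directory holds one short script per capability
(scoring, agreement statistics, sample size, simulation, full pipeline);
the `ideal` command line mirrors the same steps for CSV files
(`ideal score`, `ideal agree`, `ideal simulate`, `ideal study`,
`ideal samplesize`).

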