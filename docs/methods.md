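# Methods

## The IDEAL scoring rule

Five dichotomous items — joint Incongruity, Displacement, trauma Energy,
patient Age, Associated Lesions — each score 0 or 1; the total 0–5 maps
to Type I (0–1), II (2–3) or III (4–5). The rule is total-additive, so
raising any component can never lower the type (verified exhaustively
over all 2⁵ component vectors), and the three bands partition the score
range with no gaps or overlaps.

**Boundary conventions.** The published criteria state the articular
step/gap cut-off both as "> 2 mm" and as "≥ 2 mm", and the age cut-off
both as "≥ 60" and with exactly 60 left undefined. This implementation
fixes both boundaries as *inclusive*: a step of exactly 2.0 mm scores 1,
and age exactly 60 scores 1. The three displacement thresholds
(shortening 3 mm, volar tilt 10°, radial inclination 5°) are *strict*,
matching their printed wording. An explicit requires-reduction judgement,
when supplied, overrides the displacement thresholds — clinically the
reduction decision is the primary datum and the thresholds its proxy.
Units are fixed (mm, degrees, years); no auto-detection.

## Agreement statistics

**Cohen's κ** (two raters): κ = (p_o − p_e)/(1 − p_e), with p_e from the
product of the raters' marginal distributions. The standard error is the
Fleiss–Cohen–Everitt large-sample (non-null) variance; confidence
intervals are normal-approximation, clipped to [−1, 1]. The default
confidence level is 95%, configurable everywhere.

**Fleiss's κ** (m raters per subject): chance-corrected mean pairwise
agreement from the subjects × categories count matrix. The standard
error is the Fleiss–Nee–Landis large-sample formula — derived under the
no-agreement null, which is the conventional reference SE for this
statistic; tests that compare estimates to analytic values therefore use
it as a scale for Monte-Carlo tolerances, not as an exact non-null SE.

**Arrangements.** Intraobserver agreement across T1…Tk treats one
observer's sessions as interchangeable replicate raters and applies
Fleiss's κ (with two sessions this is the 2-replicate special case); the
method itself does not dictate this arrangement, so the consecutive-pair
Cohen κs (T1 vs T2, T2 vs T3) are exposed separately as the session-drift
check for learning effects. Interobserver agreement is Fleiss's κ across
observers at one session; the mean pairwise Cohen κ over all observer
pairs is also reported, as the two summarize different aspects (pooled
marginals vs average pair concordance).

**Degeneracy.** Whenever expected agreement p_e = 1 (both raters constant
and identical; all rating mass in one category) κ is defined as 1 with
zero SE and flagged `degenerate` rather than returning NaN. Degenerate
pairs are excluded from pairwise means with a warning.

**Interpretation bands.** κ < 0.5 unsatisfactory, 0.5 ≤ κ ≤ 0.75
satisfactory, κ > 0.75 excellent. The band description "between 0.5 and
0.75" does not assign the endpoints; both are placed in the middle band
(closed interval), a choice that only matters at exact boundary values.

**Cross-system comparison.** The classical "Fisher F-test" label is
implemented as one-way ANOVA on unit-level κ values — units are
observers for intraobserver comparisons and sessions for interobserver
comparisons — with all pairwise two-group F tests alongside and an
optional permutation p-value for users unwilling to assume normality of
κ values. Zero between-group variance yields F = 0, p = 1; zero
within-group variance with non-zero between yields F = ∞, p = 0; both
edge cases are handled explicitly and all-constant inputs are flagged
degenerate.

**Missing ratings.** Subjects lacking a complete rater/session panel are
dropped per analysis with a warning and a recorded count; no imputation.
Analyses with fewer than two complete subjects raise, and the pipeline
records them as skipped rather than reporting silent zeros.

## Sample size by expected CI width

The design model is the common-correlation binary reproducibility study:
n subjects, two ratings each, trait prevalence π, intraclass kappa κ₀.
The large-sample variance of the estimated κ is

    var(κ̂) = (1 − κ₀)/n · [ (1 − κ₀)(1 − 2κ₀) + κ₀(2 − κ₀) / (2π(1 − π)) ]

and the expected full CI width is 2·z·√var. `required_n` returns the
smallest n ≥ 2 whose expected width meets the tolerance; minimality is
enforced (width(n) ≤ target < width(n−1)).

Defaults: π = 0.5 and two replicates, both exposed. For m > 2 replicates
the two-replicate variance is divided by (m − 1) — a pragmatic
approximation treating the additional replicates as extra effective
rating pairs; it is exact at m = 2, the design the width method was
derived for, and conservative relative to ignoring the extra replicates.

**The 50-subject reference design.** At κ₀ = 0.70 and 90% confidence the
method is often quoted as requiring 50 subjects without stating the
assumed width or prevalence. With π = 0.5, any width tolerance in
[0.3322, 0.3356) — an expected CI of roughly ±0.17 — yields exactly
n = 50 (`width_window_for_n(0.70, 50)` computes the window for other
assumptions). Because the (π, width) pair is not uniquely recoverable,
n = 50 is documented as a worked reference point, not asserted as an
oracle against unstated assumptions.

## The rating simulator

The generator emulates a reproducibility study on 60 fracture
radiographs read by a mixed six-observer panel in three blinded,
randomized sessions under four systems. Its defaults define the study
conditions used throughout the tests.

**Case mix.** No case-level distributions were published for such
samples, so the defaults are a plausible fracture-clinic mix chosen
once: ages ≈ N(62, 16²) truncated to 18–95 (distal radius fractures
cluster in older patients), 25% high-energy, 15% with associated
lesions, 55% displaced; displaced cases draw shortening/tilt/inclination
losses from zero-truncated normals (means 4.5 mm, 14°, 7°) and 45% of
them are intra-articular with step ≈ 2.8 mm; undisplaced cases carry
small half-normal measurement residuals (scale 0.3). True IDEAL labels
follow from scoring the true measurements. True Frykman/Fernandez/AO
labels are *sampled* from configurable category distributions (uniform
by default): those systems' morphological logic is out of scope and only
their label alphabets are modelled. The AO alphabet defaults to the nine
main subgroups A1–C3; a 27-label full-subgroup alphabet is available.

**Observer error.** IDEAL ratings are produced mechanistically: additive
Gaussian measurement noise truncated at zero on each continuous finding
(defaults 0.4 mm step, 0.8 mm shortening, 3° tilt, 2° inclination,
scaled per observer), small flip probabilities on the binary context
items, then re-scoring — so IDEAL disagreement emerges from measurement
uncertainty interacting with the thresholds, as it would on real
radiographs. Categorical systems use per-observer row-stochastic
confusion matrices; the default panel uses symmetric matrices (correct
with probability 1 − e, errors uniform) with error rates 0.05–0.30
grading the six observers from specialist to student. This is the
simplest model with closed-form agreement probabilities.

**Session correlation.** For each session after the first, with
probability ρ the observer reuses their session-1 perception of the
case, else re-perceives independently (default ρ = 0.35 in the standard
panel). ρ = 1 forces identical sessions (intraobserver κ = 1); ρ = 0
gives conditional independence. Per-session error multipliers scale all
error sources to model conditioning/learning effects.

**Analytic expectations.** For confusion-matrix observers the population
κ has closed forms: pair agreement Σ_t p_t Σ_l A[t,l]B[t,l], marginals
Aᵀp, and under the reuse model session 1 agrees with a later session
with probability ρ + (1 − ρ)a while two later sessions agree with
ρ² + (1 − ρ²)a, where a is the fresh-redraw self-agreement. These are
implemented in `analytic_cohen_kappa`, `analytic_fleiss_kappa` and
`analytic_intraobserver_kappa` and recovered by the estimators within
three standard errors at n = 1000 (500 for the session-correlation
check) in the test suite.

**Seeding.** One global seed expands into named substreams (cases;
observer i), so adding observers never changes the generated cases and
every output is bit-reproducible given the seed.

**What the simulator does not capture.** Real observers are not
conditionally independent given the truth (shared training induces
correlated errors); confusion is not symmetric across categories
(adjacent fracture patterns are confused more often); the morphological
systems' labels are unrelated to the generated measurements; and the
default panel applies one error rate per observer across all systems, so
simulated cross-system differences stem mainly from alphabet size and
the IDEAL noise model, not from intrinsic ambiguity differences between
real systems. Passing tests therefore validate the estimators and
pipeline plumbing, not any claim about real-world reproducibility of the
systems, and published study-level κ values cannot be reproduced here
because the underlying ratings were never deposited — they are covered
only through the aggregation arithmetic and interpretation-band checks.

## Pipeline and reporting conventions

Reported κs are rounded to 3 decimals with half-even (banker's)
rounding; the JSON report keeps full precision alongside. Per-system
interobserver summaries are arithmetic means over sessions.
Intraobserver summaries are reported two ways — the arithmetic mean of
per-observer κs and a pooled Fleiss κ over all (subject, observer)
session panels — because summary rows in published tables of this kind
are not always reproducible as plain means of the printed per-observer
values, and the two aggregations answer slightly different questions.
Validation reports duplicate keys, out-of-alphabet labels and missing
values as row-addressed errors and incomplete design grids as warnings;
logging goes to standard error, machine-readable output to files.

## Problem sizes in tests

Exhaustive kappa-oracle equivalence runs over all configurations with
≤ 4 subjects, ≤ 3 categories, ≤ 3 raters (≈ 20 000 instances, tolerance
1e-12). Stochastic checks use 1000 subjects (3-SE tolerance), 3000
Monte-Carlo replicates at n = 200 for the sample-size variance oracle
(the variance formula is asymptotic, so it is validated in its large-n
regime), and 2000 replicates for the F-test type-I-error check; these
sizes make the stochastic assertions comfortably stable under their
fixed seeds.
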