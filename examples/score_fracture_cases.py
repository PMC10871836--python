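"""Score individual distal radius fracture cases with the IDEAL rule.

Builds two illustrative cases, scores them, and prints the five component
points, the total and the resulting fracture type with its guidance.
"""

from idealdrf import CaseContext, RadiographicFindings, classify

cases = {
    "undisplaced fracture, 30-year-old, low-energy fall": (
        RadiographicFindings(articular_step_mm=0.5),
        CaseContext(age_years=30, energy="low", lesions_present=False),
    ),
    "displaced intra-articular fracture, 72-year-old, traffic accident": (
        RadiographicFindings(
            articular_step_mm=2.5,
            radial_shortening_mm=4.0,
            volar_tilt_loss_deg=12.0,
        ),
        CaseContext(age_years=72, energy="high", lesions_present=False),
    ),
}

for name, (findings, context) in cases.items():
    result = classify(findings, context)
    print(f"{name}:")
    print(
        f"  I={result.score_i} D={result.score_d} E={result.score_e} "
        f"A={result.score_a} L={result.score_l}  total={result.total}"
    )
    print(
        f"  Type {result.fracture_type.value} ({result.description}) — "
        f"treatment: {result.treatment}; prognosis: {result.prognosis}"
    )

# Each of the five items contributes 0 or 1 point; totals 0-1, 2-3 and 4-5
# map to Types I, II and III, ordered by severity and treatment complexity.
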