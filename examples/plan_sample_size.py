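"""Plan an agreement study by the expected-CI-width criterion.

Prints the number of subjects needed so that the anticipated confidence
interval for kappa is acceptably narrow, and the width tolerances that
reproduce a 50-subject design at kappa0 = 0.70 and 90% confidence.
"""

from idealdrf import SampleSizeSpec, expected_ci_width, required_n, width_window_for_n

spec = SampleSizeSpec(
    kappa0=0.70,          # anticipated agreement
    prevalence=0.5,       # binary trait prevalence
    confidence_level=0.90,
    max_expected_width=0.333,  # tolerated full CI width
)
n = required_n(spec)
print(f"required subjects: {n}")
print(f"expected 90% CI width at n={n}: {expected_ci_width(spec, n):.4f}")
print(f"expected 90% CI width at n={n - 1}: {expected_ci_width(spec, n - 1):.4f}")

low, high = width_window_for_n(0.70, 50, prevalence=0.5, confidence_level=0.90)
print(f"width tolerances yielding exactly n=50: [{low:.4f}, {high:.4f})")

# The returned n is minimal: the expected width meets the tolerance at n
# but exceeds it at n-1.  A 50-subject design corresponds to accepting an
# expected CI of roughly +/- 0.17 around the estimated kappa.
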