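"""Kappa agreement statistics on a small hand-built rating table.

Two observers rate ten subjects twice under the IDEAL label alphabet;
the script prints Cohen's kappa for one observer pair, the Fleiss-style
intraobserver kappa across sessions, and the interpretation bands.
"""

from idealdrf import (
    RatingTable,
    cohen_kappa,
    interobserver_kappa,
    interpret_kappa,
    intraobserver_kappa,
)

subjects = [f"S{i:02d}" for i in range(10)]
labels = {
    ("alice", "T1"): ["I", "I", "II", "II", "III", "I", "II", "III", "I", "II"],
    ("alice", "T2"): ["I", "I", "II", "II", "III", "I", "II", "II", "I", "II"],
    ("bob", "T1"):   ["I", "II", "II", "II", "III", "I", "I", "III", "I", "II"],
    ("bob", "T2"):   ["I", "II", "II", "I", "III", "I", "II", "III", "I", "II"],
}
records = [
    (subject, observer, session, "IDEAL", label)
    for (observer, session), seq in labels.items()
    for subject, label in zip(subjects, seq)
]
table = RatingTable.from_records(records)

pair = cohen_kappa(labels[("alice", "T1")], labels[("bob", "T1")])
print(f"Cohen kappa alice-vs-bob at T1: {pair.kappa:.3f} "
      f"(SE {pair.standard_error:.3f}, {pair.interpretation})")

for observer in ("alice", "bob"):
    intra = intraobserver_kappa(table, observer, "IDEAL")
    print(f"intraobserver kappa for {observer}: {intra.kappa:.3f} ({intra.interpretation})")

inter = interobserver_kappa(table, "T1", "IDEAL")
print(f"interobserver kappa at T1: {inter.kappa:.3f} ({inter.interpretation})")

# Kappa corrects raw agreement for what chance alone would produce:
# below 0.5 is unsatisfactory, 0.5-0.75 satisfactory, above 0.75 excellent.
print("band of kappa = 0.771:", interpret_kappa(0.771))
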