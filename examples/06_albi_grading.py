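"""ALBI score and modified ALBI grade from albumin and total bilirubin."""

from immunoprox import albi_score

cases = [
    ("well-preserved liver", 0.5, 4.5),
    ("worked example", 1.0, 4.0),
    ("typical cohort median", 0.9, 3.5),
    ("impaired reserve", 2.5, 2.6),
]
for label, bili, alb in cases:
    res = albi_score(bili, alb)  # mg/dL and g/dL, converted internally
    print(f"{label:22s} bilirubin {bili:3.1f} mg/dL, albumin {alb:3.1f} g/dL"
          f"  ->  ALBI {res.albi_score:6.3f}, mALBI grade {res.grade}")
print("\nGrades: 1 (<= -2.60), 2a (<= -2.270), 2b (<= -1.39), 3 (above);")
print("lower scores mean better hepatic reserve.")
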