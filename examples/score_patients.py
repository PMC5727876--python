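"""Score three emergency-department presentations with all three systems.

The GBS and mGBS rise with haemodynamic compromise and laboratory evidence
of bleeding; the pre-endoscopy Rockall score rises with age, shock and
comorbidity. A GBS/mGBS above 9 flags likely need of intervention; a
Rockall score above 4 flags high 30-day mortality risk.
"""

from ugib_triage import PatientRecord, compute_gbs, compute_mgbs, compute_pre_e_rs

patients = {
    "stable 50-year-old": PatientRecord(
        age=50, sex="male", pulse=80, sbp=130, bun=15, hb=14.5
    ),
    "anaemic 72-year-old with melena": PatientRecord(
        age=72, sex="female", pulse=105, sbp=105, bun=32, hb=9.2,
        melena=True, rockall_comorbidity="major",
    ),
    "shocked 85-year-old with cirrhosis": PatientRecord(
        age=85, sex="male", pulse=120, sbp=85, bun=80, hb=7.5,
        melena=True, syncope=True, hepatic_disease=True,
        rockall_comorbidity="severe",
    ),
}

print(f"{'patient':38s} {'mGBS':>5s} {'GBS':>4s} {'Pre-E RS':>9s}")
for label, p in patients.items():
    print(f"{label:38s} {compute_mgbs(p):5d} {compute_gbs(p):4d} {compute_pre_e_rs(p):9d}")
print()
print("mGBS/GBS > 9 suggests need of intervention; Pre-E RS > 4 flags high")
print("30-day mortality risk (Youden-optimal cutoffs of the source cohort).")
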