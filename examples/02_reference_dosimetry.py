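"""Full reference dosimetry on a synthetic cohort.

Each time-activity curve is fitted (mono-exponential, uptake
bi-exponential, or trapezoid-with-tail fallback), integrated to infinity,
and converted to absorbed dose with the sphere-model self-dose factor.
Printed means should sit near the configured population targets: kidneys
~0.71, parotid ~0.28, submandibular ~0.22 mGy/MBq, lesions declining from
~3.9 (cycle 1) to ~2.0 mGy/MBq (cycle 4).
"""

from lutadose import CohortConfig, cumulate_doses, generate_cohort, run_reference_dosimetry
from lutadose.dose import summarize_records

cohort = generate_cohort(CohortConfig(seed=42))
records = run_reference_dosimetry(cohort)

print(f"{len(records)} dose records (one per patient/cycle/region)\n")
summary = summarize_records(records)
print("normalized dose and effective half-life, mean +/- SD by kind and cycle:")
print(summary.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

# cumulative organ doses over the 4 cycles, checked against the proposed
# limits (28 Gy kidneys, 35 Gy salivary glands)
kidneys = records[records["kind"] == "kidney"]
totals = cumulate_doses(kidneys)
print(
    f"\nkidney totals over 4 cycles: median {totals['total_Gy'].median():.1f} Gy, "
    f"range {totals['total_Gy'].min():.1f}-{totals['total_Gy'].max():.1f} Gy, "
    f"{int((totals['flag_limit'] != '').sum())} patient(s) flagged vs 28 Gy limit"
)
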