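"""Generate a paired pre/mid phantom cohort and inspect its ground truth.

Each patient has a pre-treatment image with ellipsoidal lesions (label 1 =
primary tumor, label 2 = nodal), a mid-treatment image where each lesion has
shrunk or vanished, and a "registered" prior mask offset from the truth by a
small simulated registration error.
"""

from gradmapseg import PhantomConfig, generate_cohort, truth_volume_cc

records = generate_cohort(PhantomConfig(), 5, seed=1)

for rec in records:
    pre_p = truth_volume_cc(rec, "pre", 1)
    mid_p = truth_volume_cc(rec, "mid", 1)
    offs = [t.reg_offset for t in rec.truth]
    print(f"{rec.patient_id}: GTVp {pre_p:.4f} cc -> {mid_p:.4f} cc "
          f"({len(rec.truth)} lesions, registration offsets {offs})")

# Volumes are in cubic centimetres; the pre->mid drop reflects the drawn
# shrink factor (0 cc at mid means the lesion disappeared under treatment).
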