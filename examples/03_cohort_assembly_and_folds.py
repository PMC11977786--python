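"""Assemble the doubled two-channel sample set and patient-level folds.

Every patient contributes a pre-treatment and a mid-treatment sample (two
channels each: intensity + gradient map), doubling the cohort. Folds are
assigned per patient; validation keeps only mid-treatment samples, so a
10-patient cohort splits 16 train / 2 validation per fold.
"""

import tempfile

from gradmapseg import (
    PhantomConfig, generate_cohort, assemble_samples, make_folds, split_fold,
    export_trainer_layout,
)

records = generate_cohort(PhantomConfig(), 10, seed=5)
samples = assemble_samples(records, seed=5)
print(f"{len(records)} patients -> {len(samples)} samples")

assignment = make_folds([r.patient_id for r in records], k=5, seed=5)
for fold in range(5):
    train, val = split_fold(samples, assignment, fold)
    leak = {s.patient_id for s in train} & {s.patient_id for s in val}
    print(f"fold {fold}: {len(train)} train / {len(val)} val "
          f"(val phases: {sorted({s.phase for s in val})}, leakage: {len(leak)})")

with tempfile.TemporaryDirectory() as tmp:
    manifest = export_trainer_layout(samples, assignment, tmp)
    print(f"exported {len(manifest)} samples; columns: {list(manifest.columns)}")
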