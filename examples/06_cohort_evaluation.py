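"""Subject-independent fold planning and AHI-stratified metric reporting.

Builds a 5-fold subject-level cross-validation plan for 100 synthetic
subjects (test sets partition the cohort; 15% of the remainder validates),
audits it for leakage, and shows metric computation on a fabricated
prediction set: accuracy, macro-F1 and Cohen's kappa per AHI cohort.
"""

import numpy as np

from sleepmod.evaluation import (
    metrics_from_labels,
    stratify_by_ahi,
    subject_folds,
)
from sleepmod.io_formats import STAGES, SubjectTable
import pandas as pd

rng = np.random.default_rng(0)
subjects = [f"S{i:03d}" for i in range(100)]
table = SubjectTable(pd.DataFrame({
    "subject_id": subjects,
    "ahi": rng.uniform(0, 60, 100).round(1),
}))
cohort_map = {c.subject_id: c.cohort for c in stratify_by_ahi(table)}

plan = subject_folds(subjects, k=5, val_frac=0.15, seed=0, cohorts=cohort_map)
audit = plan.audit()
fold0 = plan.folds[0]
print(f"fold sizes: test={len(fold0['test'])}, val={len(fold0['val'])}, "
      f"train={len(fold0['train'])}")
print(f"leakage audit: {audit}")

# fabricated predictions: 80% correct, errors uniform over other stages
true = rng.integers(0, 5, 2000)
pred = np.where(rng.random(2000) < 0.8, true, rng.integers(0, 5, 2000))
rep = metrics_from_labels([STAGES[i] for i in true], [STAGES[i] for i in pred])
print(f"\nfabricated 80%-correct staging: accuracy={rep.accuracy:.3f} "
      f"macro-F1={rep.macro_f1:.3f} kappa={rep.kappa:.3f}")
print("kappa < accuracy because chance agreement is discounted")
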