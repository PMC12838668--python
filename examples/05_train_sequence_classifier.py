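"""Train the CNN+BiLSTM stager on a tiny synthetic Normal cohort.

Four subjects (two train, one validation, one test) at 60 epochs each —
a few minutes on one CPU.  The script prints the early-stopping history and
held-out metrics; on these cleanly separable synthetic stages the held-out
macro-F1 should be high even at this miniature scale.
"""

import numpy as np

from sleepmod.evaluation import metrics_from_labels
from sleepmod.experiments import desk_scale_config
from sleepmod.pipeline import run_experiment
from sleepmod.synthetic_data import CohortSpec, generate_cohort

spec = CohortSpec(n_subjects_per_cohort=4, epochs_per_subject=60,
                  cohorts=("Normal",), seed=7)
_, data = generate_cohort(spec)
ids = sorted(data)
train_ids, val_ids, test_ids = ids[:2], ids[2:3], ids[3:4]

cfg = desk_scale_config(seed=7)
result = run_experiment(data, train_ids, val_ids, test_ids, cfg, verbose=True)

print(f"\nstopped after epoch {result.history.stopped_epoch} "
      f"({result.history.n_evaluations} validation evaluations)")
t_all, p_all = [], []
for sid in test_ids:
    t_all += result.truths[sid]
    p_all += result.predictions[sid]
rep = metrics_from_labels(t_all, p_all)
print(f"held-out subject {test_ids[0]}: accuracy={rep.accuracy:.3f} "
      f"macro-F1={rep.macro_f1:.3f} kappa={rep.kappa:.3f}")
print("per-class F1:", np.round(rep.per_class_f1, 3), "(W, N1, N2, N3, R)")
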