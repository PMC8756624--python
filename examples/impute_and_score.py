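"""Impute one incomplete dataset with all eight methods and score each.

A coupled stochastic cohort is amputed under MCAR at a 30% missing
proportion, each method fills the masked cells, and two views are
reported: the fraction of masked cells restored to their true category
(cell accuracy) and the downstream discharge model's sensitivity / AUC /
kappa on the completed data, against the complete-data reference.
"""

import numpy as np

from imputebench import (DEFAULT_DEPENDENCE, METHODS, OUTCOME, TARGET,
                         ImputerConfig, MissingScenario, ampute,
                         compute_metrics, evaluate_scenario,
                         fit_outcome_model, generate_cohort, impute,
                         table2_profile)

cohort = generate_cohort(table2_profile(), mode="stochastic",
                         dependence=DEFAULT_DEPENDENCE, seed=2)
model = fit_outcome_model(cohort.records)
labels = cohort.records[OUTCOME].to_numpy(dtype=int)
reference = compute_metrics(model.probabilities, labels, 0.5)
print("complete-data reference: "
      f"sens={reference.sensitivity:.3f} auc={reference.auc:.3f} "
      f"kappa={reference.kappa:.3f}\n")

incomplete = ampute(cohort, MissingScenario("MCAR", 0.30, 3))
truth = incomplete.original_target.iloc[incomplete.missing_index].to_numpy()
config = ImputerConfig.fast(seed=2)

print(f"{'method':9s} {'cell acc':>8s} {'sens':>6s} {'auc':>6s} {'kappa':>6s}")
for method in METHODS:
    completed = impute(incomplete, method, config)
    filled = completed.records[TARGET].iloc[incomplete.missing_index]
    acc = float(np.mean(filled.to_numpy() == truth))
    result = evaluate_scenario(completed, reference)
    m = result.metrics
    print(f"{method:9s} {acc:8.3f} {m.sensitivity:6.3f} "
          f"{m.auc:6.3f} {m.kappa:6.3f}")

print("\ncell accuracy shows distribution recovery; the metric columns show "
      "what matters\nclinically — whether the completed data changes the "
      "discharge model's decisions.")
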