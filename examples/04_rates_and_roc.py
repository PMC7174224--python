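"""Per-class rates and one-vs-rest ROC/AUC for one classifier.

Runs a nearest-neighbor model on a small synthetic set and derives the
confusion matrix, the TP/FN/PP/FD rate table (TP+FN = 100 and PP+FD = 100
per class by construction) and the per-class AUCs from the pooled
out-of-fold predictions of the first repetition.
"""

import numpy as np

from saffronvision.classify import CvConfig, model_suite, run_cv
from saffronvision.evaluate import class_rates, confusion, roc_auc
from saffronvision.pipeline import RunConfig, build_feature_table
from saffronvision.preprocess import PreprocessParams

config = RunConfig(
    counts={"Pushal": 10, "Negin": 10, "Sargol": 10},
    preprocess=PreprocessParams(min_component_area=64, structuring_radius=2),
    seed=3,
)
table = build_feature_table(config)
X = table.drop(columns=["sample_id", "class"])
y = table["class"].to_numpy()

spec = next(s for s in model_suite() if s.id == "medium_knn")
res = run_cv(X, y, spec, CvConfig(k=5, repetitions=2, seed=3))
print(f"{spec.name}: mean accuracy {res.mean_accuracy:.1f} % "
      f"(SD {res.sd_accuracy:.2f}) over {len(res.accuracies)} repetitions")

cm = confusion(y, res.oof_predictions[0])
print("\nconfusion matrix (rows true, columns predicted):")
print(np.array2string(cm.counts), "classes:", cm.classes)

rates = class_rates(cm).as_frame()
print("\nper-class rates (percent; TP+FN = 100, PP+FD = 100):")
print(rates.round(1).to_string())

print("\none-vs-rest AUC per class (0.5 = no discrimination, 1 = perfect):")
col = {c: j for j, c in enumerate(res.classes)}
for c in cm.classes:
    _, auc = roc_auc(res.oof_scores[0][:, col[c]], y, c)
    print(f"  {c:<8s} {auc:.3f}")
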