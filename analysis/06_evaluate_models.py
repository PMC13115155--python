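"""Evaluate the classifier by LOOCV and summarize with the composite score.

Output: results/evaluation.json, results/loocv_predictions.csv.
"""

import json

import numpy as np
import pandas as pd

from saucelife import models

if __name__ == "__main__":
    table = pd.read_csv("results/features.csv")
    fits = json.load(open("results/fits.json"))
    res = models.loocv(table["time_days"], table["HSV_S_mean"], table["label"])
    pd.DataFrame(
        {
            "sample_id": table["sample_id"],
            "label": table["label"],
            "oof_probability": res.probabilities,
            "predicted_label": res.predicted_labels,
        }
    ).to_csv("results/loocv_predictions.csv", index=False)
    r2 = float(np.clip(fits["quadratic"]["r2"], 0.0, 1.0))
    composite = models.ccc([r2, res.accuracy, res.auc], [0.68, 0.25, 0.25])
    summary = {
        "loocv": {"n_folds": res.n_folds, "accuracy": res.accuracy, "auc": res.auc},
        "ccc": {"sub_scores": [r2, res.accuracy, res.auc],
                "weights": [0.68, 0.25, 0.25], "C": composite},
    }
    with open("results/evaluation.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    n_correct = int(round(res.accuracy * res.n_folds))
    print(f"LOOCV over {res.n_folds} folds: accuracy {100 * res.accuracy:.1f}% "
          f"({n_correct} correct), AUC {res.auc:.3f}")
    print(f"composite confidence score C = {composite:.3f}")
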