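"""Fit the two-stage model: quadratic saturation kinetics + logistic classifier.

Output: results/fits.json.
"""

import json

import numpy as np
import pandas as pd

from saucelife import models

if __name__ == "__main__":
    table = pd.read_csv("results/features.csv")
    t, S, y = table["time_days"], table["HSV_S_mean"], table["label"]
    poly = models.fit_quadratic(t, S)
    logit = models.fit_logistic(t, S, y)
    summary = {
        "quadratic": {
            "beta": list(poly.beta), "r2": poly.r2, "rmse": poly.rmse,
            "p_beta2": poly.p_beta2, "n": poly.n,
        },
        "logistic": {
            "alpha": logit.alpha.tolist(), "se": logit.se.tolist(),
            "log_likelihood": logit.log_likelihood,
            "converged": logit.converged, "separation": logit.separation, "n": logit.n,
        },
    }
    with open("results/fits.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    print(f"quadratic kinetics: R2 = {poly.r2:.3f}, RMSE = {poly.rmse:.2f} "
          f"(curvature p = {poly.p_beta2:.2g})")
    print(f"logistic classifier: alpha = {np.round(logit.alpha, 4).tolist()}")
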