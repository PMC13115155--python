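"""Correlation screening of color features against storage time.

Each feature's Pearson correlation with storage time is computed within
every (storage temperature x acceptability class) group, and features
are ranked by the mean correlation across groups.  The feature that
tracks storage most consistently across conditions — in practice the
mean HSV saturation of the sauce — is the one carried into modeling.

Averaging uses signed r by default (the screening is after the feature
with the strongest consistent *positive* association with time); set
``use_abs=True`` to rank by mean |r| instead.  No significance testing
or multiplicity control is performed here: screening is descriptive.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .colorfeat import FEATURE_NAMES

__all__ = ["pearson", "grouped_correlations", "rank_features"]


def pearson(x, y) -> float:
    """Product-moment correlation; zero-variance input yields 0 with a warning."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("pearson: length mismatch")
    if x.size < 3:
        raise ValueError("pearson: need at least 3 observations")
    dx, dy = x - x.mean(), y - y.mean()
    sxx, syy = np.sum(dx**2), np.sum(dy**2)
    if sxx == 0.0 or syy == 0.0:
        warnings.warn("pearson: zero-variance input, correlation undefined (reported as 0)")
        return 0.0
    return float(np.sum(dx * dy) / np.sqrt(sxx * syy))


def grouped_correlations(
    table: pd.DataFrame, feature_cols: list[str] | None = None
) -> dict[tuple[float, int], pd.DataFrame]:
    """Per-(temperature, class) correlation tables of features vs time.

    Returns one DataFrame (columns feature, r, defined, n) per group
    present in the data; groups with fewer than 3 records are skipped
    with a warning.  Raises if no group is usable.
    """
    cols = list(feature_cols) if feature_cols is not None else [
        c for c in FEATURE_NAMES if c in table.columns
    ]
    if not cols:
        raise ValueError("grouped_correlations: no feature columns found")
    for required in ("temperature_c", "label", "time_days"):
        if required not in table.columns:
            raise ValueError(f"grouped_correlations: missing column {required}")
    out: dict[tuple[float, int], pd.DataFrame] = {}
    for (temp, lab), grp in table.groupby(["temperature_c", "label"], sort=True):
        if len(grp) < 3:
            warnings.warn(
                f"group (temperature {temp}, class {lab}) has n={len(grp)} < 3; skipped"
            )
            continue
        t = grp["time_days"].to_numpy(dtype=float)
        rows = []
        t_const = np.ptp(t) == 0
        for feat in cols:
            v = grp[feat].to_numpy(dtype=float)
            defined = (np.ptp(v) != 0) and not t_const
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = pearson(v, t) if defined else 0.0
            rows.append({"feature": feat, "r": r, "defined": defined, "n": len(grp)})
        out[(float(temp), int(lab))] = pd.DataFrame(rows)
    if not out:
        raise ValueError("grouped_correlations: no group with n >= 3")
    return out


def rank_features(tables, use_abs: bool = False) -> pd.DataFrame:
    """Rank features by mean per-group correlation with time.

    Undefined (zero-variance) group entries are excluded from the mean; a
    feature undefined in every group gets mean_r = NaN, sorts last, and
    is flagged.  Ties in mean_r break alphabetically by feature name.
    """
    tables = list(tables.values()) if isinstance(tables, dict) else list(tables)
    if not tables:
        raise ValueError("rank_features: need at least one correlation table")
    cat = pd.concat(tables, ignore_index=True)
    if use_abs:
        cat = cat.assign(r=cat["r"].abs())
    rows = []
    for feat, grp in cat.groupby("feature", sort=True):
        valid = grp[grp["defined"]]
        rows.append(
            {
                "feature": feat,
                "mean_r": valid["r"].mean() if len(valid) else np.nan,
                "n_groups": int(len(valid)),
                "undefined_everywhere": bool(len(valid) == 0),
            }
        )
    ranking = pd.DataFrame(rows).sort_values(
        ["mean_r", "feature"], ascending=[False, True], na_position="last"
    )
    return ranking.reset_index(drop=True)
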