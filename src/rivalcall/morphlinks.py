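"""Linear correlations between call features, morphometrics and dominance.

Each acoustic parameter (per-male mean over his calls) is regressed on each
of the four morphometric measures (vertical height, body length, body
perimeter, head perimeter) and on the final seasonal Elo score; the Elo
score is additionally regressed on the four morph measures.  Fits are
ordinary least squares and report the adjusted R-squared

    adj R2 = 1 - (1 - R2) (n - 1) / (n - 2)

which can legitimately go negative for uninformative predictors at small n.
No multiple-testing correction is applied to the headline table; a
Benjamini-Hochberg adjusted column is emitted alongside, clearly marked as
an addition, for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

from .errors import DegeneratePredictorError, ValidationError

MORPH_MEASURES = [
    "vertical_height_m",
    "body_length_m",
    "body_perimeter_m",
    "head_perimeter_m",
]

ACOUSTIC_PARAMS = [
    "duration_s",
    "pulse_rate_hz",
    "n_pulses",
    "f_max_hz",
    "centroid_hz",
    "q25_hz",
    "q50_hz",
    "q75_hz",
    "bw12_hz",
    "db_peak",
]


@dataclass(frozen=True)
class LineFit:
    slope: float
    intercept: float
    r2_adjusted: float
    p_value: float
    n: int


def fit_line(x, y) -> LineFit:
    """OLS fit of y on x with adjusted R-squared and two-sided slope p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DegeneratePredictorError("x and y lengths differ")
    n = x.size
    if n < 3:
        raise DegeneratePredictorError(f"need n >= 3 points, got {n}")
    if np.ptp(x) == 0:
        raise DegeneratePredictorError("constant predictor")
    res = spstats.linregress(x, y)
    r2 = res.rvalue**2
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return LineFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2_adjusted=float(r2_adj),
        p_value=float(res.pvalue),
        n=n,
    )


def aggregate_features(call_features: pd.DataFrame) -> pd.DataFrame:
    """Per-male mean of each call feature (one row per male)."""
    cols = [c for c in ACOUSTIC_PARAMS if c in call_features.columns]
    return call_features.groupby("male_id", as_index=False)[cols].mean()


def correlation_table(
    features: pd.DataFrame,
    morph: pd.DataFrame,
    elo: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All (acoustic x {morph, Elo}) and (Elo x morph) line fits, one row each.

    ``features`` holds per-male mean call features, ``morph`` the
    morphometric table, ``elo`` the final seasonal scores
    (columns ``male_id``, ``elo_final``); males must match across tables.
    """
    for name, df in (("features", features), ("morph", morph), ("elo", elo)):
        if "male_id" not in df.columns:
            raise ValidationError(f"{name} table lacks a male_id column")
    merged = features.merge(morph, on="male_id", how="outer", indicator=True)
    bad = merged.loc[merged["_merge"] != "both", "male_id"].tolist()
    if bad:
        raise ValidationError(f"unmatched male_ids between features and morph: {bad}")
    merged = merged.drop(columns="_merge").merge(elo, on="male_id", how="outer", indicator=True)
    bad = merged.loc[merged["_merge"] != "both", "male_id"].tolist()
    if bad:
        raise ValidationError(f"unmatched male_ids against the Elo table: {bad}")
    merged = merged.drop(columns="_merge")

    # keep only measures actually available (e.g. db_peak is absent when no
    # call was calibrated)
    acoustic_cols = [
        c
        for c in ACOUSTIC_PARAMS
        if c in merged.columns and merged[c].notna().sum() >= 3
    ]
    predictors = [c for c in MORPH_MEASURES if c in merged.columns] + ["elo_final"]
    rows = []
    for response in acoustic_cols:
        for predictor in predictors:
            sub = merged[[predictor, response]].dropna()
            fit = fit_line(sub[predictor], sub[response])
            rows.append((response, predictor, fit))
    for predictor in predictors[:-1]:  # Elo against each morph measure
        sub = merged[[predictor, "elo_final"]].dropna()
        fit = fit_line(sub[predictor], sub["elo_final"])
        rows.append(("elo_final", predictor, fit))

    table = pd.DataFrame(
        [
            {
                "response": response,
                "predictor": predictor,
                "n": fit.n,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r2_adjusted": fit.r2_adjusted,
                "p_value": fit.p_value,
            }
            for response, predictor, fit in rows
        ]
    )
    table["significant"] = table["p_value"] < alpha
    # Benjamini-Hochberg column: an addition to the uncorrected presentation
    table["p_bh"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return table
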