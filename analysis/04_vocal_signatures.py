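"""Test whether calls carry individual signatures, and whether they are stable.

Runs the cross-validated permuted discriminant analysis on the year-1 calls
(100 random 2/3-1/3 splits; 500 label permutations) and the two-year
stability analysis in the (pulse rate, centroid) plane.  Writes the pDFA
summary, the confusion matrix, per-individual distance means and distance
densities.
"""

import json
from pathlib import Path

import pandas as pd

from rivalcall import signature

SEED = 37
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    fpath = RESULTS / "features.csv"
    if not fpath.exists():
        raise SystemExit("run analysis/03_extract_features.py first")
    features = pd.read_csv(fpath)
    year1 = features[features["year"] == 1]

    result = signature.pdfa(
        year1, n_iterations=100, n_permutations=500, seed=SEED
    )
    with open(RESULTS / "pdfa.json", "w") as fh:
        json.dump(result.summary(), fh, indent=2)
    result.confusion.to_csv(RESULTS / "confusion.csv")
    print(
        f"pDFA: {result.mean_correct:.1f} % correct (chance {result.chance:.1f} %), "
        f"p = {result.p_value:.4g} ({result.n_permutations} permutations)"
    )

    stability = signature.stability_distances(features, group_col="year")
    stability.per_individual.to_csv(RESULTS / "stability.csv", index=False)
    stability.density_frame().to_csv(RESULTS / "stability_density.csv", index=False)
    per = stability.per_individual
    print(
        "stability: mean within-year distance "
        f"{per['within_mean'].mean():.3f}, between-years {per['between_mean'].mean():.3f}, "
        f"other-individual {per['across_mean'].mean():.3f} "
        f"(matched-pairs p = {stability.p_value:.3f})"
    )
    print(f"wrote pdfa.json, confusion.csv, stability.csv, stability_density.csv")


if __name__ == "__main__":
    main()
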