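"""Individual vocal-identity analysis.

Two questions are answered here.  First, do calls carry an individual
signature strong enough to assign them to their emitter?  That is tested
with a cross-validated, permuted discriminant function analysis (pDFA):
linear discriminant functions are fitted on a stratified two-thirds of each
male's calls and evaluated on the held-out third, the effect size (mean %
correctly classified over random splits) is compared to a null distribution
obtained by re-running the whole procedure on label-permuted data, and a
confusion matrix of conditional probabilities p(classified as j | emitted by
i) is aggregated over held-out classifications.

Second, is the signature stable over years and across social contexts?
Calls are placed in the two-dimensional space of the two most individually
distinctive parameters (pulse rate, spectral centroid), z-scored against a
reference pool, and Euclidean distances are compared within versus between
group levels per individual with a matched-pairs Wilcoxon test.

The permutation p-value uses the (b + 1) / (m + 1) estimator with ties
counted as exceedances, the standard valid form; it differs from the raw
proportion by at most 1/(m + 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .errors import InvalidConfigError

logger = logging.getLogger(__name__)

#: the nine call measures entering the discriminant analysis
DFA_FEATURES = [
    "duration_s",
    "n_pulses",
    "pulse_rate_hz",
    "f_max_hz",
    "centroid_hz",
    "q25_hz",
    "q50_hz",
    "q75_hz",
    "bw12_hz",
]

#: the two parameters defining the signature plane for stability analysis
STABILITY_FEATURES = ["pulse_rate_hz", "centroid_hz"]


@dataclass
class PDFAResult:
    """Cross-validated classification outcome, optionally with permutation p."""

    mean_correct: float
    per_iteration: np.ndarray
    confusion: pd.DataFrame
    chance: float
    n_iterations: int
    p_value: float | None = None
    n_permutations: int | None = None

    def summary(self) -> dict:
        out = {
            "mean_correct_pct": float(self.mean_correct),
            "chance_pct": float(self.chance),
            "n_iterations": int(self.n_iterations),
        }
        if self.p_value is not None:
            out["p_value"] = float(self.p_value)
            out["n_permutations"] = int(self.n_permutations)
        return out


def _check_features(X: np.ndarray, labels: np.ndarray, min_calls: int = 3) -> None:
    if X.ndim != 2 or X.shape[0] != labels.size:
        raise InvalidConfigError("feature matrix and labels are misaligned")
    if np.any(~np.isfinite(X)):
        raise InvalidConfigError("feature matrix contains missing/non-finite cells")
    unique, counts = np.unique(labels, return_counts=True)
    if unique.size < 2:
        raise InvalidConfigError("need at least 2 individuals")
    low = unique[counts < min_calls]
    if low.size:
        raise InvalidConfigError(
            f"each individual needs >= {min_calls} calls; too few for {list(low)}"
        )


def _fit_lda(X_train: np.ndarray, y_train: np.ndarray) -> LinearDiscriminantAnalysis:
    """Pooled-covariance linear discriminant, with a shrinkage fallback when
    the pooled covariance is ill-conditioned."""
    try:
        lda = LinearDiscriminantAnalysis(solver="svd")
        lda.fit(X_train, y_train)
        return lda
    except np.linalg.LinAlgError:
        logger.info("singular within-class covariance; refitting with small shrinkage")
        lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage=1e-6)
        lda.fit(X_train, y_train)
        return lda


def _split_indices(
    labels: np.ndarray, classes: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random split: ceil(2n/3) training calls per individual.

    Rounding the training size up guarantees every individual keeps at least
    one validation call for class sizes >= 3.
    """
    train, test = [], []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        perm = rng.permutation(idx)
        n_train = math.ceil(2 * idx.size / 3)
        if n_train == idx.size:
            n_train = idx.size - 1
        train.append(perm[:n_train])
        test.append(perm[n_train:])
    return np.concatenate(train), np.concatenate(test)


def _one_crossval(
    X: np.ndarray,
    labels: np.ndarray,
    classes: np.ndarray,
    rng: np.random.Generator,
    confusion_counts: np.ndarray | None = None,
    class_index: dict | None = None,
) -> float:
    train_idx, test_idx = _split_indices(labels, classes, rng)
    lda = _fit_lda(X[train_idx], labels[train_idx])
    predicted = lda.predict(X[test_idx])
    truth = labels[test_idx]
    if confusion_counts is not None:
        for t, p in zip(truth, predicted):
            confusion_counts[class_index[t], class_index[p]] += 1
    return 100.0 * float(np.mean(predicted == truth))


def _as_matrix(features, labels=None) -> tuple[np.ndarray, np.ndarray]:
    """Accept (DataFrame with male_id) or (array, labels)."""
    if isinstance(features, pd.DataFrame):
        if labels is None:
            labels = features["male_id"].to_numpy()
        cols = [c for c in DFA_FEATURES if c in features.columns]
        X = features[cols].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        labels = np.asarray(labels)
    return X, np.asarray(labels)


def crossval_dfa(
    features,
    labels=None,
    n_iterations: int = 100,
    seed: int | None = 0,
    zscore: bool = True,
) -> PDFAResult:
    """Cross-validated linear discriminant classification of callers.

    ``features`` may be a tidy DataFrame carrying a ``male_id`` column and the
    nine measure columns, or a plain array with ``labels`` given separately.
    Per iteration a stratified random 2/3 split is fitted and the held-out
    third classified; ``mean_correct`` is the average held-out accuracy (%),
    and the confusion matrix is aggregated over all held-out classifications
    and row-normalised to conditional probabilities.
    """
    X, y = _as_matrix(features, labels)
    _check_features(X, y)
    if zscore:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    classes = np.unique(y)
    class_index = {c: i for i, c in enumerate(classes)}
    rng = np.random.default_rng(seed)
    counts = np.zeros((classes.size, classes.size))
    per_iter = np.array(
        [
            _one_crossval(X, y, classes, rng, counts, class_index)
            for _ in range(n_iterations)
        ]
    )
    row_sums = counts.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    confusion = pd.DataFrame(counts / row_sums, index=classes, columns=classes)
    return PDFAResult(
        mean_correct=float(per_iter.mean()),
        per_iteration=per_iter,
        confusion=confusion,
        chance=100.0 / classes.size,
        n_iterations=n_iterations,
    )


def pdfa_pvalue(
    features,
    labels=None,
    n_permutations: int = 1000,
    iters_per_perm: int = 1,
    n_iterations: int = 100,
    seed: int | None = 0,
    observed: float | None = None,
) -> float:
    """Permutation p-value for the cross-validated effect size.

    Labels are shuffled across calls (call-level exchangeability), the full
    train/validate procedure re-run per permutation (``iters_per_perm``
    random splits each), and p computed as (b + 1) / (m + 1) where b counts
    permuted effect sizes >= the observed one.  The minimum attainable p is
    therefore 1 / (m + 1).

    Validity requires the observed statistic to be computed by exactly the
    same procedure as the permuted ones, so by default the observed effect is
    recomputed here as a mean over ``iters_per_perm`` random splits (not the
    ``n_iterations``-averaged effect size, whose smaller Monte-Carlo variance
    would bias the comparison).  Pass ``observed`` only if it was produced by
    a matching procedure.
    """
    if n_permutations < 1:
        raise InvalidConfigError("n_permutations must be >= 1")
    X, y = _as_matrix(features, labels)
    _check_features(X, y)
    rng = np.random.default_rng(seed)
    classes_obs = np.unique(y)
    if observed is None:
        observed = float(
            np.mean(
                [_one_crossval(X, y, classes_obs, rng) for _ in range(iters_per_perm)]
            )
        )
    classes = np.unique(y)
    exceed = 0
    for _ in range(n_permutations):
        y_perm = rng.permutation(y)
        effects = [
            _one_crossval(X, y_perm, classes, rng) for _ in range(iters_per_perm)
        ]
        if float(np.mean(effects)) >= observed:
            exceed += 1
    return (exceed + 1) / (n_permutations + 1)


def pdfa(
    features,
    labels=None,
    n_iterations: int = 100,
    n_permutations: int = 1000,
    iters_per_perm: int = 1,
    seed: int | None = 0,
) -> PDFAResult:
    """Convenience wrapper: cross-validation plus permutation significance.

    ``mean_correct`` is the ``n_iterations``-averaged effect size; the
    p-value is computed with an observed statistic recomputed over
    ``iters_per_perm`` splits so that it is exchangeable with the permuted
    statistics (see :func:`pdfa_pvalue`).
    """
    rng = np.random.default_rng(seed)
    result = crossval_dfa(
        features, labels, n_iterations=n_iterations, seed=rng.integers(2**31)
    )
    result.p_value = pdfa_pvalue(
        features,
        labels,
        n_permutations=n_permutations,
        iters_per_perm=iters_per_perm,
        seed=rng.integers(2**31),
    )
    result.n_permutations = n_permutations
    return result


# ---------------------------------------------------------------------------
# signature stability
# ---------------------------------------------------------------------------


@dataclass
class StabilityResult:
    """Within- versus between-group signature distances in the z-scored plane."""

    per_individual: pd.DataFrame
    within_distances: np.ndarray
    between_distances: np.ndarray
    across_individual_distances: np.ndarray
    statistic: float
    p_value: float
    reference_level: object
    excluded: list

    def density_frame(self, n_points: int = 128) -> pd.DataFrame:
        """Gaussian-KDE summaries of the three distance categories."""
        frames = []
        for name, values in (
            ("within", self.within_distances),
            ("between", self.between_distances),
            ("across_individuals", self.across_individual_distances),
        ):
            if values.size < 2 or np.ptp(values) == 0:
                continue
            kde = spstats.gaussian_kde(values)
            grid = np.linspace(0.0, float(values.max()) * 1.1, n_points)
            frames.append(
                pd.DataFrame({"category": name, "distance": grid, "density": kde(grid)})
            )
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["category", "distance", "density"]
        )


def _pairwise(a: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """Euclidean distances: all unordered pairs within ``a``, or all cross
    pairs between ``a`` and ``b``."""
    if b is None:
        if a.shape[0] < 2:
            return np.array([])
        diffs = a[:, None, :] - a[None, :, :]
        d = np.sqrt((diffs**2).sum(-1))
        iu = np.triu_indices(a.shape[0], k=1)
        return d[iu]
    diffs = a[:, None, :] - b[None, :, :]
    return np.sqrt((diffs**2).sum(-1)).ravel()


def stability_distances(
    features: pd.DataFrame,
    group_col: str,
    male_col: str = "male_id",
    value_cols: tuple[str, str] = ("pulse_rate_hz", "centroid_hz"),
    reference_level=None,
) -> StabilityResult:
    """Per-individual signature stability across two group levels.

    ``group_col`` is typically a year or a social context.  Z-scores use the
    mean/s.d. of the reference-level pool (default: the lowest sorted level)
    and are applied to all calls.  Three distance categories are produced:
    within the reference level per individual, between levels per individual,
    and between each individual's reference calls and all other individuals'
    reference calls.  The within/between per-individual means are compared
    with a matched-pairs Wilcoxon test.
    """
    levels = sorted(features[group_col].dropna().unique())
    if len(levels) != 2:
        raise InvalidConfigError(
            f"stability analysis needs exactly 2 levels of {group_col!r}, got {levels}"
        )
    if reference_level is None:
        reference_level = levels[0]
    other_level = [lv for lv in levels if lv != reference_level][0]

    ref_pool = features.loc[features[group_col] == reference_level, list(value_cols)]
    mu = ref_pool.mean().to_numpy()
    sd = ref_pool.std(ddof=0).to_numpy()
    sd[sd == 0] = 1.0

    def z(df: pd.DataFrame) -> np.ndarray:
        return (df[list(value_cols)].to_numpy(dtype=float) - mu) / sd

    rows = []
    excluded = []
    within_all, between_all, across_all = [], [], []
    males = sorted(features[male_col].unique())
    ref_calls = {
        m: z(features[(features[male_col] == m) & (features[group_col] == reference_level)])
        for m in males
    }
    for male in males:
        a = ref_calls[male]
        b = z(features[(features[male_col] == male) & (features[group_col] == other_level)])
        if a.shape[0] < 2 or b.shape[0] < 2:
            excluded.append(male)
            logger.info("excluding %s: fewer than 2 calls in a level", male)
            continue
        within = _pairwise(a)
        between = _pairwise(a, b)
        others = np.vstack([ref_calls[m] for m in males if m != male and ref_calls[m].size])
        across = _pairwise(a, others)
        within_all.append(within)
        between_all.append(between)
        across_all.append(across)
        rows.append(
            {
                male_col: male,
                "within_mean": float(within.mean()),
                "between_mean": float(between.mean()),
                "across_mean": float(across.mean()),
            }
        )
    per_individual = pd.DataFrame(rows)
    if len(per_individual) < 2:
        raise InvalidConfigError("fewer than 2 individuals usable for stability analysis")
    diffs = per_individual["within_mean"] - per_individual["between_mean"]
    if np.allclose(diffs, 0):
        statistic, p_value = 0.0, 1.0
    else:
        statistic, p_value = spstats.wilcoxon(
            per_individual["within_mean"], per_individual["between_mean"]
        )
    return StabilityResult(
        per_individual=per_individual,
        within_distances=np.concatenate(within_all) if within_all else np.array([]),
        between_distances=np.concatenate(between_all) if between_all else np.array([]),
        across_individual_distances=np.concatenate(across_all) if across_all else np.array([]),
        statistic=float(statistic),
        p_value=float(p_value),
        reference_level=reference_level,
        excluded=excluded,
    )
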