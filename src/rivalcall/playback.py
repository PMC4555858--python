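"""Playback-stimulus construction and behavioural response scoring.

Stimulus side: natural playback series concatenate three different calls
separated by 3 s of silence; modified-call series use two repetitions of a
single call.  Size-cue manipulations operate directly on a natural call:

* ``modify_pulse_rate``  keeps every pulse verbatim and rescales the silent
  intervals so the re-measured rate hits the target (1 / 1.7 / 3 Hz mimic
  small / medium / large males);
* ``modify_pulse_count`` deletes pulses from the end or appends copies of
  the final pulse (7 / 14 / 21 pulses), re-spacing uniformly so the measured
  rate is preserved;
* ``shift_q25``          reshapes the spectral envelope with a smooth
  frequency tilt, closed-loop tuned until the measured first energy quartile
  hits the target (536 Hz low / 804 Hz high), leaving temporal structure
  intact.

All series are rendered at a nominal source level of 116 dB peak re 20 uPa
at 1 m, assuming the supplied calibration maps digital full scale to
pascals at 1 m.

Response side: the six behavioural measures per trial are collapsed by a
PCA on their correlation matrix; components with eigenvalue > 1 are
retained and varimax-rotated, and each component's sign is fixed so that an
aggressive response (calls given, approach) scores negative.  Paired
conditions are compared with matched-pairs Wilcoxon tests (exact null
distribution up to n = 25); the distance experiment uses a within-male
permutation test of a linear distance trend, a deliberately simple
substitute for a mixed-model analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.multivariate.factor_rotation import rotate_factors

from . import acoustics
from .acoustics import AnalysisConfig, CallWaveform, DEFAULT_CONFIG, P_REF
from .errors import InfeasibleTargetError, InvalidConfigError

logger = logging.getLogger(__name__)

STIMULUS_KINDS = ("natural_series", "mod_pulse_rate", "mod_pulse_count", "mod_q25")

#: silent gap between renditions in a playback series (s)
DEFAULT_GAP_S = 3.0
#: nominal broadcast level, dB peak re 20 uPa at 1 m
DEFAULT_LEVEL_DB = 116.0

#: the size-cue targets: pulse rate (Hz), pulse count, Q25 (Hz) for
#: small / medium / large male mimics
PULSE_RATE_TARGETS = {"small": 1.0, "medium": 1.7, "large": 3.0}
PULSE_COUNT_TARGETS = {"small": 7, "medium": 14, "large": 21}
Q25_TARGETS = {"low": 536.0, "high": 804.0}

#: chunk margin around each detected pulse when cutting it out (s)
PULSE_MARGIN_S = 0.010


@dataclass(frozen=True)
class StimulusSpec:
    """One playback stimulus configuration."""

    kind: str
    target_pulse_rate: float | None = None
    target_n_pulses: int | None = None
    target_q25: float | None = None
    repetitions: int = 3
    gap: float = DEFAULT_GAP_S
    level: float = DEFAULT_LEVEL_DB

    def __post_init__(self) -> None:
        if self.kind not in STIMULUS_KINDS:
            raise InvalidConfigError(f"unknown stimulus kind {self.kind!r}")
        if self.repetitions not in (2, 3):
            raise InvalidConfigError("repetitions must be 2 or 3")
        if self.gap <= 0:
            raise InvalidConfigError("gap must be positive")
        needed = {
            "natural_series": (),
            "mod_pulse_rate": ("target_pulse_rate",),
            "mod_pulse_count": ("target_n_pulses",),
            "mod_q25": ("target_q25",),
        }[self.kind]
        for name in ("target_pulse_rate", "target_n_pulses", "target_q25"):
            value = getattr(self, name)
            if name in needed and value is None:
                raise InvalidConfigError(f"{self.kind} requires {name}")
            if name not in needed and value is not None:
                raise InvalidConfigError(f"{self.kind} does not accept {name}")


def seven_signal_configurations() -> list[StimulusSpec]:
    """The seven distinct modified-signal configurations of the size-cue design.

    Three pulse-rate variants at 14 pulses, the small and large pulse-count
    variants at 1.7 Hz (the medium count variant coincides with the medium
    rate variant), and the low/high spectral variants at 1.7 Hz / 14 pulses.
    """
    specs = [
        StimulusSpec(kind="mod_pulse_rate", target_pulse_rate=rate, repetitions=2)
        for rate in PULSE_RATE_TARGETS.values()
    ]
    specs += [
        StimulusSpec(kind="mod_pulse_count", target_n_pulses=count, repetitions=2)
        for count in (PULSE_COUNT_TARGETS["small"], PULSE_COUNT_TARGETS["large"])
    ]
    specs += [
        StimulusSpec(kind="mod_q25", target_q25=q, repetitions=2)
        for q in Q25_TARGETS.values()
    ]
    assert len(set(specs)) == 7
    return specs


# ---------------------------------------------------------------------------
# pulse-level surgery
# ---------------------------------------------------------------------------


@dataclass
class _PulseTrain:
    """Detected pulse chunks of a call, ready for re-assembly."""

    chunks: list[np.ndarray]  # raw samples, pulse plus margins
    up_offsets: list[int]  # up-crossing position within each chunk (samples)
    widths: list[int]  # up-cross .. down-cross width per pulse (samples)
    sample_rate: float


def _segment_pulses(call: CallWaveform, config: AnalysisConfig) -> _PulseTrain:
    """Cut each detected pulse (threshold crossing to crossing, plus a small
    margin) out of the raw waveform."""
    env = acoustics.envelope(call, config)
    onsets = acoustics.detect_pulses(env, config.threshold, config.min_gap)
    if onsets.size == 0:
        raise InfeasibleTargetError("no detectable pulses in the call")
    fs = call.sample_rate
    v = env.values
    above = v >= config.threshold
    margin = int(round(PULSE_MARGIN_S * fs))
    chunks, up_offsets, widths = [], [], []
    onset_idx = np.round(onsets * fs).astype(int)
    for k, i_on in enumerate(onset_idx):
        # down-cross: first sample below threshold after the onset, bounded by
        # the next onset
        stop = onset_idx[k + 1] if k + 1 < onset_idx.size else v.size
        below = np.flatnonzero(~above[i_on:stop])
        i_off = i_on + (below[0] if below.size else stop - i_on)
        lo = max(0, i_on - margin)
        hi = min(call.samples.size, i_off + margin)
        chunks.append(call.samples[lo:hi].copy())
        up_offsets.append(i_on - lo)
        widths.append(i_off - i_on)
    return _PulseTrain(chunks=chunks, up_offsets=up_offsets, widths=widths, sample_rate=fs)


_LEAD_PAD_S = 0.25


def _assemble(train: _PulseTrain, interval_s: float) -> np.ndarray:
    """Rebuild a waveform with pulse up-crossings at a uniform interval.

    Raises when the requested interval would make pulse chunks overlap.
    """
    fs = train.sample_rate
    n = len(train.chunks)
    pad = int(round(_LEAD_PAD_S * fs))
    positions = [pad + int(round(k * interval_s * fs)) for k in range(n)]
    starts = [p - off for p, off in zip(positions, train.up_offsets)]
    ends = [s + c.size for s, c in zip(starts, train.chunks)]
    for k in range(1, n):
        if starts[k] < ends[k - 1]:
            raise InfeasibleTargetError(
                "target would make pulses overlap; rate too high for pulse widths"
            )
    out = np.zeros(ends[-1] + pad)
    for start, chunk in zip(starts, train.chunks):
        out[start : start + chunk.size] = chunk
    return out


def _respaced(
    call: CallWaveform, train: _PulseTrain, rate: float, n_pulses: int
) -> CallWaveform:
    """Interval such that measured duration (first onset to last offset) gives
    ``n_pulses / duration == rate``."""
    if n_pulses < 2:
        # a single pulse has duration equal to its own width; rate is fixed
        return replace(call, samples=_assemble(train, 0.0))
    w_last = train.widths[-1] / train.sample_rate
    interval = (n_pulses / rate - w_last) / (n_pulses - 1)
    if interval <= 0:
        raise InfeasibleTargetError(f"pulse rate {rate} Hz infeasible for these pulses")
    return replace(call, samples=_assemble(train, interval))


def modify_pulse_rate(
    call: CallWaveform, target: float, config: AnalysisConfig = DEFAULT_CONFIG
) -> CallWaveform:
    """Rescale inter-pulse silences so the re-measured pulse rate equals ``target``.

    Pulse waveforms are preserved verbatim and the pulse count is unchanged.
    """
    if target <= 0:
        raise InvalidConfigError("target pulse rate must be positive")
    train = _segment_pulses(call, config)
    return _respaced(call, train, target, len(train.chunks))


def modify_pulse_count(
    call: CallWaveform, target: int, config: AnalysisConfig = DEFAULT_CONFIG
) -> CallWaveform:
    """Delete pulses from the end, or append copies of the final pulse, until
    the count equals ``target``; the measured pulse rate is preserved.

    ``target`` equal to the current count returns the call unchanged
    (bit-identical).
    """
    if target < 1:
        raise InvalidConfigError("target pulse count must be >= 1")
    train = _segment_pulses(call, config)
    env = acoustics.envelope(call, config)
    onsets = acoustics.detect_pulses(env, config.threshold, config.min_gap)
    _, n_now, rate_now = acoustics.temporal_features(onsets, env, config.threshold)
    if target == n_now:
        return replace(call, samples=call.samples.copy())
    if target < n_now:
        train.chunks = train.chunks[:target]
        train.up_offsets = train.up_offsets[:target]
        train.widths = train.widths[:target]
    else:
        for _ in range(target - n_now):
            train.chunks.append(train.chunks[-1].copy())
            train.up_offsets.append(train.up_offsets[-1])
            train.widths.append(train.widths[-1])
    return _respaced(call, train, rate_now, target)


def shift_q25(
    call: CallWaveform,
    target: float,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> CallWaveform:
    """Spectral-envelope tilt, closed-loop tuned so measured Q25 hits ``target``.

    The tilt is a smooth gain ramp across frequency applied in the Fourier
    domain, so pulse timing (and hence all temporal features) is preserved;
    the loop stops once the Welch-measured Q25 of the rhythmic portion is
    within half an FFT bin of the target.
    """
    nyq = call.sample_rate / 2.0
    if not 0 < target < nyq:
        raise InvalidConfigError("Q25 target must lie strictly inside (0, Nyquist)")
    from .synth import tune_q25  # local import avoids a module cycle

    trimmed, onsets, env = acoustics.rhythmic_portion(call, config)
    offset = onsets[0] + acoustics.temporal_features(onsets, env, config.threshold)[0]
    i0 = int(onsets[0] * call.sample_rate)
    i1 = int(np.ceil(offset * call.sample_rate)) + 1
    tuned = tune_q25(call.samples, call.sample_rate, target, config, trim=(i0, i1))
    return replace(call, samples=tuned)


# ---------------------------------------------------------------------------
# series construction
# ---------------------------------------------------------------------------


def build_series(
    calls: list[CallWaveform], spec: StimulusSpec
) -> CallWaveform:
    """Concatenate renditions with silent gaps and render at the spec level.

    Natural series take three distinct calls; modified kinds take a single
    call repeated twice.  The output carries the calibration under which its
    digital peak corresponds to ``spec.level`` dB peak re 20 uPa at 1 m.
    """
    if not calls:
        raise InvalidConfigError("no calls supplied")
    if spec.kind == "natural_series":
        if len(calls) != 3 or spec.repetitions != 3:
            raise InvalidConfigError("a natural series requires 3 distinct calls")
        renditions = list(calls)
    else:
        if len(calls) != 1 or spec.repetitions != 2:
            raise InvalidConfigError(
                f"{spec.kind} requires exactly 1 call repeated twice"
            )
        renditions = [calls[0]] * 2
    fs = renditions[0].sample_rate
    if any(c.sample_rate != fs for c in renditions):
        raise InvalidConfigError("all calls in a series must share a sample rate")
    gap = np.zeros(int(round(spec.gap * fs)))
    pieces: list[np.ndarray] = []
    for i, call in enumerate(renditions):
        if i:
            pieces.append(gap)
        pieces.append(call.samples)
    samples = np.concatenate(pieces)
    peak = np.abs(samples).max()
    if peak <= 0:
        raise InvalidConfigError("silent series cannot be rendered at a target level")
    target_peak_pa = P_REF * 10.0 ** (spec.level / 20.0)
    calibration = renditions[0].calibration
    if calibration is not None:
        samples = samples * (target_peak_pa / (calibration * peak))
    else:
        # peak-normalise and let the sidecar calibration carry the level
        samples = samples / peak
        calibration = target_peak_pa
    return CallWaveform(samples=samples, sample_rate=fs, calibration=calibration)


# ---------------------------------------------------------------------------
# response scoring
# ---------------------------------------------------------------------------

RESPONSE_MEASURES = [
    "latency_orient",
    "latency_posture",
    "latency_vocalize",
    "n_calls",
    "latency_move",
    "distance_moved",
]

#: measures whose loadings define the "aggressive = negative" sign convention
AGGRESSION_MEASURES = ("n_calls", "distance_moved")


@dataclass
class PCScores:
    """Varimax-rotated principal-component summary of response vectors."""

    loadings: pd.DataFrame  # measures x retained components
    variance_explained: np.ndarray  # % of total variance per retained component
    scores: np.ndarray  # trials x retained components
    n_retained: int
    eigenvalues: np.ndarray  # all eigenvalues, descending
    dropped_measures: list


def response_pca(responses: pd.DataFrame) -> PCScores:
    """PCA of the six response measures on their correlation matrix.

    Components with eigenvalue > 1 are retained and varimax-rotated
    (retained components only); rotated components are ordered by explained
    variance.  Each component's sign is fixed so that the aggression-linked
    measures (number of calls, distance moved) load negatively: a negative
    score then means a strong reaction.  Constant measures are dropped with
    a logged notice.
    """
    cols = [c for c in RESPONSE_MEASURES if c in responses.columns]
    if not cols:
        cols = list(responses.columns)
    X = responses[cols].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    dropped = [c for c, s in zip(cols, sd) if s == 0 or not np.isfinite(s)]
    for c in dropped:
        logger.info("dropping constant response measure %r", c)
    keep = [i for i, c in enumerate(cols) if c not in dropped]
    cols = [cols[i] for i in keep]
    X = X[:, keep]
    if X.shape[1] < 2:
        raise InvalidConfigError("need at least 2 non-constant measures for a PCA")
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    corr = np.corrcoef(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    n_retained = max(1, int(np.sum(eigvals > 1.0)))
    lam = eigvals[:n_retained]
    V = eigvecs[:, :n_retained]
    loadings = V * np.sqrt(lam)
    scores = (Z @ V) / np.sqrt(lam)  # unit-variance component scores
    if n_retained > 1:
        loadings, T = rotate_factors(loadings, "varimax")
        scores = scores @ T
    # order rotated components by explained variance
    explained = (loadings**2).sum(axis=0)
    order = np.argsort(explained)[::-1]
    loadings, scores, explained = loadings[:, order], scores[:, order], explained[order]
    # sign convention: aggression-linked measures load negatively
    for j in range(n_retained):
        idx = [cols.index(m) for m in AGGRESSION_MEASURES if m in cols]
        key = loadings[idx, j].sum() if idx else 0.0
        if abs(key) < 1e-10:
            key = -loadings[np.argmax(np.abs(loadings[:, j])), j]
        if key > 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCScores(
        loadings=pd.DataFrame(
            loadings, index=cols, columns=[f"PC{j + 1}" for j in range(n_retained)]
        ),
        variance_explained=100.0 * explained / len(cols),
        scores=scores,
        n_retained=n_retained,
        eigenvalues=eigvals,
        dropped_measures=dropped,
    )


def compare_conditions(scores_a, scores_b) -> tuple[float, float]:
    """Matched-pairs Wilcoxon signed-rank comparison of two paired score sets.

    Exact null distribution when the (non-zero, untied) pair count is <= 25,
    normal approximation with tie correction otherwise.  All-zero
    differences return p = 1 with a logged notice.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size != b.size:
        raise InvalidConfigError("paired score sets must have equal length")
    if a.size < 5:
        raise InvalidConfigError("matched-pairs comparison needs n >= 5")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        logger.info("all paired differences are zero; no evidence of a difference")
        return 0.0, 1.0
    no_ties = np.unique(np.abs(nz)).size == nz.size
    method = "exact" if (nz.size <= 25 and no_ties) else "approx"
    res = spstats.wilcoxon(
        a, b, zero_method="wilcox", alternative="two-sided", method=method,
        correction=False,
    )
    return float(res.statistic), float(res.pvalue)


def alpha_distance_test(
    scores: pd.DataFrame,
    distances: tuple = (40.0, 30.0, 20.0, 10.0),
    n_permutations: int = 1000,
    seed: int | None = 0,
    male_col: str = "male_id",
    distance_col: str = "distance_m",
    score_col: str = "score",
) -> tuple[float, float]:
    """Within-male permutation test of a linear distance trend in PC scores.

    A methodological substitute for a mixed-model analysis of the
    playback-distance design: the statistic is the across-male mean OLS slope
    of score on speaker distance, and its null distribution is built by
    permuting each male's scores across his own distance block.  Males with
    incomplete blocks are excluded with a notice.  p uses the
    (b + 1)/(m + 1) estimator, so its minimum is 1/(n_permutations + 1).
    """
    if n_permutations < 1:
        raise InvalidConfigError("n_permutations must be >= 1")
    wanted = set(distances)
    blocks = []
    for male, grp in scores.groupby(male_col):
        if set(grp[distance_col]) != wanted or len(grp) != len(wanted):
            logger.info("excluding %s: incomplete distance block", male)
            continue
        grp = grp.sort_values(distance_col)
        blocks.append(grp[score_col].to_numpy(dtype=float))
    if not blocks:
        raise InvalidConfigError("no male has a complete distance block")
    x = np.sort(np.asarray(distances, dtype=float))
    xc = x - x.mean()
    denom = (xc**2).sum()

    def statistic(block_scores: list[np.ndarray]) -> float:
        return float(np.mean([(xc * y).sum() / denom for y in block_scores]))

    t_obs = statistic(blocks)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = [rng.permutation(y) for y in blocks]
        if abs(statistic(perm)) >= abs(t_obs):
            exceed += 1
    return t_obs, (exceed + 1) / (n_permutations + 1)
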