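# rivalcall

Rival-assessment analysis for the pulsed threat calls of breeding male
northern elephant seals (*Mirounga angustirostris*) — and, more generally,
for any system where dominance contests, individually distinctive pulsed
vocalisations, and acoustic playback experiments meet.

Breeding male elephant seals hold structured dominance hierarchies almost
entirely through ritualised displays: loud "clap threat" calls of 3–20
broadband pulses repeated at a few Hz.  Working out *what* those calls
transmit — honest cues to body size, or learned individual signatures —
requires a chain of quantitative steps.  This package implements that chain
as a tested, reusable library plus a set of narrative analysis drivers, all
exercised end-to-end on a synthetic colony generator so every stage is
verifiable without field data:

| module | what it does |
| --- | --- |
| `rivalcall.synth`     | synthetic colonies (latent-strength contest seasons), pulsed calls with per-male acoustic signatures, paired playback-response vectors |
| `rivalcall.dominance` | Elo rating of dyadic contests; dyad-asymmetry and vocalisation tallies |
| `rivalcall.acoustics` | temporal (duration, pulse count, pulse rate) and spectral (F_max, centroid, Q25/Q50/Q75, −12 dB bandwidth, dB_peak) call measures |
| `rivalcall.signature` | cross-validated permuted discriminant function analysis (pDFA) of caller identity; two-year / cross-context signature stability distances |
| `rivalcall.morphlinks`| linear correlation tables linking call features, morphometrics and dominance |
| `rivalcall.playback`  | size-cue stimulus modification (pulse rate, pulse count, Q25), playback-series rendering at calibrated level, varimax-PCA response scoring, matched-pairs tests |
| `rivalcall.io` / `rivalcall.pipeline` / `rivalcall.cli` | CSV/WAV I/O, the one-seed end-to-end pipeline, and a `rivalcall` command-line front end |

## The statistics at the core

**Elo rating.**  Every male starts the season at 1000 points.  After each
decided contest the winner's rating moves by `K·(1−E_a)` and the loser's by
`−K·(1−E_a)`, where the expected score is

    E_a = 1 / (1 + 10^((R_loser − R_winner)/400))

The update is zero-sum, so the colony-wide total is invariant — a property
the tests assert exactly.

**pDFA.**  Linear discriminant functions are fitted on a stratified random
two-thirds of each male's calls (nine temporal + spectral measures) and the
held-out third is classified; the effect size is the mean held-out accuracy
over 100 random splits, with a confusion matrix of conditional
probabilities p(classified j | emitted by i).  Significance comes from
re-running the same train/validate procedure on label-permuted data:
p = (b+1)/(m+1), where b counts permuted effects at least as large as the
observed one.

**Response scoring.**  Six behavioural measures per playback trial
(latencies to orient / change posture / vocalise / move, number of calls,
distance moved) are collapsed by a PCA on their correlation matrix;
components with eigenvalue > 1 are retained and varimax-rotated, signed so
that a negative score means a strong aggressive response.  Paired playback
conditions are compared with matched-pairs Wilcoxon tests (exact null
distribution up to n = 25).

## Worked example

```python
import numpy as np
from rivalcall import acoustics, dominance, playback, synth

# a season of contests under a known hierarchy, scored by Elo
config = synth.ColonyConfig(
    n_males=20, strength=tuple(np.linspace(0, 6, 20)),
    n_interactions=2000, steepness=1.0, seed=42,
)
table = dominance.score_season(synth.simulate_season(config))
print(round(dominance.rating_sum(table), 3))        # 20000.0  (zero-sum)

# a jitter-free 'average male' call, measured and size-modified
sig = synth.CallSignature(male_id="AVG", pulse_rate=1.7, n_pulses=14,
                          centroid_target=1700.0, q25_target=643.0, jitter=0.0)
call = synth.simulate_call(sig, sample_rate=48000.0, seed=11)
f = acoustics.extract_features(call)
print(f.n_pulses, round(f.pulse_rate, 3), round(f.q25, 1))  # 14 1.7 644.5

large = playback.modify_pulse_rate(call, 3.0)       # 'large male' variant
print(round(acoustics.extract_features(large).pulse_rate, 3))  # 3.0
```

The numbers shown are what the code prints: the extractor recovers the
generator's pulse count exactly, the pulse rate within 1 %, and the first
spectral energy quartile within one FFT bin (11.7 Hz at 48 kHz with
4096-point spectra); the pulse-rate modification re-measures at its 3 Hz
target.

The full analysis, from colony simulation through playback scoring, runs as
numbered drivers:

```sh
python analysis/01_simulate_colony.py     # season ledger + tallies
python analysis/02_score_dominance.py     # Elo ratings and trajectories
python analysis/03_extract_features.py    # two seasons of measured calls
python analysis/04_vocal_signatures.py    # pDFA + stability distances
python analysis/05_morph_correlations.py  # feature/morphometry/Elo table
python analysis/06_build_stimuli.py       # the 7 modified playback signals
python analysis/07_score_responses.py     # PCA scores + Wilcoxon tests
```

Each driver prints what it found and writes its tables under `results/`.
The same chain is available as one command: `rivalcall run --seed 7 --out out/`.

## Design notes

See `docs/methods.md` for the generative model behind the synthetic data,
the measurement conventions (notably pulse rate = n_pulses/duration), the
parameter defaults and their rationale, and known limitations.
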