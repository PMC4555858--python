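"""End-to-end orchestration of a full synthetic-season analysis.

The pipeline runs the whole chain on generated data: simulate a season of
contests, score dominance, synthesize each male's calls, extract acoustic
features, test for individual signatures (pDFA), check signature stability
across two simulated years, correlate features with morphometrics and
dominance, build the playback stimulus set, and score simulated behavioural
responses.  Everything is driven by one seed; a manifest records the seed,
the parameter hash and every output file so a run can be reproduced
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import acoustics, dominance, io, morphlinks, playback, signature, synth
from .errors import InvalidConfigError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of a full synthetic-season run."""

    seed: int = 0
    n_males: int = 12
    n_interactions: int = 800
    strength_sd: float = 1.5
    steepness: float = 8.0
    elo_k: float = 100.0
    elo_initial: float = 1000.0
    calls_per_male: int = 5
    sample_rate: float = 24000.0
    jitter: float = 0.05
    pdfa_iterations: int = 50
    pdfa_permutations: int = 100
    n_playback_trials: int = 10
    response_effect: float = 1.5
    response_noise_sd: float = 1.0
    write_wavs: bool = False

    def __post_init__(self) -> None:
        if self.n_males < 2:
            raise InvalidConfigError("n_males must be >= 2")
        if self.seed is None:
            raise InvalidConfigError("a seed is mandatory")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def parameter_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _simulate_feature_table(
    signatures, config: RunConfig, rng: np.random.Generator, years=(1, 2)
) -> pd.DataFrame:
    rows = []
    for year in years:
        for sig in signatures:
            for _ in range(config.calls_per_male):
                call = synth.simulate_call(
                    sig, sample_rate=config.sample_rate, seed=int(rng.integers(2**31))
                )
                call.male_id, call.year = sig.male_id, year
                feats = acoustics.extract_features(call)
                rows.append(feats.as_dict())
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage in order, writing tables under ``outdir``.

    Returns a report dict (also written as ``manifest.json``) with the seed,
    parameter hash and headline numbers of each stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    report: dict = {"seed": config.seed, "parameter_hash": config.parameter_hash()}
    outputs: list[str] = []

    # --- season + dominance -------------------------------------------------
    strengths = tuple(rng.normal(0.0, config.strength_sd, size=config.n_males))
    colony = synth.ColonyConfig(
        n_males=config.n_males,
        strength=strengths,
        n_interactions=config.n_interactions,
        steepness=config.steepness,
        seed=int(rng.integers(2**31)),
    )
    records = synth.simulate_season(colony)
    io.write_interaction_log(records, outdir / "interactions.csv")
    outputs.append("interactions.csv")
    table = dominance.score_season(records, K=config.elo_k, initial=config.elo_initial)
    io.write_elo_csv(table, outdir / "elo.csv")
    outputs.append("elo.csv")
    net = dominance.summarize_network(records)
    report["dominance"] = {
        "n_interactions": net.n_interactions,
        "asymmetric_fraction": net.asymmetric_fraction,
        "rating_sum_check": dominance.rating_sum(table),
    }

    # --- calls + features ---------------------------------------------------
    signatures = synth.simulate_colony_signatures(
        config.n_males, seed=int(rng.integers(2**31)), jitter=config.jitter
    )
    features = _simulate_feature_table(signatures, config, rng)
    features.to_csv(outdir / "features.csv", index=False)
    outputs.append("features.csv")

    # --- signatures ---------------------------------------------------------
    year1 = features[features["year"] == 1]
    pdfa_result = signature.pdfa(
        year1,
        n_iterations=config.pdfa_iterations,
        n_permutations=config.pdfa_permutations,
        seed=int(rng.integers(2**31)),
    )
    with open(outdir / "pdfa.json", "w") as fh:
        json.dump(pdfa_result.summary(), fh, indent=2)
    pdfa_result.confusion.to_csv(outdir / "confusion.csv")
    outputs += ["pdfa.json", "confusion.csv"]
    report["pdfa"] = pdfa_result.summary()

    stability = signature.stability_distances(features, group_col="year")
    stability.per_individual.to_csv(outdir / "stability.csv", index=False)
    outputs.append("stability.csv")
    report["stability"] = {
        "statistic": stability.statistic,
        "p_value": stability.p_value,
        "n_individuals": len(stability.per_individual),
    }

    # --- morphometrics ------------------------------------------------------
    per_male = morphlinks.aggregate_features(features[features["year"] == 1])
    morph = synth.simulate_morphometrics(
        dict(zip(per_male["male_id"], per_male["pulse_rate_hz"])),
        seed=int(rng.integers(2**31)),
    )
    corr = morphlinks.correlation_table(per_male, morph, table.to_frame())
    corr.to_csv(outdir / "correlations.csv", index=False)
    outputs.append("correlations.csv")
    report["correlations"] = {
        "n_fits": len(corr),
        "n_significant": int(corr["significant"].sum()),
    }

    # --- stimuli ------------------------------------------------------------
    base_sig = synth.CallSignature(
        male_id="BASE", pulse_rate=1.7, n_pulses=14,
        centroid_target=1700.0, q25_target=643.0, jitter=0.0,
    )
    base_call = synth.simulate_call(
        base_sig, sample_rate=config.sample_rate, seed=int(rng.integers(2**31))
    )
    stim_dir = outdir / "stimuli"
    stim_dir.mkdir(exist_ok=True)
    stim_meta = []
    for spec in playback.seven_signal_configurations():
        if spec.kind == "mod_pulse_rate":
            modified = playback.modify_pulse_rate(base_call, spec.target_pulse_rate)
            name = f"rate_{spec.target_pulse_rate:g}hz"
        elif spec.kind == "mod_pulse_count":
            modified = playback.modify_pulse_count(base_call, spec.target_n_pulses)
            name = f"count_{spec.target_n_pulses}"
        else:
            modified = playback.shift_q25(base_call, spec.target_q25)
            name = f"q25_{spec.target_q25:g}hz"
        series = playback.build_series([modified], spec)
        meta = {
            "name": name,
            "kind": spec.kind,
            "repetitions": spec.repetitions,
            "gap_s": spec.gap,
            "level_db_peak": acoustics.peak_level(series),
        }
        if config.write_wavs:
            io.write_wav(series, stim_dir / f"{name}.wav")
            meta["file"] = f"stimuli/{name}.wav"
        stim_meta.append(meta)
    with open(stim_dir / "stimuli.json", "w") as fh:
        json.dump(stim_meta, fh, indent=2)
    outputs.append("stimuli/stimuli.json")
    report["stimuli"] = {"n_configurations": len(stim_meta)}

    # --- responses ----------------------------------------------------------
    resp_a, resp_b, _ = synth.simulate_responses(
        condition_effect=config.response_effect,
        n_trials=config.n_playback_trials,
        noise_sd=config.response_noise_sd,
        seed=int(rng.integers(2**31)),
    )
    both = pd.concat([resp_a, resp_b], ignore_index=True)
    pcs = playback.response_pca(both)
    n = config.n_playback_trials
    stat, p = playback.compare_conditions(pcs.scores[:n, 0], pcs.scores[n:, 0])
    scored = both.copy()
    scored["condition"] = ["A"] * n + ["B"] * n
    for j in range(pcs.n_retained):
        scored[f"PC{j + 1}"] = pcs.scores[:, j]
    scored.to_csv(outdir / "responses_scored.csv", index=False)
    outputs.append("responses_scored.csv")
    report["responses"] = {
        "n_retained": pcs.n_retained,
        "variance_explained_pct": [float(v) for v in pcs.variance_explained],
        "wilcoxon_statistic": stat,
        "wilcoxon_p": p,
    }

    report["outputs"] = outputs
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
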