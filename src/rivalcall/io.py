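"""Shared file I/O: interaction-log CSV, feature CSV, WAV and calibration sidecars.

CSV dialect: UTF-8, comma separated, mandatory header, ``.`` decimal; dates
as integer season-day.  WAV files are PCM 16-bit or float32; because WAV has
no calibration field, absolute levels travel in a sidecar CSV mapping each
file to its pascals-per-full-scale factor.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .acoustics import CallFeatures, CallWaveform
from .dominance import CONTACT_LEVELS, EloTable, InteractionRecord
from .errors import ValidationError

logger = logging.getLogger(__name__)

INTERACTION_COLUMNS = [
    "date",
    "winner_id",
    "loser_id",
    "winner_vocalized",
    "loser_vocalized",
    "contact",
    "decided",
]

_BOOL = {"true": True, "false": False, "1": True, "0": False}


def read_interaction_log(path) -> list[InteractionRecord]:
    """Read a season ledger, validating every row; errors cite line numbers."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in INTERACTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    records = []
    problems = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            contact = str(row["contact"]).strip()
            if contact not in CONTACT_LEVELS:
                raise ValueError(f"unknown contact level {contact!r}")
            records.append(
                InteractionRecord(
                    date=int(row["date"]),
                    winner_id=str(row["winner_id"]),
                    loser_id=str(row["loser_id"]),
                    winner_vocalized=_BOOL[str(row["winner_vocalized"]).strip().lower()],
                    loser_vocalized=_BOOL[str(row["loser_vocalized"]).strip().lower()],
                    contact=contact,
                    decided=_BOOL[str(row["decided"]).strip().lower()],
                )
            )
        except (ValueError, KeyError) as exc:
            problems.append(f"line {line}: {exc}")
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))
    return records


def write_interaction_log(records: Sequence[InteractionRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "date": r.date,
                "winner_id": r.winner_id,
                "loser_id": r.loser_id,
                "winner_vocalized": r.winner_vocalized,
                "loser_vocalized": r.loser_vocalized,
                "contact": r.contact,
                "decided": r.decided,
            }
            for r in records
        ],
        columns=INTERACTION_COLUMNS,
    )
    df.to_csv(path, index=False)


def write_features_csv(features: Sequence[CallFeatures], path) -> None:
    pd.DataFrame([f.as_dict() for f in features]).to_csv(path, index=False)


def read_features_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_elo_csv(table: EloTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def write_trajectories_csv(table: EloTable, path) -> None:
    table.trajectory_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# WAV + calibration sidecar
# ---------------------------------------------------------------------------


def write_wav(wave: CallWaveform, path, bits: int = 16) -> None:
    """Write PCM (16-bit) or float32 WAV; samples are clipped to [-1, 1]."""
    samples = np.clip(wave.samples, -1.0, 1.0)
    if bits == 16:
        data = np.round(samples * 32767.0).astype(np.int16)
    elif bits == 32:
        data = samples.astype(np.float32)
    else:
        raise ValidationError("bits must be 16 (PCM) or 32 (float)")
    wavfile.write(str(path), int(wave.sample_rate), data)


def read_wav(path, calibration: float | None = None, **meta) -> CallWaveform:
    """Read a WAV file into a normalised [-1, 1] waveform."""
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data[:, 0]  # first channel of multichannel recordings
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(float) - 128.0) / 128.0
    else:
        samples = data.astype(float)
    return CallWaveform(samples=samples, sample_rate=float(rate),
                        calibration=calibration, **meta)


def write_calibration_csv(mapping: dict[str, float], path) -> None:
    """Sidecar: file name -> pascals per digital full scale."""
    pd.DataFrame(
        {"file": list(mapping), "pascals_per_full_scale": list(mapping.values())}
    ).to_csv(path, index=False)


def read_calibration_csv(path) -> dict[str, float]:
    df = pd.read_csv(path)
    return dict(zip(df["file"], df["pascals_per_full_scale"].astype(float)))
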