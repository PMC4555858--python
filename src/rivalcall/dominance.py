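"""Elo-rating dominance scoring for dyadic male–male contests.

A season of observed contests is folded chronologically into per-male Elo
ratings.  Every male starts at the same initial score (1000 by default): at
the start of the season each individual is presumed equally likely to win a
dyadic interaction.  After each decided contest the winner gains, and the
loser loses, ``K * (1 - E_a)`` points, where ``E_a`` is the winner's expected
score

    E_a = 1 / (1 + 10 ** ((R_loser - R_winner) / 400))

so that upsets move ratings more than expected outcomes.  The update is
zero-sum: the colony-wide rating total is invariant.

The update constant ``K`` scales rating volatility and cancels out of the
expected-score formula; it defaults to 100, a common choice for short
observation windows, and is exposed everywhere.

Undecided contests (e.g. sustained fights that end without a retreat) never
update ratings; they are counted in the descriptive tallies only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .errors import InvalidConfigError

logger = logging.getLogger(__name__)

CONTACT_LEVELS = ("none", "single_blows", "sustained")

DEFAULT_INITIAL = 1000.0
DEFAULT_K = 100.0


@dataclass(frozen=True)
class InteractionRecord:
    """One dyadic contest: outcome plus vocal and contact annotations.

    ``date`` is an ordinal season day; same-day records keep ledger order.
    ``decided=False`` marks a draw / no-decision contest (the ``winner_id`` /
    ``loser_id`` fields then record the two participants in ledger order).
    """

    date: int
    winner_id: str
    loser_id: str
    winner_vocalized: bool = False
    loser_vocalized: bool = False
    contact: str = "none"
    decided: bool = True

    def __post_init__(self) -> None:
        if self.winner_id == self.loser_id:
            raise InvalidConfigError(
                f"winner and loser must differ, got {self.winner_id!r} twice"
            )
        if self.contact not in CONTACT_LEVELS:
            raise InvalidConfigError(
                f"unknown contact level {self.contact!r}; expected one of {CONTACT_LEVELS}"
            )


@dataclass
class EloTable:
    """Per-male rating state plus the full trajectory of each male.

    A male's trajectory starts at ``initial`` and gains one entry per
    interaction he took part in, so its length is 1 + number of his
    interactions.
    """

    K: float = DEFAULT_K
    initial: float = DEFAULT_INITIAL
    ratings: dict[str, float] = field(default_factory=dict)
    trajectories: dict[str, list[float]] = field(default_factory=dict)
    n_applied: int = 0
    n_skipped: int = 0

    def enroll(self, male_id: str) -> None:
        if male_id not in self.ratings:
            self.ratings[male_id] = self.initial
            self.trajectories[male_id] = [self.initial]

    def final_scores(self) -> dict[str, float]:
        return dict(self.ratings)

    def to_frame(self) -> pd.DataFrame:
        """Final seasonal scores, one row per male, sorted by rating."""
        df = pd.DataFrame(
            {"male_id": list(self.ratings), "elo_final": list(self.ratings.values())}
        )
        return df.sort_values("elo_final", ascending=False, ignore_index=True)

    def trajectory_frame(self) -> pd.DataFrame:
        """Tidy trajectory export: (male_id, step, rating)."""
        rows = [
            (male, step, rating)
            for male, traj in self.trajectories.items()
            for step, rating in enumerate(traj)
        ]
        return pd.DataFrame(rows, columns=["male_id", "step", "rating"])


def expected_score(rank_1: float, rank_2: float) -> float:
    """Probability that individual 1 (rating ``rank_1``) beats individual 2.

    Complementary by construction: ``expected_score(a, b) + expected_score(b, a) == 1``.
    """
    if not (math.isfinite(rank_1) and math.isfinite(rank_2)):
        raise InvalidConfigError("Elo ratings must be finite")
    return 1.0 / (1.0 + 10.0 ** ((rank_2 - rank_1) / 400.0))


def apply_interaction(table: EloTable, rec: InteractionRecord) -> EloTable:
    """Fold one contest into the table (in place; the table is returned).

    Both males are auto-enrolled at ``table.initial`` on first appearance.
    Undecided records are skipped with a logged notice and counted.
    """
    table.enroll(rec.winner_id)
    table.enroll(rec.loser_id)
    if not rec.decided:
        logger.info(
            "undecided interaction on day %s between %s and %s: ratings unchanged",
            rec.date,
            rec.winner_id,
            rec.loser_id,
        )
        table.n_skipped += 1
        return table
    e_winner = expected_score(table.ratings[rec.winner_id], table.ratings[rec.loser_id])
    delta = table.K * (1.0 - e_winner)
    table.ratings[rec.winner_id] += delta
    table.ratings[rec.loser_id] -= delta
    table.trajectories[rec.winner_id].append(table.ratings[rec.winner_id])
    table.trajectories[rec.loser_id].append(table.ratings[rec.loser_id])
    table.n_applied += 1
    return table


def score_season(
    records: Sequence[InteractionRecord],
    K: float = DEFAULT_K,
    initial: float = DEFAULT_INITIAL,
) -> EloTable:
    """Chronological Elo fold over a season's ledger.

    Records are sorted by date with ties broken by ledger order, so the fold
    is deterministic.  Males never recorded are absent from the result.
    """
    table = EloTable(K=K, initial=initial)
    for rec in sorted(records, key=lambda r: r.date):  # stable sort keeps ledger order
        apply_interaction(table, rec)
    return table


@dataclass
class NetworkSummary:
    """Descriptive ledger statistics: opponents per male, dyad asymmetry, tallies.

    ``asymmetric_fraction`` is computed over dyads with at least one decided
    contest: a dyad is asymmetric when every decided contest was won by the
    same male.  Percentages are reported against an explicit denominator
    (``n_interactions``), because published tallies of this kind often leave
    the denominator ambiguous.
    """

    n_interactions: int
    interactant_count: dict[str, int]
    dyad_total: int
    asymmetric_fraction: float
    tallies: dict[str, int]
    percentages: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (key, self.tallies[key], self.percentages[key]) for key in self.tallies
        ]
        return pd.DataFrame(rows, columns=["event", "count", "percent_of_interactions"])


def summarize_network(records: Sequence[InteractionRecord]) -> NetworkSummary:
    """Compute per-male opponent counts, dyad asymmetry and vocal/contact tallies."""
    opponents: dict[str, set[str]] = {}
    dyad_winners: dict[tuple[str, str], set[str]] = {}
    tallies = {
        "winner_vocalized": 0,
        "loser_vocalized": 0,
        "both_vocalized": 0,
        "neither_vocalized": 0,
        "physical_contact": 0,
        "sustained_contact": 0,
        "undecided": 0,
    }
    for rec in records:
        opponents.setdefault(rec.winner_id, set()).add(rec.loser_id)
        opponents.setdefault(rec.loser_id, set()).add(rec.winner_id)
        dyad = tuple(sorted((rec.winner_id, rec.loser_id)))
        if rec.decided:
            dyad_winners.setdefault(dyad, set()).add(rec.winner_id)
        else:
            dyad_winners.setdefault(dyad, set())
            tallies["undecided"] += 1
        if rec.winner_vocalized:
            tallies["winner_vocalized"] += 1
        if rec.loser_vocalized:
            tallies["loser_vocalized"] += 1
        if rec.winner_vocalized and rec.loser_vocalized:
            tallies["both_vocalized"] += 1
        if not rec.winner_vocalized and not rec.loser_vocalized:
            tallies["neither_vocalized"] += 1
        if rec.contact != "none":
            tallies["physical_contact"] += 1
        if rec.contact == "sustained":
            tallies["sustained_contact"] += 1

    n = len(records)
    decided_dyads = {d: w for d, w in dyad_winners.items() if w}
    if decided_dyads:
        n_asym = sum(1 for winners in decided_dyads.values() if len(winners) == 1)
        asymmetric_fraction = n_asym / len(decided_dyads)
    else:
        asymmetric_fraction = float("nan")
    percentages = {
        key: (100.0 * count / n if n else float("nan"))
        for key, count in tallies.items()
    }
    return NetworkSummary(
        n_interactions=n,
        interactant_count={m: len(o) for m, o in opponents.items()},
        dyad_total=len(dyad_winners),
        asymmetric_fraction=asymmetric_fraction,
        tallies=tallies,
        percentages=percentages,
    )


def rating_sum(table: EloTable) -> float:
    """Colony-wide rating total; conserved at n_males * initial by the update."""
    return float(sum(table.ratings.values()))
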