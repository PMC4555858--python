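"""Elo-score the simulated season and check what the ratings recover.

Reads the contest ledger from 01, folds it into Elo ratings (K = 100,
initial 1000), and writes final scores and full trajectories.  The rating
total must stay at n_males x 1000 (the update is zero-sum); the printed
ranking is the data-driven estimate of the latent hierarchy.
"""

from pathlib import Path

from rivalcall import dominance, io

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ledger = RESULTS / "interactions.csv"
    if not ledger.exists():
        raise SystemExit("run analysis/01_simulate_colony.py first")
    records = io.read_interaction_log(ledger)
    table = dominance.score_season(records, K=100.0, initial=1000.0)
    io.write_elo_csv(table, RESULTS / "elo.csv")
    io.write_trajectories_csv(table, RESULTS / "elo_trajectories.csv")

    total = dominance.rating_sum(table)
    print(f"{table.n_applied} decided contests scored, {table.n_skipped} draws skipped")
    print(f"rating sum {total:.6f} (conserved at {len(table.ratings)} x 1000)")
    ranking = table.to_frame()
    print("top of the hierarchy:")
    for _, row in ranking.head(5).iterrows():
        print(f"  {row.male_id}: {row.elo_final:7.1f}")
    print(f"wrote {RESULTS / 'elo.csv'} and elo_trajectories.csv")


if __name__ == "__main__":
    main()
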