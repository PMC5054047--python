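"""Choice-derived preference scores per analysis scope.

For the simulated orangutan-style subject, tabulates the proportion of times
each of the ten liquids was chosen out of the occasions it was offered, in
the three scopes used downstream (first two encounters per pair, concealed
trials, all test trials), plus the post-experimental pairwise trials.
"""

from pathlib import Path

from afchoice import scoring, trial_model

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ds = trial_model.load_trials(ROOT / "data" / "orangutan" / "trials.csv")
    out = ROOT / "preference_scores"
    out.mkdir(parents=True, exist_ok=True)
    for name, table in scoring.scores_by_scope(ds).items():
        table.to_csv(out / f"{name}.csv")
        top = table.index[table["rank"] == table["rank"].min()][0]
        print(f"scope {name}: most preferred item {top} (score {table.loc[top, 'score']:.2f})")
    post = scoring.ranking(
        scoring.preference_scores(ds.phase_trials("post_experimental"), items=sorted(ds.items))
    )
    post.to_csv(out / "post_experimental.csv")
    print(f"post-experimental favourite: {post.index[post['rank'] == post['rank'].min()][0]}")


if __name__ == "__main__":
    main()
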