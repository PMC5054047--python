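"""Rank correlation of test-derived vs post-experimental preferences.

Kendall tau-b (permutation significance) between each AF-test scope's
preference scores and the post-experimental measure: pairwise-choice scores
for the orangutan-style subject, harmonised self-report ranks for the
human-style subject.
"""

from pathlib import Path

from afchoice import trial_model
from afchoice.cli_report import analyze_dataset

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = ROOT / "rank_correlation"
    out.mkdir(parents=True, exist_ok=True)
    for name in ("orangutan", "human"):
        data = ROOT / "data" / name
        ds = trial_model.load_trials(data / "trials.csv")
        report = (
            trial_model.load_self_report(data / "self_report.csv")
            if (data / "self_report.csv").exists()
            else None
        )
        res = analyze_dataset(ds, self_report=report, seed=0)
        taus = res["tau_correlations"]
        taus.to_csv(out / f"{name}.csv", index=False)
        for _, row in taus.iterrows():
            print(
                f"{name} / {row['scope']}: tau_b = {row['tau_b']:.2f} "
                f"(p = {row['p_value']:.3f}, N = {row['n']})"
            )


if __name__ == "__main__":
    main()
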