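"""Estimator validation: worth recovery and model-selection rates.

Simulate-and-refit experiments establishing that (1) the Bradley-Terry MLE
recovers known log-worths with error shrinking in the number of choices, and
(2) at the study's own size (48 + 225 choices) AIC reliably identifies
whether the data came from constant or early-shifted mix worths.
"""

import json
from pathlib import Path

from afchoice.cli_report import cmd_recover

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = ROOT / "recovery"
    res = cmd_recover({"seed": 0, "n_grid": [200, 1000, 5000]}, out, n_replicates=20)
    print(res["worth_recovery"].to_string(index=False))
    for truth, rates in res["model_selection"].items():
        print(
            f"{truth}: AIC picks constant model in {rates['aic_prefers_A_rate']:.0%} "
            f"of {rates['n_replicates']} study-sized replicates (MC SE {rates['mc_se']:.3f})"
        )
    (out / "README.txt").write_text(
        "worth_recovery.csv: bias/RMSE of fitted log-worths per simulated n\n"
        "model_selection.json: AIC model-choice rates at study size\n"
    )


if __name__ == "__main__":
    main()
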