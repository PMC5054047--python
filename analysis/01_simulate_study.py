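"""Simulate the two study designs and write their trial files.

Generates one orangutan-style subject (pairwise post-experimental trials,
colour control) and one human-style subject (self-reported ranks instead),
both from forecaster agents with moderate per-mix interaction noise, and
stores the CSVs that the later analysis steps read.
"""

from pathlib import Path

from afchoice.cli_report import cmd_simulate

OUT = Path(__file__).resolve().parents[1] / "results" / "data"

ORANGUTAN_CFG = {
    "subject_id": "sim_orangutan",
    "subject_species": "orangutan_style",
    "agent": {"mix_interaction_sd": 0.5, "seed": 0},
}
HUMAN_CFG = {
    "subject_id": "sim_human",
    "subject_species": "human_style",
    "agent": {"mix_interaction_sd": 0.5, "self_report_noise_sd": 0.3, "seed": 1},
}


def main() -> None:
    for name, cfg in (("orangutan", ORANGUTAN_CFG), ("human", HUMAN_CFG)):
        summary = cmd_simulate(cfg, OUT / name)
        print(
            f"{name}-style subject: {summary['n_trials']} trials "
            f"({summary['n_af_trials']} AF-test), {summary['n_items']} items, "
            f"{len(summary['design_violations'])} design violations"
        )


if __name__ == "__main__":
    main()
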