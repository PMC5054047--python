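"""Synthetic subjects and study schedules.

Generates complete forced-choice datasets with the structure the analysis
assumes: four ingredients, their six pairwise mixes, familiarisation blocks,
a 96-trial AF test (24 unique ingredient-mix pairs x 4 presentations, two
transparent then two concealed encounters each, sides counterbalanced 2-2),
a 36-trial reversed-colour control, and blocked post-experimental pairwise
trials over all C(10,2) item pairs.

Choices are drawn from a latent Bradley-Terry agent.  A *forecaster* values
a never-tasted mix at the mean of its components' log-worths (plus a fixed,
seeded per-mix interaction term allowing non-additive tastes); a
*trial_and_error* agent has no access to that forecast before tasting and
falls back on a flat prior (the median ingredient worth) during the first two
encounters.  Optional knobs add novelty, volume and colour biases to the
choice logit, a lapse rate, and an early-encounter worth shift.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .trial_model import (
    Item,
    StudyDataset,
    TrialRecord,
    derive_encounters,
    mix_id,
)

#: default ingredient set: C cherry, R rhubarb (sweet); L lemon, V vinegar (sour)
DEFAULT_INGREDIENT_WORTHS = {"C": 2.0, "R": 1.2, "L": 0.4, "V": 0.0}
SWEET_IDS = frozenset({"C", "R"})

ORIGINAL_COLOURS = {"C": "red", "R": "pink", "L": "light_green", "V": "dark_green"}
REVERSED_COLOURS = {"C": "dark_green", "R": "light_green", "L": "pink", "V": "red"}


@dataclass
class AgentSpec:
    """Latent preference structure of a simulated subject."""

    ingredient_log_worths: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INGREDIENT_WORTHS)
    )
    mix_rule: str = "forecaster"  # "forecaster" | "trial_and_error"
    mix_interaction_sd: float = 0.0
    phase_shift: float = 0.0  # added to mix log-worths during AF encounters 1-2
    novelty_bias: float = 0.0  # logit bonus for the mix option
    volume_bias: float = 0.0  # logit bonus for the 20-ml option
    colour_bias: dict[str, float] = field(default_factory=dict)
    lapse_rate: float = 0.0
    self_report_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.mix_rule not in ("forecaster", "trial_and_error"):
            raise ValueError(f"unknown mix rule {self.mix_rule!r}")
        if not (0.0 <= self.lapse_rate <= 1.0):
            raise ValueError(f"lapse rate must be in [0,1], got {self.lapse_rate}")
        if self.mix_interaction_sd < 0 or self.self_report_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        for k, v in self.ingredient_log_worths.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite worth for ingredient {k!r}")
        if len(self.ingredient_log_worths) != 4:
            raise ValueError("the study design uses exactly 4 ingredients")


@dataclass
class ScheduleSpec:
    """Trial counts per phase (defaults = the study design)."""

    n_familiarisation_blocked: int = 30
    n_familiarisation_random: int = 24
    af_reps: int = 4  # 2 transparent + 2 concealed presentations per pair
    post_block_len: int = 5
    colour_control_trials: int = 36


def make_items(ingredient_ids=("C", "L", "R", "V")) -> dict[str, Item]:
    """The ten liquids: 4 ingredients and their 6 pairwise mixes."""
    items = {
        i: Item(id=i, kind="ingredient", colour=ORIGINAL_COLOURS.get(i, ""), volume_ml=10.0)
        for i in ingredient_ids
    }
    for a, b in itertools.combinations(sorted(ingredient_ids), 2):
        m = mix_id(a, b)
        items[m] = Item(id=m, kind="mix", components=frozenset((a, b)), colour="mixed", volume_ml=20.0)
    return items


def _sides(rng: np.random.Generator, n: int) -> list[int]:
    """A counterbalanced left/right assignment: as close to n/2 each as possible."""
    s = [0] * (n // 2) + [1] * (n // 2)
    if n % 2:
        s.append(int(rng.integers(2)))
    rng.shuffle(s)
    return s


def make_schedule(
    spec: ScheduleSpec | None = None,
    seed: int = 0,
    subject_id: str = "sim",
    subject_species: str = "orangutan_style",
) -> StudyDataset:
    """Lay out all phases as a choiceless skeleton (chosen = None).

    The AF test is ``af_reps`` blocks of the 24 ingredient-mix pairs, each
    block an independent random permutation; the first half of the blocks is
    transparent, the second concealed, so encounters 1-2 fall in the
    transparent and 3-4 in the concealed condition.  Post-experimental trials
    (orangutan-style designs) present every unordered pair of the ten liquids
    in blocks of ``post_block_len``.
    """
    spec = spec or ScheduleSpec()
    rng = np.random.default_rng((int(seed), 101))
    items = make_items()
    ingredients = sorted(i for i, it in items.items() if it.kind == "ingredient")
    mixes = sorted(i for i, it in items.items() if it.kind == "mix")
    ing_pairs = list(itertools.combinations(ingredients, 2))
    trials: list[TrialRecord] = []
    phase_counter: dict[str, int] = {}

    def add(phase, condition, pair, side):
        left, right = (pair[0], pair[1]) if side == 0 else (pair[1], pair[0])
        phase_counter[phase] = phase_counter.get(phase, 0) + 1
        trials.append(
            TrialRecord(
                trial_index=phase_counter[phase],
                phase=phase,
                condition=condition,
                left_item=left,
                right_item=right,
                chosen=None,
            )
        )

    # familiarisation, blocked: each ingredient pair in one contiguous block
    reps_b, extra = divmod(spec.n_familiarisation_blocked, len(ing_pairs))
    order = list(ing_pairs)
    rng.shuffle(order)
    for bi, pair in enumerate(order):
        n = reps_b + (1 if bi < extra else 0)
        for side in _sides(rng, n):
            add("familiarisation_blocked", "not_applicable", pair, side)

    # familiarisation, randomised: pairs interleaved at random
    reps_r, extra = divmod(spec.n_familiarisation_random, len(ing_pairs))
    pool = []
    for bi, pair in enumerate(ing_pairs):
        n = reps_r + (1 if bi < extra else 0)
        pool += [(pair, side) for side in _sides(rng, n)]
    rng.shuffle(pool)
    for pair, side in pool:
        add("familiarisation_random", "not_applicable", pair, side)

    # AF test: af_reps blocks of the 24 ingredient-mix pairs
    af_pairs = [(i, m) for i in ingredients for m in mixes]
    side_seq = {p: _sides(rng, spec.af_reps) for p in af_pairs}
    half = spec.af_reps // 2
    for rep in range(spec.af_reps):
        condition = "transparent" if rep < half else "concealed"
        block = list(af_pairs)
        rng.shuffle(block)
        for pair in block:
            add("af_test", condition, pair, side_seq[pair][rep])

    if subject_species == "orangutan_style":
        # colour control: ingredient pairs, reversed colours, randomised order
        reps_c, extra = divmod(spec.colour_control_trials, len(ing_pairs))
        pool = []
        for bi, pair in enumerate(ing_pairs):
            n = reps_c + (1 if bi < extra else 0)
            pool += [(pair, side) for side in _sides(rng, n)]
        rng.shuffle(pool)
        for pair, side in pool:
            add("colour_control", "not_applicable", pair, side)

        # post-experimental: all C(10,2) pairs, blocked
        all_pairs = list(itertools.combinations(sorted(items), 2))
        rng.shuffle(all_pairs)
        for pair in all_pairs:
            for side in _sides(rng, spec.post_block_len):
                add("post_experimental", "not_applicable", pair, side)

    ds = StudyDataset(
        items=items, trials=trials, subject_id=subject_id, subject_species=subject_species
    )
    return derive_encounters(ds)


def _mix_interaction(agent: AgentSpec, mix: str) -> float:
    """Fixed per-mix interaction draw, keyed so it never depends on schedule."""
    if agent.mix_interaction_sd == 0.0:
        return 0.0
    key = int.from_bytes(mix.encode(), "big")
    rng = np.random.default_rng((int(agent.seed), 202, key))
    return float(rng.normal(0.0, agent.mix_interaction_sd))


def forecast_worth(agent: AgentSpec, mix: str, components) -> float:
    comps = sorted(components)
    mean = float(np.mean([agent.ingredient_log_worths[c] for c in comps]))
    return mean + _mix_interaction(agent, mix)


def agent_worth(
    agent: AgentSpec,
    item: Item,
    phase: str,
    encounter_index: int | None,
) -> float:
    """Effective log-worth of an item for this agent at this point of the study.

    Ingredients carry their latent worth throughout.  For mixes, the first
    two AF-test encounters are the pre-taste window: a forecaster already
    holds the forecast worth there, a trial-and-error agent only a flat prior
    (median ingredient worth); from the third encounter on, and in the
    post-experimental trials, both rules use the post-taste (forecast) value.
    ``phase_shift`` displaces mix worths inside the pre-taste window only.
    """
    if item.kind == "ingredient":
        if item.id not in agent.ingredient_log_worths:
            raise ValueError(f"agent defines no worth for ingredient {item.id!r}")
        return agent.ingredient_log_worths[item.id]

    early = phase == "af_test" and encounter_index is not None and encounter_index <= 2
    if early and agent.mix_rule == "trial_and_error":
        worth = float(np.median(list(agent.ingredient_log_worths.values())))
    else:
        worth = forecast_worth(agent, item.id, item.components)
    if early:
        worth += agent.phase_shift
    return worth


def simulate_choices(agent: AgentSpec, skeleton: StudyDataset) -> StudyDataset:
    """Fill in the choices of a schedule skeleton, reproducibly from the seed.

    Per trial the left-over-right logit is the effective worth difference
    plus the novelty bias (if exactly one option is a mix), the volume bias
    (if exactly one option is the larger 20-ml portion), and any colour-bias
    terms; with probability ``lapse_rate`` the choice is instead uniform.
    """
    rng = np.random.default_rng((int(agent.seed), 303))
    out_trials = []
    for t in skeleton.trials:
        left = skeleton.items[t.left_item]
        right = skeleton.items[t.right_item]
        logit = agent_worth(agent, left, t.phase, t.encounter_index) - agent_worth(
            agent, right, t.phase, t.encounter_index
        )
        logit += agent.novelty_bias * ((left.kind == "mix") - (right.kind == "mix"))
        is20 = lambda it: t.phase == "af_test" and it.kind == "mix"  # mixes are 20 ml in AF trials
        logit += agent.volume_bias * (is20(left) - is20(right))
        if agent.colour_bias:
            logit += _colour_term(agent, left, t.phase) - _colour_term(agent, right, t.phase)
        if rng.random() < agent.lapse_rate:
            chosen = t.left_item if rng.random() < 0.5 else t.right_item
        else:
            p_left = 1.0 / (1.0 + np.exp(-np.clip(logit, -700, 700)))
            chosen = t.left_item if rng.random() < p_left else t.right_item
        out_trials.append(
            TrialRecord(
                trial_index=t.trial_index,
                phase=t.phase,
                condition=t.condition,
                left_item=t.left_item,
                right_item=t.right_item,
                chosen=chosen,
                encounter_index=t.encounter_index,
            )
        )
    ds = StudyDataset(
        items=dict(skeleton.items),
        trials=out_trials,
        subject_id=skeleton.subject_id,
        subject_species=skeleton.subject_species,
    )
    ds.validate()
    return ds


def _colour_term(agent: AgentSpec, item: Item, phase: str) -> float:
    if item.kind != "ingredient":
        return 0.0
    scheme = REVERSED_COLOURS if phase == "colour_control" else ORIGINAL_COLOURS
    return agent.colour_bias.get(scheme.get(item.id, ""), 0.0)


def simulate_self_report(agent: AgentSpec, items: dict[str, Item] | None = None) -> dict[str, int]:
    """Self-reported ranks 1..10 (1 = most preferred) of the ten liquids.

    Ranks order the true post-taste worths perturbed by Gaussian noise of sd
    ``self_report_noise_sd``.
    """
    items = items or make_items()
    rng = np.random.default_rng((int(agent.seed), 404))
    ids = sorted(items)
    worths = np.array(
        [agent_worth(agent, items[i], "post_experimental", None) for i in ids]
    )
    noisy = worths + rng.normal(0.0, agent.self_report_noise_sd, size=len(ids))
    order = np.argsort(-noisy, kind="stable")
    ranks = np.empty(len(ids), dtype=int)
    ranks[order] = np.arange(1, len(ids) + 1)
    return dict(zip(ids, ranks.tolist()))


def simulate_study(
    agent: AgentSpec,
    schedule: ScheduleSpec | None = None,
    subject_id: str = "sim",
    subject_species: str = "orangutan_style",
) -> tuple[StudyDataset, dict[str, int] | None]:
    """Full study: schedule + choices (+ self-report for human-style designs)."""
    skeleton = make_schedule(
        schedule, seed=agent.seed, subject_id=subject_id, subject_species=subject_species
    )
    ds = simulate_choices(agent, skeleton)
    report = simulate_self_report(agent, ds.items) if subject_species == "human_style" else None
    return ds, report
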