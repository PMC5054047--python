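"""Domain model for binary forced-choice study data.

A study presents a subject with a sequence of two-alternative choices between
liquids: four familiar single-juice *ingredients* and the six pairwise *mixes*
obtainable from them.  Trials are organised in phases (familiarisation,
affective-forecasting test, colour control, post-experimental preference
trials); the AF test pairs one ingredient against one mix, four times per
unique pair, first under visual access ("transparent") and then without
("concealed").

This module holds the data types, the CSV interchange format, design
validation, and the derivation of per-pair encounter indices that every
downstream statistic keys on.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

PHASES = (
    "familiarisation_blocked",
    "familiarisation_random",
    "af_test",
    "colour_control",
    "post_experimental",
)
CONDITIONS = ("transparent", "concealed", "not_applicable")
SPECIES = ("orangutan_style", "human_style")

#: mandatory columns of the trial CSV, in order
TRIAL_COLUMNS = (
    "subject_id",
    "phase",
    "condition",
    "trial_index",
    "left_item",
    "right_item",
    "chosen",
)


class FormatError(ValueError):
    """A file does not conform to the documented interchange format."""


class ValidationError(ValueError):
    """Data violate a structural invariant of the study design."""


def mix_id(a: str, b: str) -> str:
    """Canonical mix id: sorted concatenation of the two component ids."""
    if a == b:
        raise ValidationError(f"a mix needs two distinct ingredients, got {a!r} twice")
    return "".join(sorted((a, b)))


@dataclass(frozen=True)
class Item:
    """One liquid: a familiar ingredient or a two-ingredient mix."""

    id: str
    kind: str  # "ingredient" | "mix"
    components: frozenset[str] = frozenset()
    colour: str = ""
    volume_ml: float = 10.0

    def __post_init__(self) -> None:
        if self.kind not in ("ingredient", "mix"):
            raise ValidationError(f"unknown item kind {self.kind!r} for {self.id!r}")
        if self.kind == "mix" and len(self.components) != 2:
            raise ValidationError(f"mix {self.id!r} must have exactly 2 components")
        if self.kind == "ingredient" and self.components:
            raise ValidationError(f"ingredient {self.id!r} cannot have components")
        if self.volume_ml <= 0:
            raise ValidationError(f"non-positive volume for {self.id!r}")


@dataclass
class TrialRecord:
    """One binary choice.

    ``encounter_index`` is the 1-based position of the trial among all trials
    in the same phase that present the same unordered item pair; it is
    ``None`` until :func:`derive_encounters` has run.
    """

    trial_index: int
    phase: str
    condition: str
    left_item: str
    right_item: str
    chosen: str | None
    encounter_index: int | None = None

    @property
    def pair_key(self) -> tuple[str, str]:
        return tuple(sorted((self.left_item, self.right_item)))  # type: ignore[return-value]

    def validate(self, row: int | None = None) -> None:
        at = "" if row is None else f" (row {row})"
        if self.phase not in PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}{at}")
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}{at}")
        if (self.condition != "not_applicable") != (self.phase == "af_test"):
            raise ValidationError(
                f"condition {self.condition!r} invalid outside/inside af_test{at}"
            )
        if self.left_item == self.right_item:
            raise ValidationError(f"left and right items identical{at}")
        if self.chosen is not None and self.chosen not in (self.left_item, self.right_item):
            raise ValidationError(
                f"chosen item {self.chosen!r} not among offered "
                f"({self.left_item!r}, {self.right_item!r}){at}"
            )
        if self.trial_index < 1:
            raise ValidationError(f"trial_index must be >= 1{at}")


@dataclass
class StudyDataset:
    """All trials of one subject, plus the item catalogue."""

    items: dict[str, Item]
    trials: list[TrialRecord]
    subject_id: str = "subject"
    subject_species: str = "orangutan_style"

    def validate(self) -> None:
        if self.subject_species not in SPECIES:
            raise ValidationError(f"unknown species {self.subject_species!r}")
        ingredient_ids = {i.id for i in self.items.values() if i.kind == "ingredient"}
        for item in self.items.values():
            if item.kind == "mix" and not item.components <= ingredient_ids:
                raise ValidationError(
                    f"mix {item.id!r} references unknown ingredients "
                    f"{sorted(item.components - ingredient_ids)}"
                )
        for row, t in enumerate(self.trials, start=1):
            t.validate(row)
            for iid in (t.left_item, t.right_item):
                if iid not in self.items:
                    raise ValidationError(f"trial row {row} references unknown item {iid!r}")
            if t.phase == "af_test":
                kinds = {self.items[t.left_item].kind, self.items[t.right_item].kind}
                if kinds != {"ingredient", "mix"}:
                    raise ValidationError(
                        f"af_test trial row {row} must pair an ingredient with a mix"
                    )

    def phase_trials(self, phase: str) -> list[TrialRecord]:
        return [t for t in self.trials if t.phase == phase]

    def ingredients(self) -> list[str]:
        return sorted(i.id for i in self.items.values() if i.kind == "ingredient")

    def mixes(self) -> list[str]:
        return sorted(i.id for i in self.items.values() if i.kind == "mix")


def infer_items_from_ids(ids: set[str]) -> dict[str, Item]:
    """Build an item catalogue from trial item ids alone.

    Single-character ids are ingredients; multi-character ids are mixes whose
    components are their characters (the canonical sorted-concatenation id).
    """
    items: dict[str, Item] = {}
    for iid in sorted(ids):
        if len(iid) == 1:
            items[iid] = Item(id=iid, kind="ingredient")
        else:
            comps = frozenset(iid)
            if len(iid) != 2 or len(comps) != 2 or iid != "".join(sorted(iid)):
                raise FormatError(
                    f"cannot infer item {iid!r}: mix ids are the sorted "
                    "concatenation of two distinct ingredient ids"
                )
            items[iid] = Item(id=iid, kind="mix", components=comps)
    # ensure component ingredients exist even if never offered alone
    for item in list(items.values()):
        for c in item.components:
            items.setdefault(c, Item(id=c, kind="ingredient"))
    return items


def load_items(path) -> dict[str, Item]:
    """Read an items CSV: columns id, kind, components, colour, volume_ml."""
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"id", "kind"}
    if not required <= set(df.columns):
        raise FormatError(f"items CSV missing column(s) {sorted(required - set(df.columns))}")
    items = {}
    for _, r in df.iterrows():
        comps = frozenset(c for c in str(r.get("components", "")).split("+") if c)
        items[r["id"]] = Item(
            id=r["id"],
            kind=r["kind"],
            components=comps,
            colour=str(r.get("colour", "")),
            volume_ml=float(r.get("volume_ml") or 10.0),
        )
    return items


def load_trials(path, items_path=None) -> StudyDataset:
    """Read a trial CSV into a validated :class:`StudyDataset`.

    Rows are kept in file order; ``encounter_index`` is derived.  The item
    catalogue is inferred from the trial columns unless ``items_path`` names
    an items CSV.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trial CSV missing column(s) {missing}")
    unknown = [c for c in df.columns if c not in TRIAL_COLUMNS]
    if unknown:
        raise FormatError(f"trial CSV has unknown column(s) {unknown}")

    trials = []
    for row, r in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            trial = TrialRecord(
                trial_index=int(r.trial_index),
                phase=str(r.phase),
                condition=str(r.condition),
                left_item=str(r.left_item),
                right_item=str(r.right_item),
                chosen=str(r.chosen),
            )
            trial.validate(row)
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"invalid trial at CSV line {row}: {exc}") from exc
        trials.append(trial)

    if items_path is not None:
        items = load_items(items_path)
    else:
        ids = {t.left_item for t in trials} | {t.right_item for t in trials}
        items = infer_items_from_ids(ids)

    subject_id = str(df["subject_id"].iloc[0]) if len(df) else "subject"
    ds = StudyDataset(items=items, trials=trials, subject_id=subject_id)
    ds.validate()
    return derive_encounters(ds)


def write_trials(ds: StudyDataset, path) -> None:
    """Write the trial CSV (the reader's exact inverse)."""
    rows = [
        {
            "subject_id": ds.subject_id,
            "phase": t.phase,
            "condition": t.condition,
            "trial_index": t.trial_index,
            "left_item": t.left_item,
            "right_item": t.right_item,
            "chosen": t.chosen,
        }
        for t in ds.trials
    ]
    pd.DataFrame(rows, columns=list(TRIAL_COLUMNS)).to_csv(path, index=False)


def derive_encounters(ds: StudyDataset) -> StudyDataset:
    """Assign 1-based encounter indices per (phase, unordered pair).

    Within each phase, the trials sharing a pair key are numbered 1..k in
    ``trial_index`` order.  An AF-test pair occurring more than four times is
    a schedule deviation and raises a warning, not an error.
    """
    counters: dict[tuple[str, tuple[str, str]], int] = {}
    trials = sorted(ds.trials, key=lambda t: (PHASES.index(t.phase), t.trial_index))
    for t in trials:
        key = (t.phase, t.pair_key)
        counters[key] = counters.get(key, 0) + 1
        t.encounter_index = counters[key]
        if t.phase == "af_test" and counters[key] > 4:
            warnings.warn(
                f"AF-test pair {t.pair_key} occurs more than 4 times "
                f"(encounter {counters[key]})",
                stacklevel=2,
            )
    return ds


def validate_design(ds: StudyDataset) -> list[str]:
    """Report deviations from the canonical study design (report-only).

    Checks: the AF test presents all ingredient-mix pairs (4 ingredients x 6
    mixes = 24) exactly four times each; the mixes are all C(4,2) unordered
    ingredient pairs; each AF pair's left/right placement is counterbalanced
    2-2 across its four presentations.
    """
    violations: list[str] = []
    ingredients = ds.ingredients()
    mixes = ds.mixes()

    expected_mixes = sorted(mix_id(a, b) for a, b in itertools.combinations(ingredients, 2))
    if mixes != expected_mixes:
        violations.append(
            f"mix set {mixes} differs from all ingredient pairs {expected_mixes}"
        )

    af = ds.phase_trials("af_test")
    counts: dict[tuple[str, str], int] = {}
    left_ing: dict[tuple[str, str], int] = {}
    for t in af:
        counts[t.pair_key] = counts.get(t.pair_key, 0) + 1
        ing_side_left = ds.items[t.left_item].kind == "ingredient"
        left_ing[t.pair_key] = left_ing.get(t.pair_key, 0) + int(ing_side_left)

    expected_pairs = {tuple(sorted((i, m))) for i in ingredients for m in mixes}
    if set(counts) != expected_pairs:
        missing = sorted(expected_pairs - set(counts))
        extra = sorted(set(counts) - expected_pairs)
        if missing:
            violations.append(f"AF pairs missing: {missing}")
        if extra:
            violations.append(f"unexpected AF pairs: {extra}")
    for pair, c in sorted(counts.items()):
        if c != 4:
            violations.append(f"AF pair {pair} occurs {c} times, expected 4")
        elif left_ing.get(pair) != 2:
            violations.append(
                f"AF pair {pair} ingredient-left on {left_ing.get(pair)} of 4 trials, "
                "expected 2 (counterbalancing)"
            )
    return violations


def load_self_report(path) -> dict[str, int]:
    """Read a 2-column self-report CSV (item, rank; 1 = most preferred)."""
    df = pd.read_csv(path, dtype={"item": str, "rank": int})
    if list(df.columns) != ["item", "rank"]:
        raise FormatError("self-report CSV must have exactly the columns item, rank")
    return dict(zip(df["item"], df["rank"]))


def write_self_report(ranks: dict[str, int], path) -> None:
    pd.DataFrame(
        {"item": list(ranks), "rank": [ranks[i] for i in ranks]}
    ).to_csv(path, index=False)
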