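"""Choice-consistency statistics, exact tests, and bias controls.

Consistency asks whether a subject chooses the same option on two designated
encounters with the same unordered item pair; the count of consistent pairs
is compared with chance 0.5 by an exact two-sided binomial test.  Related
controls: an ingredient-vs-mix (novelty/volume) bias check, cross-set-up
stability of familiarisation preferences, and a colour-scheme reversal check,
the latter two via Fisher's exact test.

Both exact tests use the minimum-likelihood two-sided definition (the p-value
sums the null probabilities of all outcomes no more probable than the one
observed), the convention of mainstream statistical software.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Iterable

import numpy as np
from scipy import stats

from .trial_model import StudyDataset, TrialRecord, ValidationError

#: consistency comparison -> the two encounter indices it contrasts
COMPARISON_ENCOUNTERS = {
    "first_two_encounters": (1, 2),
    "across_conditions": (2, 3),  # last transparent vs first concealed
    "within_concealed": (3, 4),
}


@dataclass
class ConsistencySummary:
    comparison_label: str
    n_pairs: int
    n_consistent: int
    p_value: float
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def proportion(self) -> float:
        return self.n_consistent / self.n_pairs


@dataclass
class BiasSummary:
    n_trials: int
    n_ingredient: int
    n_mix: int
    p_value: float


def binom_exact_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p-value, minimum-likelihood definition.

    Sums Pr(X = j | n, p0) over every outcome j whose point probability does
    not exceed that of the observed k (up to a 1e-7 relative tolerance for
    floating-point ties, as in standard implementations).
    """
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ValueError("k and n must be integers")
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"null probability must be in (0,1), got {p0}")
    probs = stats.binom.pmf(np.arange(n + 1), n, p0)
    p = probs[probs <= probs[k] * (1 + 1e-7)].sum()
    if p >= 1.0 - 1e-9:  # full-mass sum accumulates rounding below 1
        return 1.0
    return float(p)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]]."""
    cells = (a, b, c, d)
    if any(x < 0 or x != int(x) for x in cells):
        raise ValueError(f"cell counts must be non-negative integers, got {cells}")
    if sum(cells) == 0:
        raise ValueError("all-zero table")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def chosen_by_encounter(
    ds: StudyDataset,
) -> dict[tuple[str, str], dict[int, str]]:
    """Map AF-test pair -> {encounter_index: chosen item id}."""
    out: dict[tuple[str, str], dict[int, str]] = {}
    for t in ds.phase_trials("af_test"):
        if t.encounter_index is None:
            raise ValidationError("encounter indices not derived; run derive_encounters")
        out.setdefault(t.pair_key, {})[t.encounter_index] = t.chosen  # type: ignore[assignment]
    return out


def pair_consistency(ds: StudyDataset, comparison: str) -> ConsistencySummary:
    """Count pairs chosen identically on the comparison's two encounters.

    Pairs missing either required encounter are excluded and reported in the
    summary, never silently dropped.  The p-value is the exact two-sided
    binomial probability of the consistent count against chance 0.5.
    """
    if comparison not in COMPARISON_ENCOUNTERS:
        raise ValueError(
            f"unknown comparison {comparison!r}; one of {sorted(COMPARISON_ENCOUNTERS)}"
        )
    e1, e2 = COMPARISON_ENCOUNTERS[comparison]
    consistent = 0
    eligible = 0
    excluded = []
    for pair, enc in sorted(chosen_by_encounter(ds).items()):
        if e1 in enc and e2 in enc:
            eligible += 1
            consistent += int(enc[e1] == enc[e2])
        else:
            excluded.append(pair)
    if eligible == 0:
        raise ValidationError(f"no pair has both encounters {e1} and {e2}")
    return ConsistencySummary(
        comparison_label=comparison,
        n_pairs=eligible,
        n_consistent=consistent,
        p_value=binom_exact_two_sided(consistent, eligible, 0.5),
        excluded_pairs=excluded,
    )


def consistency_table(ds: StudyDataset):
    """All three standard comparisons, as rows of (label, %, p)."""
    import pandas as pd

    rows = []
    for label in COMPARISON_ENCOUNTERS:
        s = pair_consistency(ds, label)
        rows.append(
            {
                "comparison": label,
                "n_pairs": s.n_pairs,
                "n_consistent": s.n_consistent,
                "percent_consistent": 100.0 * s.proportion,
                "p_value": s.p_value,
            }
        )
    return pd.DataFrame(rows)


def ingredient_vs_mix_bias(
    ds: StudyDataset, scope=None
) -> BiasSummary:
    """Test for a novelty/volume bias: ingredient vs mix choice counts.

    In every AF-test trial one option is a familiar 10-ml ingredient and the
    other a novel 20-ml mix, so a preference for novelty or for the larger
    portion both surface as a skewed ingredient/mix choice ratio.
    """
    trials = [t for t in ds.phase_trials("af_test") if scope is None or scope(t)]
    if not trials:
        raise ValidationError("no AF-test trials in scope")
    n_mix = sum(1 for t in trials if ds.items[t.chosen].kind == "mix")
    n_ing = len(trials) - n_mix
    p = binom_exact_two_sided(min(n_ing, n_mix), len(trials), 0.5)
    return BiasSummary(n_trials=len(trials), n_ingredient=n_ing, n_mix=n_mix, p_value=p)


def _offer_choice_counts(trials: Iterable[TrialRecord], item: str) -> tuple[int, int]:
    offered = chosen = 0
    for t in trials:
        if item in (t.left_item, t.right_item):
            offered += 1
            chosen += int(t.chosen == item)
    return offered, chosen


def cross_setup_stability(ds: StudyDataset, item: str) -> float:
    """Fisher p for an item's choice rate in blocked vs randomised familiarisation.

    A non-significant p for every ingredient indicates preferences were stable
    across the two familiarisation set-ups, i.e. the subject was sufficiently
    familiarised before testing.
    """
    blocked = ds.phase_trials("familiarisation_blocked")
    random_ = ds.phase_trials("familiarisation_random")
    ob, cb = _offer_choice_counts(blocked, item)
    orr, cr = _offer_choice_counts(random_, item)
    if ob == 0 or orr == 0:
        raise ValidationError(f"item {item!r} absent from a familiarisation phase")
    return fisher_exact_2x2(cb, ob - cb, cr, orr - cr)


def colour_bias_check(
    original: Iterable[TrialRecord],
    reversed_: Iterable[TrialRecord],
    sweet_ids: set[str],
) -> dict:
    """Compare sweet-vs-sour choice rates across two colour schemes.

    2x2 Fisher table: colour scheme x (sweet chosen, sour chosen).  Returns
    the p-value and the per-scheme sweet-choice percentages.
    """
    original = list(original)
    reversed_ = list(reversed_)
    if not original or not reversed_:
        raise ValidationError("both colour-scheme trial sets must be non-empty")

    def sweet_count(trials):
        return sum(1 for t in trials if t.chosen in sweet_ids)

    so, sr = sweet_count(original), sweet_count(reversed_)
    p = fisher_exact_2x2(so, len(original) - so, sr, len(reversed_) - sr)
    return {
        "p_value": p,
        "n_original": len(original),
        "n_reversed": len(reversed_),
        "percent_sweet_original": 100.0 * so / len(original),
        "percent_sweet_reversed": 100.0 * sr / len(reversed_),
    }
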