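"""Choice-derived preference scores and rankings.

The preference score of an item over a set of trials is the proportion of
times it was chosen out of all occasions on which it was offered — the
"percentage chosen of occasions encountered" statistic used throughout the
study.  Three trial scopes matter downstream: the first two encounters with
each novel ingredient-mix pair, the concealed trials only, and all test
trials.
"""

from __future__ import annotations

import logging
from collections.abc import Callable, Iterable

import pandas as pd

from .trial_model import StudyDataset, TrialRecord

log = logging.getLogger(__name__)

Scope = Callable[[TrialRecord], bool]


def scope_first_two(t: TrialRecord) -> bool:
    """First and second encounters with each AF-test pair."""
    return t.phase == "af_test" and t.encounter_index in (1, 2)


def scope_concealed(t: TrialRecord) -> bool:
    return t.phase == "af_test" and t.condition == "concealed"


def scope_all_test(t: TrialRecord) -> bool:
    return t.phase == "af_test"


SCOPES: dict[str, Scope] = {
    "first_two": scope_first_two,
    "concealed": scope_concealed,
    "all_test": scope_all_test,
}


def preference_scores(
    trials: Iterable[TrialRecord],
    scope: Scope | None = None,
    items: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Tally offered/chosen counts and scores per item.

    Parameters
    ----------
    trials
        Trial records (must have choices recorded).
    scope
        Optional predicate restricting which trials are counted.
    items
        Items to include even if never offered in scope; such items get
        ``offered = 0`` and a missing (NaN) score.

    Returns
    -------
    DataFrame indexed by item id with columns ``offered``, ``chosen``,
    ``score``.  ``score = chosen / offered`` where defined.
    """
    in_scope = [t for t in trials if scope is None or scope(t)]
    if not in_scope:
        log.warning("preference_scores: empty trial scope")
    counts: dict[str, list[int]] = {}
    for iid in items or ():
        counts[iid] = [0, 0]
    for t in in_scope:
        if t.chosen is None:
            raise ValueError(f"trial {t.trial_index} in phase {t.phase} has no choice")
        for iid in (t.left_item, t.right_item):
            counts.setdefault(iid, [0, 0])[0] += 1
        counts[t.chosen][1] += 1
    table = pd.DataFrame(
        {
            "offered": {k: v[0] for k, v in counts.items()},
            "chosen": {k: v[1] for k, v in counts.items()},
        }
    ).sort_index()
    table.index.name = "item"
    table["score"] = table["chosen"] / table["offered"]
    return table


def ranking(prefs: pd.DataFrame) -> pd.DataFrame:
    """Append a ``rank`` column, 1 = most preferred, average ranks for ties.

    Tied scores deliberately share the average of the ranks they cover: the
    downstream tau-b correlation relies on tie information being preserved.
    """
    if prefs["score"].isna().any():
        bad = list(prefs.index[prefs["score"].isna()])
        raise ValueError(f"cannot rank items with undefined scores: {bad}")
    out = prefs.copy()
    out["rank"] = out["score"].rank(ascending=False, method="average")
    return out.sort_values(["rank", "item"] if "item" in out.columns else "rank")


def scores_by_scope(ds: StudyDataset) -> dict[str, pd.DataFrame]:
    """Ranked preference tables for the three standard AF-test scopes."""
    all_items = sorted(ds.items)
    return {
        name: ranking(preference_scores(ds.trials, scope, items=all_items))
        for name, scope in SCOPES.items()
    }
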