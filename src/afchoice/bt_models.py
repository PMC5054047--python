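"""Bradley-Terry models of pairwise choice, with a phase-split variant.

The Bradley-Terry model assigns each item i a positive worth w_i and sets
Pr(i chosen over j) = w_i / (w_i + w_j); on the log scale used here,
Pr = logistic(lw_i - lw_j).  One item's log-worth is pinned to 0 for
identifiability.

Two nested specifications are compared:

* ``constant`` (model A) — one worth per item across all fitted trials,
  consistent with choices among novel mixes being driven by stable hedonic
  predictions formed before the first taste.
* ``split_first_two`` (model B) — the six mixes get a *separate* worth for
  the first two encounters with each novel ingredient-mix pair, as expected
  if early choices were trial-and-error rather than prediction.  Ingredients
  are familiar throughout and keep a single worth, so model B adds exactly
  six parameters.

Model selection uses AIC, BIC (n = number of binary choices) and the
likelihood-ratio test with df = the number of extra worths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from collections.abc import Iterable, Mapping

import numpy as np
from scipy import optimize, stats

from .trial_model import StudyDataset, TrialRecord, ValidationError

WORTH_CAP = 20.0  # |log-worth| bound; reached only under perfect separation

#: slot tag for the separate early-encounter worth of a phased item
EARLY = "first_two"
LATE = "all"


@dataclass(frozen=True)
class BTSpec:
    """Model structure: items, phase structure, identifiability constraint."""

    items: tuple[str, ...]
    phase_structure: str = "constant"  # "constant" | "split_first_two"
    reference_item: str | None = None
    phased_items: tuple[str, ...] = ()

    def __post_init__(self):
        if self.phase_structure not in ("constant", "split_first_two"):
            raise ValueError(f"unknown phase structure {self.phase_structure!r}")
        ref = self.reference_item if self.reference_item is not None else sorted(self.items)[0]
        object.__setattr__(self, "reference_item", ref)
        if ref not in self.items:
            raise ValueError(f"reference item {ref!r} not among items")
        if self.phase_structure == "constant" and self.phased_items:
            raise ValueError("constant structure admits no phased items")
        bad = set(self.phased_items) - set(self.items)
        if bad:
            raise ValueError(f"phased items {sorted(bad)} not among items")
        if ref in self.phased_items:
            raise ValueError("reference item cannot be phased")

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return len(self.items) - 1 + len(self.phased_items)

    def slots(self) -> list[tuple[str, str]]:
        """All worth slots, the reference's (fixed at 0) first."""
        base = [(i, LATE) for i in self.items]
        early = [(i, EARLY) for i in self.phased_items]
        return base + early

    def slot_of(self, trial: TrialRecord, item: str) -> tuple[str, str]:
        if item not in self.items:
            raise ValidationError(
                f"trial {trial.trial_index} ({trial.phase}) references item {item!r} "
                "not in the model spec"
            )
        if (
            self.phase_structure == "split_first_two"
            and item in self.phased_items
            and trial.phase == "af_test"
            and trial.encounter_index is not None
            and trial.encounter_index <= 2
        ):
            return (item, EARLY)
        return (item, LATE)


@dataclass
class BTFit:
    spec: BTSpec
    log_worths: dict[tuple[str, str], float]
    loglik: float
    n_choices: int
    converged: bool

    @property
    def k(self) -> int:
        return self.spec.k

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik

    @property
    def bic(self) -> float:
        return self.k * np.log(self.n_choices) - 2 * self.loglik


def choice_prob(lw_i: float, lw_j: float) -> float:
    """Pr(item with log-worth lw_i is chosen over one with lw_j)."""
    lw_i, lw_j = float(lw_i), float(lw_j)
    if not (np.isfinite(lw_i) and np.isfinite(lw_j)):
        raise ValueError("log-worths must be finite")
    d = np.clip(lw_i - lw_j, -745.0, 745.0)
    return float(1.0 / (1.0 + np.exp(-d)))


def bt_fit_scope(ds: StudyDataset) -> list[TrialRecord]:
    """The trials entering the model fits: AF-test first-two encounters plus
    all post-experimental pairwise trials."""
    return [
        t
        for t in ds.trials
        if (t.phase == "af_test" and t.encounter_index in (1, 2))
        or t.phase == "post_experimental"
    ]


def _design(spec: BTSpec, trials: list[TrialRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Per trial, the parameter indices of the chosen and unchosen slots.

    Index -1 denotes the reference slot (log-worth fixed at 0).
    """
    slot_index: dict[tuple[str, str], int] = {}
    j = 0
    for slot in spec.slots():
        if slot == (spec.reference_item, LATE):
            slot_index[slot] = -1
        else:
            slot_index[slot] = j
            j += 1
    chosen_ix = np.empty(len(trials), dtype=int)
    other_ix = np.empty(len(trials), dtype=int)
    for row, t in enumerate(trials):
        if t.chosen is None:
            raise ValidationError(f"trial {t.trial_index} in {t.phase} has no recorded choice")
        unchosen = t.right_item if t.chosen == t.left_item else t.left_item
        chosen_ix[row] = slot_index[spec.slot_of(t, t.chosen)]
        other_ix[row] = slot_index[spec.slot_of(t, unchosen)]
    return chosen_ix, other_ix


def _nll_grad(theta: np.ndarray, chosen_ix: np.ndarray, other_ix: np.ndarray):
    lw = np.concatenate([theta, [0.0]])  # index -1 -> reference at 0
    d = lw[chosen_ix] - lw[other_ix]
    nll = np.logaddexp(0.0, -d).sum()
    q = -1.0 / (1.0 + np.exp(d))  # d nll / d d_row
    grad = np.zeros(len(theta) + 1)
    np.add.at(grad, chosen_ix, q)
    np.add.at(grad, other_ix, -q)
    return nll, grad[:-1]


def neg_loglik(
    log_worths: Mapping[tuple[str, str], float] | Mapping[str, float],
    trials: Iterable[TrialRecord],
    spec: BTSpec,
) -> float:
    """Negative log-likelihood of the choices under given log-worths.

    ``log_worths`` maps slots (item, phase-slot) — or plain item ids for a
    constant-structure spec — to log-worths.  Invariant under adding a common
    constant to every slot.
    """
    trials = list(trials)
    lw = {}
    for key, v in log_worths.items():
        lw[(key, LATE) if isinstance(key, str) else key] = float(v)
    total = 0.0
    for t in trials:
        unchosen = t.right_item if t.chosen == t.left_item else t.left_item
        try:
            a = lw[spec.slot_of(t, t.chosen)]
            b = lw[spec.slot_of(t, unchosen)]
        except KeyError as exc:
            raise ValidationError(
                f"no log-worth for slot {exc.args[0]} (trial {t.trial_index}, {t.phase})"
            ) from exc
        total += np.logaddexp(0.0, -(a - b))
    return float(total)


def fit(spec: BTSpec, trials: Iterable[TrialRecord]) -> BTFit:
    """Maximum-likelihood fit with the reference log-worth fixed at 0.

    Deterministic: zero initialisation, L-BFGS-B with tight tolerances, and
    log-worths bounded at +/-20 so perfectly separated items (always or never
    chosen) saturate at the cap with a warning instead of diverging.
    """
    trials = list(trials)
    if not trials:
        raise ValidationError("cannot fit a Bradley-Terry model to zero trials")
    chosen_ix, other_ix = _design(spec, trials)

    n_param = spec.k
    appearances = np.bincount(
        np.concatenate([chosen_ix, other_ix]) % (n_param + 1), minlength=n_param + 1
    )
    wins = np.bincount(chosen_ix % (n_param + 1), minlength=n_param + 1)
    slots = [s for s in spec.slots() if s != (spec.reference_item, LATE)]
    for j, slot in enumerate(slots):
        if appearances[j] == 0:
            raise ValidationError(f"slot {slot} never appears in the fitted trials")
        if wins[j] == 0 or wins[j] == appearances[j]:
            warnings.warn(
                f"perfect separation for slot {slot}: "
                f"chosen {wins[j]} of {appearances[j]}; log-worth capped at +/-{WORTH_CAP}",
                stacklevel=2,
            )

    res = optimize.minimize(
        _nll_grad,
        np.zeros(n_param),
        args=(chosen_ix, other_ix),
        jac=True,
        method="L-BFGS-B",
        bounds=[(-WORTH_CAP, WORTH_CAP)] * n_param,
        options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-10},
    )
    _, grad = _nll_grad(res.x, chosen_ix, other_ix)
    at_bound = np.abs(res.x) >= WORTH_CAP - 1e-6
    converged = bool(res.success or np.linalg.norm(grad[~at_bound], np.inf) < 1e-8)
    if not converged:
        warnings.warn(f"Bradley-Terry fit did not converge: {res.message}", stacklevel=2)

    log_worths = {(spec.reference_item, LATE): 0.0}
    for j, slot in enumerate(slots):
        log_worths[slot] = float(res.x[j])
    return BTFit(
        spec=spec,
        log_worths=log_worths,
        loglik=-float(res.fun),
        n_choices=len(trials),
        converged=converged,
    )


@dataclass
class ModelComparison:
    delta_aic: float  # AIC(B) - AIC(A)
    delta_bic: float
    lrt_stat: float
    df: int
    lrt_p: float
    preferred_by: dict[str, str]


def chi2_sf(x: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution."""
    if x < 0:
        raise ValueError(f"chi-square statistic must be >= 0, got {x}")
    if df < 1 or df != int(df):
        raise ValueError(f"df must be a positive integer, got {df}")
    return float(stats.chi2.sf(x, df))


def compare_models(fitA: BTFit, fitB: BTFit, alpha: float = 0.05) -> ModelComparison:
    """Compare the constant model (A) with the phase-split model (B).

    A must be nested in B (same trials, same items and reference, constant
    within split_first_two).  Reports AIC/BIC differences, the likelihood
    ratio statistic with df = k_B - k_A, and which model each measure prefers.
    """
    a, b = fitA.spec, fitB.spec
    if a.phase_structure != "constant" or b.phase_structure != "split_first_two":
        raise ValueError("expected fitA constant and fitB split_first_two")
    if set(a.items) != set(b.items) or a.reference_item != b.reference_item:
        raise ValueError("models are not nested: different items or reference")
    if fitA.n_choices != fitB.n_choices:
        raise ValueError(
            f"models fitted to different data: n={fitA.n_choices} vs {fitB.n_choices}"
        )
    if fitB.k <= fitA.k:
        raise ValueError("model B must have more parameters than model A")

    lrt = 2.0 * (fitB.loglik - fitA.loglik)
    if lrt < -1e-6:
        raise ValueError(f"nested model B fits worse than A (lrt = {lrt:.3g}); check convergence")
    lrt = max(lrt, 0.0)
    df = fitB.k - fitA.k
    p = chi2_sf(lrt, df)
    return ModelComparison(
        delta_aic=fitB.aic - fitA.aic,
        delta_bic=fitB.bic - fitA.bic,
        lrt_stat=lrt,
        df=df,
        lrt_p=p,
        preferred_by={
            "aic": "A" if fitA.aic <= fitB.aic else "B",
            "bic": "A" if fitA.bic <= fitB.bic else "B",
            "lrt": "B" if p < alpha else "A",
        },
    )


def standard_specs(ds: StudyDataset, reference_item: str | None = None) -> tuple[BTSpec, BTSpec]:
    """The study's model pair for a dataset: constant vs mix-split specs."""
    items = tuple(sorted(ds.items))
    ref = reference_item if reference_item is not None else ds.ingredients()[0]
    spec_a = BTSpec(items=items, phase_structure="constant", reference_item=ref)
    spec_b = BTSpec(
        items=items,
        phase_structure="split_first_two",
        reference_item=ref,
        phased_items=tuple(ds.mixes()),
    )
    return spec_a, spec_b
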