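"""Rank association between test-derived and post-experimental preferences.

The study's key validity check correlates choice-derived preference scores
from the AF test with independently collected post-experimental preferences
(pairwise-choice scores for the orangutan design, 1-10 self-report ranks for
the humans).  Because the data are small, discrete, and tied, the
tie-corrected Kendall tau-b is used, with significance from a permutation
test rather than asymptotics.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats


def harmonize_self_report(ranks) -> dict[str, float] | np.ndarray:
    """Convert self-report ranks (1 = most preferred) to higher-is-better values.

    ``value = n + 1 - rank`` so that the most preferred of n items scores n.
    Accepts a mapping item -> rank or a sequence of ranks; returns the same
    shape.  The ranks must be a permutation of 1..n.
    """
    if isinstance(ranks, dict):
        keys = list(ranks)
        values = harmonize_self_report(np.array([ranks[k] for k in keys]))
        return dict(zip(keys, values.tolist()))
    arr = np.asarray(ranks)
    n = len(arr)
    if sorted(arr.tolist()) != list(range(1, n + 1)):
        raise ValueError(f"self-report ranks must be a permutation of 1..{n}, got {arr.tolist()}")
    return (n + 1 - arr).astype(float)


def kendall_tau_b(x, y) -> float:
    """Tie-corrected Kendall rank correlation.

    tau_b = (C - D) / sqrt((n0 - t_x)(n0 - t_y)) with n0 = n(n-1)/2, C and D
    the concordant/discordant pair counts, and t_x, t_y the numbers of tied
    pairs within x and within y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-d arrays with n >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("tau-b is undefined when x or y is constant")
    tau = stats.kendalltau(x, y).statistic
    return float(tau)


def tau_b_pvalue(
    x,
    y,
    method: str = "exact_permutation",
    n_resamples: int = 100_000,
    seed: int = 0,
) -> float:
    """Two-sided significance of tau-b under random relabelling of y.

    ``exact_permutation`` enumerates all n! orderings of y for n <= 8; for
    larger n it draws ``n_resamples`` seeded random permutations (with the
    +1 correction so p > 0).  ``normal_approx`` is the tie-corrected
    asymptotic test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if method == "normal_approx":
        return float(stats.kendalltau(x, y).pvalue)
    if method != "exact_permutation":
        raise ValueError(f"unknown method {method!r}")
    if n < 3:
        raise ValueError("permutation test needs n >= 3")

    # the tie counts (hence tau-b's denominator) are invariant under
    # relabelling of y, so |tau*| >= |tau_obs| iff |C* - D*| >= |C - D|:
    # only the concordance sum over pairs needs recomputing per permutation
    kendall_tau_b(x, y)  # raises on degenerate input
    iu, ju = np.triu_indices(n, k=1)
    sx = np.sign(x[iu] - x[ju])

    def concordance(yy: np.ndarray) -> float:
        return float(np.sum(sx * np.sign(yy[iu] - yy[ju])))

    observed = abs(concordance(y))
    tol = 1e-9
    if n <= 8:
        hits = total = 0
        for perm in itertools.permutations(y):
            total += 1
            if abs(concordance(np.array(perm))) >= observed - tol:
                hits += 1
        return hits / total
    rng = np.random.default_rng(seed)
    hits = 0
    yy = y.copy()
    for _ in range(n_resamples):
        rng.shuffle(yy)
        if abs(concordance(yy)) >= observed - tol:
            hits += 1
    return (hits + 1) / (n_resamples + 1)
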