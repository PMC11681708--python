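"""Variable-ratio greedy caliper matching on the propensity score, plus
covariate-balance and representativeness diagnostics.

Matching is greedy on the logit-PS scale with a caliper of 0.2 pooled
logit-PS standard deviations.  Variable 1:cap ratios are built in
sequential rounds: in round r every still-eligible target (visited in a
seeded shuffled order, fixed across rounds) claims its nearest unmatched
comparator within the caliper; targets that find no comparator in round 1
are excluded from the matched cohort.  Nearest-distance ties are broken
toward the comparator with the lower input ordinal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logit


@dataclass
class MatchedCohort:
    """Matched strata: one target plus 1..ratio_cap comparators each."""

    rows: pd.DataFrame                # columns: person_idx, stratum_id, treated
    ratio_cap: int
    caliper_logit: float              # absolute caliper width on the logit scale
    n_target_matched: int
    n_comparator_matched: int

    def person_indices(self) -> np.ndarray:
        return self.rows["person_idx"].to_numpy()


def match_variable_ratio(scores: np.ndarray, arms: np.ndarray,
                         ratio_cap: int = 10, caliper: float = 0.2,
                         seed: int = 0) -> MatchedCohort:
    """Greedy variable-ratio caliper matching.

    Parameters
    ----------
    scores : propensity scores in (0,1), one per person.
    arms : boolean vector, True = target.
    ratio_cap : maximum comparators per target (1 gives 1:1 matching).
    caliper : width in units of the SD of logit(scores) over all persons.

    Returns a MatchedCohort whose `rows` reference positions in the input
    arrays.  Raises if no target can be matched.
    """
    scores = np.asarray(scores, dtype=float)
    arms = np.asarray(arms, dtype=bool)
    if np.any(scores <= 0) or np.any(scores >= 1):
        raise ValueError("scores must lie strictly in (0,1)")
    if not arms.any() or arms.all():
        raise ValueError("both arms must be non-empty")
    ls = logit(scores)
    width = caliper * float(np.std(ls))

    t_idx = np.nonzero(arms)[0]
    c_idx = np.nonzero(~arms)[0]
    order = np.random.default_rng(seed).permutation(len(t_idx))

    # comparators sorted by logit score; availability tracked with a
    # doubly-linked list over the sorted order so "nearest unmatched"
    # stays O(1) amortized.  Sort ties by input ordinal so that the
    # documented tie-break (lower ordinal wins) is what the walk finds.
    c_sort = np.lexsort((c_idx, ls[c_idx]))
    c_sorted_vals = ls[c_idx][c_sort]
    c_sorted_ids = c_idx[c_sort]
    m = len(c_sort)
    left = np.arange(-1, m)            # nearest-alive neighbour pointers
    right = np.arange(1, m + 1)
    alive = np.ones(m, dtype=bool)

    def _nearest_alive(pos: int) -> tuple[int, int]:
        """Alive slots flanking insertion point `pos` (-1 / m = none)."""
        li = pos - 1
        while li >= 0 and not alive[li]:
            li = left[li]
        ri = pos
        while ri < m and not alive[ri]:
            ri = right[ri]
        return li, ri

    def _claim(slot: int) -> None:
        alive[slot] = False
        li, ri = left[slot], right[slot]
        if ri < m:
            left[ri] = li
        if li >= 0:
            right[li] = ri

    matched_targets: list[int] = []
    strata: dict[int, list[int]] = {}
    excluded = np.zeros(len(t_idx), dtype=bool)

    for r in range(ratio_cap):
        any_claim = False
        for oi in order:
            if excluded[oi]:
                continue
            v = ls[t_idx[oi]]
            pos = int(np.searchsorted(c_sorted_vals, v))
            li, ri = _nearest_alive(pos)
            dl = v - c_sorted_vals[li] if li >= 0 else np.inf
            dr = c_sorted_vals[ri] - v if ri < m else np.inf
            if dl < dr:
                slot = li
            elif dr < dl:
                slot = ri
            elif np.isinf(dl):
                slot = -1
            else:  # exact tie: lower input ordinal wins
                slot = li if c_sorted_ids[li] < c_sorted_ids[ri] else ri
            if slot < 0 or min(dl, dr) > width:
                if r == 0:
                    excluded[oi] = True
                continue
            _claim(slot)
            strata.setdefault(oi, []).append(int(c_sorted_ids[slot]))
            any_claim = True
        if not any_claim:
            break

    if not strata:
        raise ValueError("empty matched cohort: no target matched within caliper")

    recs = []
    for stratum_id, oi in enumerate(sorted(strata)):
        recs.append((int(t_idx[oi]), stratum_id, True))
        for cid in strata[oi]:
            recs.append((cid, stratum_id, False))
    rows = pd.DataFrame(recs, columns=["person_idx", "stratum_id", "treated"])
    return MatchedCohort(rows=rows, ratio_cap=ratio_cap, caliper_logit=width,
                         n_target_matched=len(strata),
                         n_comparator_matched=int((~rows["treated"]).sum()))


def standardized_difference(p1: float, p2: float,
                            v1: float | None = None,
                            v2: float | None = None) -> float:
    """Absolute standardized difference (ASD).

    For binary covariates pass prevalences only: |p1-p2| in units of the
    pooled Bernoulli SD.  For continuous covariates pass means and
    variances.  Defined as 0 when both variances vanish and the means
    agree, and infinity when both variances vanish but the means differ.
    """
    if v1 is None:
        v1, v2 = p1 * (1 - p1), p2 * (1 - p2)
    pooled = (v1 + v2) / 2.0
    diff = abs(p1 - p2)
    if pooled == 0:
        return 0.0 if diff == 0 else float("inf")
    return float(diff / np.sqrt(pooled))


def _prevalences(cov: "np.ndarray | object", rows: np.ndarray) -> np.ndarray:
    sub = cov[rows]
    return np.asarray(sub.mean(axis=0)).ravel()


def covariate_balance(covariates, arms: np.ndarray,
                      matched: MatchedCohort,
                      covariate_ids: np.ndarray | None = None) -> pd.DataFrame:
    """Before/after-matching prevalence and ASD for every covariate.

    `covariates` is the full (persons x covariates) matrix; `arms` the
    full boolean target indicator; `matched` identifies the after-matching
    persons by position.
    """
    arms = np.asarray(arms, dtype=bool)
    n_cov = covariates.shape[1]
    if covariate_ids is None:
        covariate_ids = np.arange(n_cov)
    t_before = _prevalences(covariates, np.nonzero(arms)[0])
    c_before = _prevalences(covariates, np.nonzero(~arms)[0])
    midx = matched.rows["person_idx"].to_numpy()
    mt = matched.rows["treated"].to_numpy()
    t_after = _prevalences(covariates, midx[mt])
    c_after = _prevalences(covariates, midx[~mt])

    def _asd(p1, p2):
        pooled = (p1 * (1 - p1) + p2 * (1 - p2)) / 2.0
        diff = np.abs(p1 - p2)
        with np.errstate(divide="ignore", invalid="ignore"):
            asd = diff / np.sqrt(pooled)
        asd[(pooled == 0) & (diff == 0)] = 0.0
        asd[(pooled == 0) & (diff > 0)] = np.inf
        return asd

    return pd.DataFrame({
        "covariate_id": covariate_ids,
        "target_prev_before": t_before, "comparator_prev_before": c_before,
        "target_prev_after": t_after, "comparator_prev_after": c_after,
        "before_asd": _asd(t_before, c_before),
        "after_asd": _asd(t_after, c_after),
    })


def balance_gate(balance: pd.DataFrame, threshold: float = 0.1
                 ) -> tuple[bool, float]:
    """Pass iff the largest after-matching ASD is strictly below threshold.

    Returns (passed, d_max)."""
    if len(balance) == 0:
        raise ValueError("empty balance report")
    d_max = float(balance["after_asd"].max())
    return bool(d_max < threshold), d_max


def representativeness_report(covariates, initial_rows: np.ndarray,
                              analytic_rows: np.ndarray,
                              covariate_ids: np.ndarray | None = None
                              ) -> pd.DataFrame:
    """Initial-vs-analytic target cohort prevalences with ASDs.

    Purely descriptive: the study protocol attaches no pass/fail threshold
    to representativeness.
    """
    n_cov = covariates.shape[1]
    if covariate_ids is None:
        covariate_ids = np.arange(n_cov)
    p_init = _prevalences(covariates, np.asarray(initial_rows))
    p_analytic = _prevalences(covariates, np.asarray(analytic_rows))
    asd = np.array([standardized_difference(a, b)
                    for a, b in zip(p_init, p_analytic)])
    return pd.DataFrame({"covariate_id": covariate_ids,
                         "initial_target_prev": p_init,
                         "analytic_target_prev": p_analytic,
                         "asd": asd})
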