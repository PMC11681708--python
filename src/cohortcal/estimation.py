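"""Matched-set Cox estimation, incidence rates, and minimum detectable RR.

The hazard-ratio estimator is a Cox proportional-hazards partial
likelihood conditioned on the matched sets (one stratum per matched set)
with treatment status as the sole covariate.  Because the covariate is a
single 0/1 indicator, the score and information reduce to closed-form
sums over per-stratum risk sets, so the maximizer is found by a scalar
Newton iteration over precomputed (stratum x event-day) risk-set counts.
Tied event days — guaranteed by day-granularity data — are handled with
the Efron approximation (Breslow available for comparison).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohorts_tar import DAYS_PER_YEAR

Z_975 = 1.959964


class InestimableError(ValueError):
    """No informative stratum: the partial likelihood carries no signal."""


@dataclass
class EstimationResult:
    """One uncalibrated comparative estimate with its bookkeeping."""

    log_hr: float
    se_log_hr: float
    hr: float
    ci95_low: float
    ci95_high: float
    p_value: float
    target_events: int
    comparator_events: int
    target_py: float
    comparator_py: float
    ir_target_per_1k: float
    ir_comparator_per_1k: float
    mdrr: float
    converged: bool = True
    n_strata_informative: int = 0
    n_strata_dropped: int = 0


def _risk_set_counts(stratum: np.ndarray, treated: np.ndarray,
                     time: np.ndarray, event: np.ndarray):
    """Per (stratum, event time): at-risk counts by arm and tied events.

    Returns arrays (R1, R0, d, d1) over event-time groups, where R1/R0
    count subjects at risk (time >= t) in the treated/control arm and
    d/d1 the tied events (total/treated) at that time.
    """
    df = pd.DataFrame({"s": stratum, "x": treated.astype(np.int64),
                       "t": time, "e": event.astype(np.int64)})
    df = df.sort_values(["s", "t"], ascending=[True, False], kind="mergesort")
    s = df["s"].to_numpy()
    x = df["x"].to_numpy()
    t = df["t"].to_numpy()
    e = df["e"].to_numpy()
    new_s = np.r_[True, s[1:] != s[:-1]]
    # cumulative at-risk counts within stratum, descending time
    grp = np.cumsum(new_s) - 1
    c1 = pd.Series(x).groupby(grp).cumsum().to_numpy()
    c0 = pd.Series(1 - x).groupby(grp).cumsum().to_numpy()
    # group rows by (stratum, time); at-risk = cumulative count at the last
    # row of the tie block (time sorted descending, so the block's end)
    new_block = new_s | np.r_[True, t[1:] != t[:-1]]
    block_id = np.cumsum(new_block) - 1
    bdf = pd.DataFrame({"b": block_id, "e": e, "ex": e * x,
                        "c1": c1, "c0": c0})
    agg = bdf.groupby("b").agg(d=("e", "sum"), d1=("ex", "sum"),
                               R1=("c1", "last"), R0=("c0", "last"))
    agg = agg[agg["d"] > 0]
    return (agg["R1"].to_numpy(np.float64), agg["R0"].to_numpy(np.float64),
            agg["d"].to_numpy(np.float64), agg["d1"].to_numpy(np.float64))


def _efron_terms(beta: float, R1, R0, d, d1, ties: str):
    """(loglik, score, information) of the stratified partial likelihood."""
    r = np.exp(beta)
    S0 = R0 + R1 * r
    S1 = R1 * r
    ll = float(np.sum(d1) * beta)
    U = float(np.sum(d1))
    I = 0.0
    max_d = int(d.max())
    for l in range(max_d):
        mask = d > l
        if ties == "efron":
            frac = l / d[mask]
            S0l = S0[mask] - frac * ((d[mask] - d1[mask]) + d1[mask] * r)
            S1l = S1[mask] - frac * d1[mask] * r
        else:  # breslow
            S0l, S1l = S0[mask], S1[mask]
        ratio = S1l / S0l
        ll -= float(np.sum(np.log(S0l)))
        U -= float(np.sum(ratio))
        I += float(np.sum(ratio * (1.0 - ratio)))
    return ll, U, I


def fit_stratified_cox(stratum: np.ndarray, treated: np.ndarray,
                       time: np.ndarray, event: np.ndarray,
                       ties: str = "efron", max_iter: int = 100,
                       tol: float = 1e-10) -> tuple[float, float]:
    """Maximize the matched-set-stratified Cox partial likelihood.

    Parameters are parallel per-record arrays: stratum id, treated flag,
    follow-up time in days (>= 1) and event indicator.  Returns
    (log_hr, se_log_hr).  Raises InestimableError when no stratum has an
    event together with subjects of both arms at risk, and warns on a
    monotone likelihood (all events in one arm), returning a diverged
    estimate flagged by a huge |log_hr|.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    time = np.asarray(time)
    if (time < 1).any():
        raise ValueError("survival times must be >= 1 day")
    R1, R0, d, d1 = _risk_set_counts(np.asarray(stratum),
                                     np.asarray(treated, dtype=bool),
                                     time, np.asarray(event, dtype=bool))
    informative = (R1 > 0) & (R0 > 0)
    if not informative.any():
        raise InestimableError("no stratum with an event and both arms at risk")
    R1, R0, d, d1 = R1[informative], R0[informative], d[informative], d1[informative]
    # monotone likelihood: every informative event is (or none is) treated
    if np.sum(d1) == 0 or np.sum(d1) == np.sum(d):
        warnings.warn("monotone partial likelihood (all events in one arm); "
                      "estimate diverges", RuntimeWarning, stacklevel=2)

    beta = 0.0
    for _ in range(max_iter):
        _, U, I = _efron_terms(beta, R1, R0, d, d1, ties)
        if I <= 0:
            break
        step = U / I
        beta += np.clip(step, -2.0, 2.0)
        if abs(step) < tol:
            break
        if abs(beta) > 25:
            break
    _, _, I = _efron_terms(beta, R1, R0, d, d1, ties)
    se = float(1.0 / np.sqrt(I)) if I > 0 else float("inf")
    return float(beta), se


def incidence_rate(events: int, person_days: float) -> float:
    """Events per 1,000 person-years."""
    if person_days <= 0:
        raise ValueError("person-time must be positive")
    return float(events / (person_days / DAYS_PER_YEAR) * 1000.0)


def minimum_detectable_rr(total_events: int, treated_persontime_fraction: float,
                          alpha: float = 0.05, power: float = 0.8) -> float:
    """Smallest hazard ratio detectable with the given power.

    Two-sided Wald calculation on the log scale with the variance of the
    log rate ratio approximated by 1/(E f (1-f)), E = total events and
    f = the treated fraction of person-time."""
    f = treated_persontime_fraction
    if not (0 < f < 1):
        raise ValueError("treated person-time fraction must be in (0,1)")
    if total_events <= 0:
        return float("inf")
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    return float(np.exp(z / np.sqrt(total_events * f * (1 - f))))


def nonzero_events_gate(target_events: int, comparator_events: int) -> bool:
    """Pass iff both arms observed at least one event during their TAR."""
    return target_events > 0 and comparator_events > 0


def overlay_outcome(tar: pd.DataFrame, outcomes: pd.DataFrame,
                    outcome_id: int) -> pd.DataFrame:
    """Attach first-event/censoring survival columns to a TAR table.

    Survival time counts days from TAR start, inclusive of the event day;
    persons whose first event falls outside their TAR are censored at TAR
    end.  Returns tar plus `event` (bool) and `time_days` (>= 1 whenever
    days_at_risk >= 1).
    """
    ev = (outcomes[outcomes["outcome_id"] == outcome_id]
          .groupby("person_id")["event_day"].min())
    t = tar.copy()
    eday = t["person_id"].map(ev)
    in_tar = eday.notna() & (eday >= t["tar_start_day"]) & (eday <= t["tar_end_day"])
    t["event"] = in_tar.to_numpy()
    t["time_days"] = np.where(in_tar,
                              (eday - t["tar_start_day"] + 1).fillna(0),
                              t["days_at_risk"]).astype(np.int64)
    return t


def estimate_hazard_ratio(survival: pd.DataFrame, ties: str = "efron"
                          ) -> EstimationResult:
    """Full matched-set estimate from a survival table.

    `survival` needs columns stratum_id, treated, time_days, event; rows
    with zero time at risk must have been dropped upstream.
    """
    t_mask = survival["treated"].to_numpy(bool)
    ev = survival["event"].to_numpy(bool)
    te, ce = int(ev[t_mask].sum()), int(ev[~t_mask].sum())
    t_days = float(survival.loc[t_mask, "time_days"].sum())
    c_days = float(survival.loc[~t_mask, "time_days"].sum())
    log_hr, se = fit_stratified_cox(survival["stratum_id"].to_numpy(),
                                    t_mask, survival["time_days"].to_numpy(),
                                    ev, ties=ties)
    hr = float(np.exp(log_hr))
    z = log_hr / se if se > 0 else np.inf
    frac = t_days / (t_days + c_days)
    return EstimationResult(
        log_hr=log_hr, se_log_hr=se, hr=hr,
        ci95_low=float(np.exp(log_hr - Z_975 * se)),
        ci95_high=float(np.exp(log_hr + Z_975 * se)),
        p_value=float(2 * stats.norm.sf(abs(z))),
        target_events=te, comparator_events=ce,
        target_py=t_days / DAYS_PER_YEAR, comparator_py=c_days / DAYS_PER_YEAR,
        ir_target_per_1k=incidence_rate(te, t_days),
        ir_comparator_per_1k=incidence_rate(ce, c_days),
        mdrr=minimum_detectable_rr(te + ce, frac),
        converged=bool(abs(log_hr) < 25))
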