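"""Negative-control estimation, the empirical null, EASE, and calibrated
hazard ratios.

Negative-control outcomes are presumed causally unrelated to either
exposure, so their estimated log hazard ratios measure residual
systematic error.  The empirical null models that error as
Normal(mu, sigma^2): each control's estimate b_i ~ N(mu, sigma^2 + tau_i^2)
where tau_i is its sampling SE, and (mu, sigma) are fit by maximum
likelihood — the same structure as the random-effects component of a
meta-analysis.  EASE (expected absolute systematic error) is the mean of
|error| under the fitted null, i.e. a folded-normal mean; analyses with
EASE > 0.25 fail the calibration diagnostic.  Calibration shifts an
estimate by mu and convolves its sampling error with sigma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .estimation import (InestimableError, Z_975, fit_stratified_cox,
                         nonzero_events_gate, overlay_outcome)


@dataclass
class NegativeControlEstimates:
    """Per-control Cox estimates; inestimable controls carry NaN."""

    estimates: pd.DataFrame   # outcome_id, log_hr, se, target_events, comparator_events, estimable
    n_attempted: int
    n_estimable: int

    def estimable(self) -> pd.DataFrame:
        return self.estimates[self.estimates["estimable"]]


@dataclass
class EmpiricalNull:
    """Fitted systematic-error distribution Normal(mu, sigma^2) and EASE."""

    mu: float
    sigma: float
    n_controls_used: int
    ease: float


@dataclass
class CalibratedResult:
    log_hr_cal: float
    se_cal: float
    hr_cal: float
    ci95_low: float
    ci95_high: float
    p_cal: float


def estimate_negative_controls(outcomes: pd.DataFrame, tar: pd.DataFrame,
                               matched_rows: pd.DataFrame,
                               persons: pd.DataFrame,
                               control_ids: np.ndarray | None = None
                               ) -> NegativeControlEstimates:
    """Run the matched-set Cox analysis on every negative-control outcome.

    Matching is outcome-independent and reused across controls; only the
    per-outcome prior-event exclusion and event overlay differ.  Controls
    failing the non-zero-events gate (or with an inestimable likelihood)
    are recorded but excluded from the null fit.

    Parameters
    ----------
    outcomes : OutcomeTable (outcome_id >= 1 are controls).
    tar : TAR table for (at least) all matched persons.
    matched_rows : person_id, stratum_id, treated for the matched cohort.
    persons : PersonTable (for index days, prior-event exclusion).
    """
    if control_ids is None:
        control_ids = np.sort(outcomes.loc[outcomes["outcome_id"] >= 1,
                                           "outcome_id"].unique())
    base = matched_rows.merge(tar, on="person_id")
    base = base.merge(persons[["person_id", "index_day"]], on="person_id")
    recs = []
    for oid in control_ids:
        ev = outcomes[outcomes["outcome_id"] == oid]
        first = base["person_id"].map(ev.groupby("person_id")["event_day"].min())
        sub = base[~(first.notna() & (first <= base["index_day"]))]
        surv = overlay_outcome(sub, outcomes, oid)
        surv = surv[surv["days_at_risk"] > 0]
        t_ev = int(surv.loc[surv["treated"], "event"].sum())
        c_ev = int(surv.loc[~surv["treated"], "event"].sum())
        rec = {"outcome_id": int(oid), "log_hr": np.nan, "se": np.nan,
               "target_events": t_ev, "comparator_events": c_ev,
               "estimable": False}
        if nonzero_events_gate(t_ev, c_ev):
            try:
                import warnings as _w
                with _w.catch_warnings():
                    _w.simplefilter("ignore", RuntimeWarning)
                    b, se = fit_stratified_cox(
                        surv["stratum_id"].to_numpy(),
                        surv["treated"].to_numpy(bool),
                        surv["time_days"].to_numpy(),
                        surv["event"].to_numpy(bool))
                if np.isfinite(b) and np.isfinite(se) and abs(b) < 25:
                    rec.update(log_hr=float(b), se=float(se), estimable=True)
            except InestimableError:
                pass
        recs.append(rec)
    est = pd.DataFrame(recs)
    n_est = int(est["estimable"].sum())
    if n_est == 0:
        raise InestimableError(
            "no estimable negative control: empirical null cannot be fit")
    return NegativeControlEstimates(estimates=est,
                                    n_attempted=len(control_ids),
                                    n_estimable=n_est)


def fit_empirical_null(estimates: NegativeControlEstimates | pd.DataFrame
                       ) -> EmpiricalNull:
    """Maximum-likelihood fit of the systematic-error distribution.

    Under b_i ~ N(mu, sigma^2 + tau_i^2) the profile is optimized over
    (mu, sigma >= 0) starting from the precision-weighted mean and a
    moment guess for sigma.
    """
    df = (estimates.estimable()
          if isinstance(estimates, NegativeControlEstimates) else estimates)
    b = df["log_hr"].to_numpy(float)
    tau = df["se"].to_numpy(float)
    if len(b) < 2:
        raise ValueError("need >= 2 estimable negative controls")
    if np.any(tau <= 0):
        raise ValueError("control SEs must be positive")

    w = 1.0 / tau**2
    mu0 = float(np.sum(w * b) / np.sum(w))
    sigma0 = float(max(1e-3, np.std(b, ddof=1) - np.mean(tau)))

    def nll(mu, sigma):
        v = sigma**2 + tau**2
        return 0.5 * np.sum(np.log(2 * np.pi * v) + (b - mu) ** 2 / v)

    # optimize over log sigma (smooth near the sigma=0 boundary), then
    # compare against the exact sigma=0 profile solution
    res = optimize.minimize(lambda th: nll(th[0], np.exp(th[1])),
                            x0=np.array([mu0, np.log(sigma0)]),
                            method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 2000})
    if not res.success:
        raise RuntimeError(f"empirical-null MLE failed: {res.message}")
    mu, sigma = float(res.x[0]), float(np.exp(res.x[1]))
    if sigma < 1e-8 or nll(mu0, 0.0) <= nll(mu, sigma):
        mu, sigma = mu0, 0.0
    return EmpiricalNull(mu=mu, sigma=sigma, n_controls_used=len(b),
                         ease=compute_ease(mu, sigma))


def compute_ease(mu: float, sigma: float) -> float:
    """Expected absolute systematic error: E|X|, X ~ N(mu, sigma^2).

    Folded-normal mean; degenerates to |mu| as sigma -> 0."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return abs(mu)
    return float(sigma * np.sqrt(2 / np.pi) * np.exp(-mu**2 / (2 * sigma**2))
                 + mu * (1 - 2 * stats.norm.cdf(-mu / sigma)))


def sigma_for_ease(ease: float, mu: float = 0.0) -> float:
    """Invert the folded-normal mean: sigma with compute_ease(mu, sigma)=ease."""
    if ease < abs(mu):
        raise ValueError("EASE cannot be below |mu|")
    if ease == abs(mu):
        return 0.0
    hi = (ease + abs(mu) + 1.0) * np.sqrt(np.pi / 2)
    return float(optimize.brentq(lambda s: compute_ease(mu, s) - ease, 1e-12, hi))


def null_coverage_interval(null: EmpiricalNull, level: float = 0.95
                           ) -> tuple[float, float]:
    """HR-scale interval holding `level` of the systematic error: under a
    true RR of 1 an observed RR falls here with that probability."""
    z = stats.norm.ppf(0.5 + level / 2)
    return (float(np.exp(null.mu - z * null.sigma)),
            float(np.exp(null.mu + z * null.sigma)))


def ease_gate(ease: float, threshold: float = 0.25) -> bool:
    """Pass iff EASE does not exceed the threshold."""
    return ease <= threshold


def calibrate_estimate(log_hr: float, se: float, null: EmpiricalNull
                       ) -> CalibratedResult:
    """Shift by the null mean and widen by the systematic-error SD.

    The systematic error is taken as additive and constant on the log-HR
    scale: log_hr_cal = log_hr - mu, se_cal = sqrt(se^2 + sigma^2)."""
    if se <= 0:
        raise ValueError("se must be positive")
    b = log_hr - null.mu
    s = float(np.sqrt(se**2 + null.sigma**2))
    z = b / s
    return CalibratedResult(log_hr_cal=float(b), se_cal=s,
                            hr_cal=float(np.exp(b)),
                            ci95_low=float(np.exp(b - Z_975 * s)),
                            ci95_high=float(np.exp(b + Z_975 * s)),
                            p_cal=float(2 * stats.norm.sf(abs(z))))
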