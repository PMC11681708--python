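"""End-to-end execution of one comparative analysis on one database.

Chains the stages in protocol order: TAR construction, design
restrictions, LSPS fit, equipoise, variable-ratio matching, balance,
outcome estimation, negative-control calibration, and the four-diagnostic
verdict.  The result dict plugs directly into synthesis.build_results_table.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import cohorts_tar, propensity, matching_balance, estimation, calibration
from .estimation import InestimableError
from .synthesis import Thresholds, apply_diagnostics
from .synthetic_data import SyntheticStudy


@dataclass(frozen=True)
class AnalysisSettings:
    """One analysis variant: PS strategy x TAR definition + knobs."""

    tar: str = "on_treatment"        # or "itt"
    ratio_cap: int = 10
    caliper: float = 0.2
    persistence_window: int = 90
    surveillance: int = 90
    cv_folds: int = 10
    prior_variance_grid: tuple[float, ...] = propensity.DEFAULT_PRIOR_VARIANCE_GRID
    seed: int = 0
    thresholds: Thresholds = Thresholds()

    @property
    def ps_strategy(self) -> str:
        return f"1:{self.ratio_cap}"


def run_analysis(study: SyntheticStudy,
                 settings: AnalysisSettings = AnalysisSettings(),
                 comparison: str = "target_vs_comparator",
                 database: str = "synthetic") -> dict:
    """Execute the full pipeline; returns a result dict with the verdict,
    the (possibly blinded) estimates, and all intermediate diagnostics."""
    persons = study.persons
    tar = cohorts_tar.build_tar_table(
        persons, study.administrations, study.censor_exposures,
        kind=settings.tar, persistence_window=settings.persistence_window,
        surveillance=settings.surveillance)
    analytic, attrition = cohorts_tar.apply_design_restrictions(
        persons, study.outcomes, tar)

    pos = pd.Series(np.arange(len(persons)), index=persons["person_id"])
    rows = pos[analytic["person_id"]].to_numpy()
    arms = (analytic["arm"] == "target").to_numpy()
    X = study.covariates[rows]

    ps = propensity.fit_lsps(X, arms, cv_folds=settings.cv_folds,
                             prior_variance_grid=settings.prior_variance_grid,
                             seed=settings.seed)
    pref = propensity.preference_score(ps.scores, float(arms.mean()))
    equipoise = propensity.equipoise_proportion(pref)

    matched = matching_balance.match_variable_ratio(
        ps.scores, arms, ratio_cap=settings.ratio_cap,
        caliper=settings.caliper, seed=settings.seed)
    balance = matching_balance.covariate_balance(X, arms, matched,
                                                study.covariate_ids)
    _, d_max = matching_balance.balance_gate(balance,
                                             settings.thresholds.balance_asd)

    matched_rows = pd.DataFrame({
        "person_id": analytic["person_id"].to_numpy()[matched.person_indices()],
        "stratum_id": matched.rows["stratum_id"].to_numpy(),
        "treated": matched.rows["treated"].to_numpy(),
    })
    surv = estimation.overlay_outcome(matched_rows.merge(tar, on="person_id"),
                                      study.outcomes, outcome_id=0)
    surv = surv[surv["days_at_risk"] > 0]
    t_ev = int(surv.loc[surv["treated"], "event"].sum())
    c_ev = int(surv.loc[~surv["treated"], "event"].sum())

    result: dict = {
        "comparison": comparison, "database": database,
        "ps_strategy": settings.ps_strategy, "tar": settings.tar,
        "attrition": attrition, "balance": balance,
        "equipoise": equipoise, "d_max": d_max,
        "ps_model": ps, "matched": matched,
        "n_target_matched": matched.n_target_matched,
        "n_comparator_matched": matched.n_comparator_matched,
    }

    est = None
    if estimation.nonzero_events_gate(t_ev, c_ev):
        try:
            est = estimation.estimate_hazard_ratio(surv)
        except InestimableError:
            est = None
    if est is not None:
        result.update(hr=est.hr, ci95_low=est.ci95_low, ci95_high=est.ci95_high,
                      log_hr=est.log_hr, se_log_hr=est.se_log_hr,
                      estimate=est)

    nc = calibration.estimate_negative_controls(
        study.outcomes, tar, matched_rows, persons)
    null = calibration.fit_empirical_null(nc)
    result.update(negative_controls=nc, null=null, ease=null.ease)

    if est is not None:
        cal = calibration.calibrate_estimate(est.log_hr, est.se_log_hr, null)
        result.update(hr_cal=cal.hr_cal, cal_ci95_low=cal.ci95_low,
                      cal_ci95_high=cal.ci95_high, log_hr_cal=cal.log_hr_cal,
                      se_cal=cal.se_cal, calibrated=cal)

    result["verdict"] = apply_diagnostics(
        t_ev, c_ev, d_max, equipoise, null.ease, settings.thresholds)
    return result
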