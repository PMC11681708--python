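"""Synthetic observational-study generator with known ground truth.

Emulates the raw material of a new-user, active-comparator cohort study:
two exposure cohorts with high-dimensional sparse binary baseline
covariates, confounded treatment assignment, repeated drug administrations
with per-cycle persistence dropout, a time-to-event outcome of interest
with a configurable true hazard ratio, and a battery of negative-control
outcomes whose true log hazard ratios can be biased away from zero to
inject residual systematic error.

Every random draw is routed through seed streams spawned from a single
seed, one stream per sub-generator, so e.g. changing the number of
negative controls does not perturb cohort composition.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import expit, logit
from scipy.optimize import brentq


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters for one synthetic study database.

    Defaults describe a mid-sized claims database: two cohorts of 20,000
    new users, ~2,000 sparse binary baseline covariates with prevalences
    log-uniform on [0.001, 0.3], 20 of which confound both treatment
    choice and outcome hazard, an uncommon outcome of interest, and 86
    negative-control outcomes.
    """

    seed: int = 0
    n_target: int = 20_000
    n_comparator: int = 20_000
    n_covariates: int = 2_000
    covariate_prevalence_range: tuple[float, float] = (0.001, 0.3)
    n_confounders: int = 20
    treatment_coefs: tuple[float, ...] | None = None   # log-odds, len n_confounders
    outcome_coefs: tuple[float, ...] | None = None     # log-hazard, len n_confounders
    true_log_hr: float = 0.0
    baseline_hazard: float = 1e-4                      # events / person-day
    n_negative_controls: int = 86
    nc_bias_mean: float = 0.0                          # mu_bias on log-HR scale
    nc_bias_sd: float = 0.0                            # sigma_bias
    nc_baseline_hazard_range: tuple[float, float] = (5e-5, 2e-4)
    admin_interval_days: int = 56
    persistence_dropout_prob: float = 0.15             # per administration cycle
    obs_followup_range_days: tuple[int, int] = (180, 1825)
    index_day_range: tuple[int, int] = (365, 1095)
    censor_exposure_rate: float = 2e-4                 # censoring-drug starts / day
    prior_outcome_prob: float = 0.002                  # pre-index event probability

    def __post_init__(self) -> None:
        for name in ("n_target", "n_comparator", "n_covariates",
                     "n_negative_controls", "admin_interval_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_confounders < 0 or self.n_confounders > self.n_covariates:
            raise ValueError("n_confounders must be in [0, n_covariates]")
        lo, hi = self.covariate_prevalence_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("covariate_prevalence_range must satisfy 0 < lo <= hi <= 1")
        if not (0 <= self.persistence_dropout_prob <= 1):
            raise ValueError("persistence_dropout_prob must be a probability")
        if not (0 <= self.prior_outcome_prob <= 1):
            raise ValueError("prior_outcome_prob must be a probability")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        nlo, nhi = self.nc_baseline_hazard_range
        if not (0 < nlo <= nhi):
            raise ValueError("nc_baseline_hazard_range must be positive and ordered")
        if self.nc_bias_sd < 0:
            raise ValueError("nc_bias_sd must be >= 0")
        flo, fhi = self.obs_followup_range_days
        if not (0 < flo <= fhi):
            raise ValueError("obs_followup_range_days must be positive and ordered")
        for name in ("treatment_coefs", "outcome_coefs"):
            v = getattr(self, name)
            if v is not None and len(v) != self.n_confounders:
                raise ValueError(f"{name} must have length n_confounders")


def default_confounder_coefs(n_confounders: int, scale: float = 0.7
                             ) -> tuple[float, ...]:
    """Alternating-sign coefficients of magnitude `scale`, e.g. for both
    treatment_coefs (log-odds) and outcome_coefs (log-hazard)."""
    return tuple(scale * (1 if i % 2 == 0 else -1) for i in range(n_confounders))


@dataclass
class SyntheticStudy:
    """One generated database: persons, covariates, exposures, outcomes, truth."""

    persons: pd.DataFrame          # person_id, arm, index_day, obs_start_day, obs_end_day
    covariates: "sparse.csr_matrix"  # persons x covariates, binary
    covariate_ids: np.ndarray
    administrations: pd.DataFrame  # person_id, day (sorted ascending within person)
    censor_exposures: pd.DataFrame  # person_id, day
    outcomes: pd.DataFrame         # person_id, outcome_id (0 = interest), event_day
    truth: dict

    @property
    def person_ids(self) -> np.ndarray:
        return self.persons["person_id"].to_numpy()

    def write(self, out_dir: str | Path) -> None:
        """Write the long-format CSV extract plus truth.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.persons.to_csv(out / "persons.csv", index=False)
        coo = self.covariates.tocoo()
        pd.DataFrame({
            "person_id": self.person_ids[coo.row],
            "covariate_id": self.covariate_ids[coo.col],
            "value": coo.data.astype(int),
        }).to_csv(out / "covariates.csv", index=False)
        self.administrations.to_csv(out / "administrations.csv", index=False)
        self.censor_exposures.to_csv(out / "censor_exposures.csv", index=False)
        self.outcomes.to_csv(out / "outcomes.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, default=float)


def _spawn_rngs(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _sample_covariates(rng: np.random.Generator, n: int, prevalences: np.ndarray,
                       chunk: int = 200) -> sparse.csr_matrix:
    """Sparse Bernoulli matrix, column j ~ Bernoulli(prevalences[j])."""
    blocks = []
    for start in range(0, len(prevalences), chunk):
        p = prevalences[start:start + chunk]
        u = rng.random((n, len(p)))
        blocks.append(sparse.csr_matrix(u < p[None, :], dtype=np.float64))
    return sparse.hstack(blocks, format="csr")


def _exponential_event_days(rng: np.random.Generator, rates: np.ndarray) -> np.ndarray:
    """Integer days-to-event from a constant-hazard (exponential) model.

    Continuous time t ~ Exp(rate); the event is recorded on day ceil(t)
    after index (day granularity, earliest possible event day = index+1).
    """
    t = rng.exponential(1.0 / rates)
    return np.ceil(t).astype(np.int64)


def generate_study(config: SimConfig) -> SyntheticStudy:
    """Generate one complete synthetic study database.

    Treatment assignment follows logit P(T=1|X) = alpha + sum_j gamma_j X_j
    over the confounder columns, with alpha tuned by root finding so the
    expected treated count equals n_target.  Event times for the outcome
    of interest are exponential with hazard
    lambda0 * exp(beta_T * T + sum_j delta_j X_j); each negative control k
    uses its own baseline hazard and a true log-HR b_k ~ N(mu_bias,
    sigma_bias^2).  Raises if either realized arm is empty.
    """
    cfg = config
    rngs = _spawn_rngs(cfg.seed, ["prevalence", "covariates", "treatment",
                                  "observation", "administrations", "censoring",
                                  "outcome", "negative_controls"])
    n = cfg.n_target + cfg.n_comparator

    lo, hi = cfg.covariate_prevalence_range
    prevalences = np.exp(rngs["prevalence"].uniform(np.log(lo), np.log(hi),
                                                    cfg.n_covariates))
    X = _sample_covariates(rngs["covariates"], n, prevalences)

    gamma = np.asarray(cfg.treatment_coefs
                       if cfg.treatment_coefs is not None
                       else default_confounder_coefs(cfg.n_confounders, 0.7))
    delta = np.asarray(cfg.outcome_coefs
                       if cfg.outcome_coefs is not None
                       else default_confounder_coefs(cfg.n_confounders, 0.5))

    Xc = X[:, :cfg.n_confounders]
    eta = Xc @ gamma if cfg.n_confounders else np.zeros(n)
    target_frac = cfg.n_target / n
    if np.allclose(gamma, 0.0) or cfg.n_confounders == 0:
        alpha = float(logit(target_frac))
    else:
        alpha = float(brentq(lambda a: expit(a + eta).mean() - target_frac, -30, 30))
    treated = rngs["treatment"].random(n) < expit(alpha + eta)
    if treated.all() or not treated.any():
        raise ValueError(
            "degenerate treatment assignment: one arm is empty; "
            "reduce |treatment_coefs| or rebalance n_target/n_comparator")

    person_id = np.arange(n, dtype=np.int64)
    index_day = rngs["observation"].integers(cfg.index_day_range[0],
                                             cfg.index_day_range[1] + 1, n)
    flo, fhi = cfg.obs_followup_range_days
    obs_end = index_day + rngs["observation"].integers(flo, fhi + 1, n)
    persons = pd.DataFrame({
        "person_id": person_id,
        "arm": np.where(treated, "target", "comparator"),
        "index_day": index_day,
        "obs_start_day": index_day - 365,
        "obs_end_day": obs_end,
    })

    # administrations: first dose on index day, then one per interval until a
    # geometric per-cycle dropout; truncated at observation end
    if cfg.persistence_dropout_prob > 0:
        n_cycles = rngs["administrations"].geometric(cfg.persistence_dropout_prob, n)
    else:
        n_cycles = np.full(n, 10_000, dtype=np.int64)
    max_by_obs = (obs_end - index_day) // cfg.admin_interval_days + 1
    n_cycles = np.minimum(n_cycles, max_by_obs)
    reps = n_cycles.astype(np.int64)
    pid_rep = np.repeat(person_id, reps)
    cycle_idx = np.concatenate([np.arange(k) for k in reps]) if reps.sum() else np.array([], int)
    admin_day = np.repeat(index_day, reps) + cycle_idx * cfg.admin_interval_days
    administrations = pd.DataFrame({"person_id": pid_rep, "day": admin_day})

    # censoring-drug exposures: rare memoryless process after index
    if cfg.censor_exposure_rate > 0:
        wait = rngs["censoring"].exponential(1.0 / cfg.censor_exposure_rate, n)
        censor_day = index_day + np.ceil(wait).astype(np.int64)
        keep = censor_day <= obs_end
        censor_exposures = pd.DataFrame({"person_id": person_id[keep],
                                         "day": censor_day[keep]})
    else:
        censor_exposures = pd.DataFrame({"person_id": np.array([], np.int64),
                                         "day": np.array([], np.int64)})

    lp = Xc @ delta if cfg.n_confounders else np.zeros(n)

    out_frames = []

    def _overlay(outcome_id: int, rates: np.ndarray,
                 rng: np.random.Generator) -> None:
        days = index_day + _exponential_event_days(rng, rates)
        post = days <= obs_end
        prior = rng.random(n) < cfg.prior_outcome_prob
        prior_day = index_day - rng.integers(0, 365, n)  # within the lookback
        event_day = np.where(prior, prior_day, days)
        keep = prior | post
        out_frames.append(pd.DataFrame({
            "person_id": person_id[keep],
            "outcome_id": outcome_id,
            "event_day": event_day[keep],
        }))

    rates0 = cfg.baseline_hazard * np.exp(cfg.true_log_hr * treated + lp)
    _overlay(0, rates0, rngs["outcome"])

    nc_rng = rngs["negative_controls"]
    b_k = nc_rng.normal(cfg.nc_bias_mean, cfg.nc_bias_sd, cfg.n_negative_controls)
    nlo, nhi = cfg.nc_baseline_hazard_range
    lam0k = np.exp(nc_rng.uniform(np.log(nlo), np.log(nhi), cfg.n_negative_controls))
    for k in range(cfg.n_negative_controls):
        _overlay(k + 1, lam0k[k] * np.exp(b_k[k] * treated + lp), nc_rng)

    outcomes = pd.concat(out_frames, ignore_index=True)

    truth = {
        "config": dataclasses.asdict(cfg),
        "alpha": alpha,
        "treatment_coefs": gamma.tolist(),
        "outcome_coefs": delta.tolist(),
        "true_log_hr": cfg.true_log_hr,
        "nc_true_log_hr": b_k.tolist(),
        "nc_baseline_hazard": lam0k.tolist(),
        "n_treated_realized": int(treated.sum()),
    }
    return SyntheticStudy(persons=persons, covariates=X,
                          covariate_ids=np.arange(cfg.n_covariates, dtype=np.int64),
                          administrations=administrations,
                          censor_exposures=censor_exposures,
                          outcomes=outcomes, truth=truth)


def generate_phenotype_fixture(seed: int, n_persons: int,
                               prob_model_params: tuple[float, float, float, float, float]
                               = (0.5, 2.0, 8.0, 8.0, 2.0),
                               flag_model_params: tuple[float, float] = (-2.0, 4.0),
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Case probabilities and binary flags for phenotype-validation tests.

    The reference standard is probabilistic: each person carries a case
    probability drawn from a two-component Beta mixture
    (mix_weight, a0, b0, a1, b1) — one mode near 0 (clear non-cases), one
    near 1 (clear cases).  The phenotype flag is Bernoulli with
    logit P(flag) = c0 + c1 * case_prob, so flags correlate with, but do
    not determine, case status.
    """
    if n_persons <= 0:
        raise ValueError("n_persons must be > 0")
    rng = np.random.default_rng(seed)
    w, a0, b0, a1, b1 = prob_model_params
    comp = rng.random(n_persons) < w
    case_probs = np.where(comp, rng.beta(a1, b1, n_persons),
                          rng.beta(a0, b0, n_persons))
    c0, c1 = flag_model_params
    flagged = rng.random(n_persons) < expit(c0 + c1 * case_probs)
    return case_probs, flagged
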