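"""Four-diagnostic gatekeeper with estimate blinding, and DerSimonian-Laird
random-effects meta-analysis gated on heterogeneity.

An analysis is reported only if it passes all four pre-specified validity
diagnostics (non-zero events in both arms; max after-matching ASD < 0.1;
equipoise proportion >= 0.35; EASE <= 0.25); otherwise its estimate is
blinded — shown as NA — so invalid results cannot be interpreted.
Database-specific calibrated estimates are pooled by DerSimonian-Laird
when at least two databases pass and between-database heterogeneity is
acceptable (I^2 < 40%, strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .estimation import Z_975, nonzero_events_gate
from .propensity import equipoise_gate
from .calibration import ease_gate


@dataclass(frozen=True)
class Thresholds:
    """Pre-specified diagnostic thresholds (protocol constants)."""

    balance_asd: float = 0.1
    equipoise: float = 0.35
    ease: float = 0.25
    i2: float = 0.40


@dataclass
class DiagnosticsVerdict:
    """The gate deciding whether an estimate is reported or blinded."""

    pass_events: bool
    pass_balance: bool
    pass_equipoise: bool
    pass_ease: bool
    d_max: float
    equipoise_proportion: float
    ease: float
    target_events: int
    comparator_events: int

    @property
    def n_passed(self) -> int:
        return int(self.pass_events) + int(self.pass_balance) + \
            int(self.pass_equipoise) + int(self.pass_ease)

    @property
    def blinded(self) -> bool:
        return self.n_passed < 4


@dataclass
class MetaResult:
    pooled_log_hr: float
    pooled_se: float
    ci95_low: float
    ci95_high: float
    tau2_dl: float
    Q: float
    i2: float
    databases_included: int
    pooled: bool = False     # set by the heterogeneity gate


def apply_diagnostics(target_events: int, comparator_events: int,
                      d_max: float, equipoise_proportion: float, ease: float,
                      thresholds: Thresholds = Thresholds()
                      ) -> DiagnosticsVerdict:
    """Evaluate the four validity gates; the estimate is blinded unless
    every gate passes."""
    return DiagnosticsVerdict(
        pass_events=nonzero_events_gate(target_events, comparator_events),
        pass_balance=bool(d_max < thresholds.balance_asd),
        pass_equipoise=equipoise_gate(equipoise_proportion, thresholds.equipoise),
        pass_ease=ease_gate(ease, thresholds.ease),
        d_max=d_max, equipoise_proportion=equipoise_proportion, ease=ease,
        target_events=target_events, comparator_events=comparator_events)


def dersimonian_laird(log_hrs: Sequence[float], ses: Sequence[float]
                      ) -> MetaResult:
    """Moment-based random-effects pooling of per-database log hazard ratios.

    Fixed-effect weights w_i = 1/se_i^2 give Cochran's Q; the DL
    between-database variance is tau^2 = max(0, (Q-(k-1)) / (sum w -
    sum w^2 / sum w)); random-effect weights 1/(se_i^2 + tau^2) give the
    pooled estimate.  I^2 = max(0, (Q-(k-1))/Q).
    """
    b = np.asarray(log_hrs, dtype=float)
    se = np.asarray(ses, dtype=float)
    k = len(b)
    if k < 2:
        raise ValueError("meta-analysis needs >= 2 estimates")
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / se**2
    beta_fe = float(np.sum(w * b) / np.sum(w))
    Q = float(np.sum(w * (b - beta_fe) ** 2))
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    i2 = max(0.0, (Q - (k - 1)) / Q) if Q > 0 else 0.0
    wr = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(wr * b) / np.sum(wr))
    pooled_se = float(1.0 / np.sqrt(np.sum(wr)))
    return MetaResult(pooled_log_hr=pooled, pooled_se=pooled_se,
                      ci95_low=float(np.exp(pooled - Z_975 * pooled_se)),
                      ci95_high=float(np.exp(pooled + Z_975 * pooled_se)),
                      tau2_dl=tau2, Q=Q, i2=i2, databases_included=k)


def heterogeneity_gate(meta: MetaResult, threshold: float = 0.40) -> MetaResult:
    """Allow pooling iff I^2 is strictly below the threshold (and k >= 2)."""
    meta.pooled = bool(meta.i2 < threshold and meta.databases_included >= 2)
    return meta


def _mask(n: int, mask_small: bool) -> str:
    return "<5" if mask_small and 1 <= n <= 4 else str(n)


def build_results_table(analyses: Sequence[dict],
                        thresholds: Thresholds = Thresholds(),
                        mask_small_counts: bool = False
                        ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Assemble the study report from per-analysis result dicts.

    Each dict needs keys: comparison, database, ps_strategy, tar,
    verdict (DiagnosticsVerdict), and — when estimable — hr, ci95_low,
    ci95_high, log_hr_cal, se_cal, hr_cal, cal_ci95_low, cal_ci95_high.
    Blinded analyses carry NA in every estimate column.  Meta rows pool
    the calibrated log-HRs of unblinded analyses per (comparison,
    ps_strategy, tar) when the heterogeneity gate allows.

    Returns (results table, meta table, pass-count histogram).
    """
    rows = []
    for a in analyses:
        v: DiagnosticsVerdict = a["verdict"]
        blinded = v.blinded
        rows.append({
            "comparison": a["comparison"], "database": a["database"],
            "ps_strategy": a.get("ps_strategy", "1:10"),
            "tar": a.get("tar", "on_treatment"),
            "target_events": _mask(v.target_events, mask_small_counts),
            "comparator_events": _mask(v.comparator_events, mask_small_counts),
            "pass_events": int(v.pass_events),
            "max_asd": v.d_max, "pass_asd": int(v.pass_balance),
            "equipoise": v.equipoise_proportion,
            "pass_equipoise": int(v.pass_equipoise),
            "ease": v.ease, "pass_ease": int(v.pass_ease),
            "total_passed": v.n_passed,
            "hr": np.nan if blinded else a.get("hr", np.nan),
            "ci95_low": np.nan if blinded else a.get("ci95_low", np.nan),
            "ci95_high": np.nan if blinded else a.get("ci95_high", np.nan),
            "hr_cal": np.nan if blinded else a.get("hr_cal", np.nan),
            "cal_ci95_low": np.nan if blinded else a.get("cal_ci95_low", np.nan),
            "cal_ci95_high": np.nan if blinded else a.get("cal_ci95_high", np.nan),
        })
    table = pd.DataFrame(rows)

    meta_rows = []
    for keys, grp in table.groupby(["comparison", "ps_strategy", "tar"]):
        ok = grp["total_passed"] == 4
        sub = [a for a in analyses
               if (a["comparison"], a.get("ps_strategy", "1:10"),
                   a.get("tar", "on_treatment")) == keys
               and not a["verdict"].blinded
               and np.isfinite(a.get("log_hr_cal", np.nan))]
        if len(sub) < 2:
            continue
        meta = heterogeneity_gate(
            dersimonian_laird([a["log_hr_cal"] for a in sub],
                              [a["se_cal"] for a in sub]),
            thresholds.i2)
        meta_rows.append({
            "comparison": keys[0], "ps_strategy": keys[1], "tar": keys[2],
            "databases_included": meta.databases_included,
            "i2": meta.i2, "tau2_dl": meta.tau2_dl, "Q": meta.Q,
            "pooled": meta.pooled,
            "hr_cal": np.exp(meta.pooled_log_hr) if meta.pooled else np.nan,
            "cal_ci95_low": meta.ci95_low if meta.pooled else np.nan,
            "cal_ci95_high": meta.ci95_high if meta.pooled else np.nan,
        })
    meta_table = pd.DataFrame(meta_rows)

    histogram = {i: int((table["total_passed"] == i).sum()) for i in range(5)}
    return table, meta_table, histogram
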