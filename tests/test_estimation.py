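"""Stratified Cox against brute-force and lifelines oracles, incidence
rates, minimum detectable RR, and the non-zero-events gate."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import cohortcal as cc
from cohortcal.estimation import (fit_stratified_cox, incidence_rate,
                                  minimum_detectable_rr, nonzero_events_gate,
                                  overlay_outcome, InestimableError)


def brute_force_loglik(beta, records, ties="efron"):
    """Hand-written stratified partial log-likelihood (pure Python loops)."""
    ll = 0.0
    strata = sorted({r[0] for r in records})
    for s in strata:
        rows = [r for r in records if r[0] == s]
        event_times = sorted({t for (_, x, t, e) in rows if e})
        for t in event_times:
            D = [x for (_, x, tt, e) in rows if e and tt == t]
            R = [x for (_, x, tt, _e) in rows if tt >= t]
            d = len(D)
            s0_tied = sum(math.exp(beta * x) for x in D)
            s1_tied = sum(x * math.exp(beta * x) for x in D)
            ll += sum(beta * x for x in D)
            for l in range(d):
                s0 = sum(math.exp(beta * x) for x in R)
                s1 = sum(x * math.exp(beta * x) for x in R)
                if ties == "efron":
                    s0 -= (l / d) * s0_tied
                    s1 -= (l / d) * s1_tied
                ll -= math.log(s0)
    return ll


def brute_force_mle(records, ties="efron"):
    res = optimize.minimize_scalar(
        lambda b: -brute_force_loglik(b, records, ties),
        bounds=(-5, 5), method="bounded",
        options={"xatol": 1e-10})
    return res.x


def _random_records(seed, n_strata=8, max_per_arm=3):
    rng = np.random.default_rng(seed)
    recs = []
    for s in range(n_strata):
        for x in (1, 0):
            for _ in range(rng.integers(1, max_per_arm + 1)):
                t = int(rng.integers(1, 15))
                e = bool(rng.random() < 0.6)
                recs.append((s, x, t, e))
    return recs


def _fit(records, ties="efron"):
    a = np.array(records, dtype=float)
    return fit_stratified_cox(a[:, 0], a[:, 1].astype(bool), a[:, 2],
                              a[:, 3].astype(bool), ties=ties)


class TestStratifiedCox:
    def test_two_strata_hand_instance_matches_grid_search(self):
        # two small strata with a hand-built event pattern in both arms
        recs = [(0, 1, 3, True), (0, 0, 5, True),
                (1, 1, 6, True), (1, 0, 4, True), (1, 0, 8, False)]
        beta, _ = _fit(recs)
        assert beta == pytest.approx(brute_force_mle(recs), abs=1e-6)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_random_small_instances_match_brute_force(self, seed):
        recs = _random_records(seed)
        if not _informative(recs):
            return
        beta, _ = _fit(recs)
        assert beta == pytest.approx(brute_force_mle(recs), abs=1e-6)

    def test_label_swap_negates_estimate(self):
        recs = _random_records(11)
        beta, se = _fit(recs)
        flipped = [(s, 1 - x, t, e) for (s, x, t, e) in recs]
        beta2, se2 = _fit(flipped)
        assert beta2 == pytest.approx(-beta, abs=1e-8)
        assert se2 == pytest.approx(se, abs=1e-8)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(5)
        rows = []
        for s in range(150):
            for i in range(int(rng.integers(2, 5))):
                treated = i == 0
                t = int(np.ceil(rng.exponential(80 / (1.6 if treated else 1))))
                c = int(rng.integers(20, 150))
                rows.append((s, int(treated), min(t, c), int(t <= c)))
        df = pd.DataFrame(rows, columns=["stratum_id", "treated",
                                         "time_days", "event"])
        beta, se = fit_stratified_cox(df["stratum_id"], df["treated"],
                                      df["time_days"], df["event"])
        cph = lifelines.CoxPHFitter()
        cph.fit(df, duration_col="time_days", event_col="event",
                strata=["stratum_id"], formula="treated")
        assert beta == pytest.approx(cph.params_.iloc[0], abs=1e-6)
        assert se == pytest.approx(cph.standard_errors_.iloc[0], abs=1e-6)

    def test_efron_equals_breslow_without_ties(self):
        rng = np.random.default_rng(9)
        times = rng.permutation(40) + 1      # all distinct
        recs = [(i // 5, int(i % 2 == 0), int(times[i]), bool(rng.random() < 0.7))
                for i in range(40)]
        if not _informative(recs):
            pytest.skip("uninformative draw")
        be, _ = _fit(recs, ties="efron")
        bb, _ = _fit(recs, ties="breslow")
        assert be == pytest.approx(bb, abs=1e-8)

    def test_stratum_relabel_and_order_invariance(self):
        recs = _random_records(21)
        beta, se = _fit(recs)
        relabeled = [(s + 100, x, t, e) for (s, x, t, e) in reversed(recs)]
        beta2, se2 = _fit(relabeled)
        assert (beta2, se2) == pytest.approx((beta, se), abs=1e-10)

    def test_uninformative_strata_raise(self):
        # events exist but no stratum has both arms at risk
        recs = [(0, 1, 5, True), (0, 1, 7, True), (1, 0, 3, True)]
        with pytest.raises(InestimableError):
            _fit(recs)

    def test_monotone_likelihood_warns(self):
        recs = [(0, 1, 3, True), (0, 0, 5, False),
                (1, 1, 2, True), (1, 0, 9, False)]
        with pytest.warns(RuntimeWarning, match="monotone"):
            _fit(recs)

    def test_null_type_one_error_near_nominal(self):
        rng = np.random.default_rng(2024)
        reject = 0
        reps = 500
        for _ in range(reps):
            n_pairs = 120
            t = np.ceil(rng.exponential(60, 2 * n_pairs)).astype(int)
            c = rng.integers(20, 120, 2 * n_pairs)
            time = np.minimum(t, c)
            event = t <= c
            stratum = np.repeat(np.arange(n_pairs), 2)
            treated = np.tile([True, False], n_pairs)
            try:
                b, se = fit_stratified_cox(stratum, treated, time, event)
            except InestimableError:
                continue
            reject += abs(b / se) > 1.959964
        assert abs(reject / reps - 0.05) < 0.02


def _informative(recs):
    """True when the partial likelihood has a finite interior maximum:
    informative events exist in both arms."""
    arms_with_events = set()
    by = {}
    for (s, x, t, e) in recs:
        by.setdefault(s, []).append((x, t, e))
    for rows in by.values():
        for (x, t, e) in rows:
            if e and any(o[0] != x and o[1] >= t for o in rows):
                arms_with_events.add(x)
    return arms_with_events == {0, 1}


class TestRatesAndGates:
    @pytest.mark.parametrize("events,days,expected", [
        (10, 5000 * 365.25, 2.0),
        (0, 365.25, 0.0),
        (1, 365.25, 1000.0),
    ])
    def test_incidence_rate(self, events, days, expected):
        assert incidence_rate(events, days) == pytest.approx(expected)

    def test_incidence_rate_requires_persontime(self):
        with pytest.raises(ValueError):
            incidence_rate(1, 0)

    def test_mdrr_hand_value(self):
        z = 1.959964 + 0.8416212
        assert minimum_detectable_rr(100, 0.5) == pytest.approx(
            np.exp(z / 5.0), rel=1e-6)

    def test_mdrr_monotone(self):
        assert minimum_detectable_rr(1000, 0.5) < minimum_detectable_rr(100, 0.5)
        assert minimum_detectable_rr(100, 0.1) > minimum_detectable_rr(100, 0.5)
        assert minimum_detectable_rr(0, 0.5) == np.inf

    @pytest.mark.parametrize("t,c,ok", [(12, 42, True), (0, 0, False),
                                        (3, 0, False), (0, 5, False)])
    def test_nonzero_events_gate(self, t, c, ok):
        assert nonzero_events_gate(t, c) is ok


class TestOverlay:
    def test_event_inside_tar_counted_with_inclusive_time(self):
        tar = pd.DataFrame({"person_id": [1, 2, 3],
                            "tar_start_day": [11, 11, 11],
                            "tar_end_day": [100, 100, 100],
                            "days_at_risk": [90, 90, 90]})
        outcomes = pd.DataFrame({"person_id": [1, 2], "outcome_id": [0, 0],
                                 "event_day": [11, 101]})
        s = overlay_outcome(tar, outcomes, 0)
        assert s.loc[s.person_id == 1, "event"].item()          # on start day
        assert s.loc[s.person_id == 1, "time_days"].item() == 1
        assert not s.loc[s.person_id == 2, "event"].item()      # after TAR end
        assert s.loc[s.person_id == 2, "time_days"].item() == 90
        assert s.loc[s.person_id == 3, "time_days"].item() == 90
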