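"""Greedy caliper matching against a literal replay oracle, ASD formulas,
and the balance / representativeness diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

import cohortcal as cc
from cohortcal.matching_balance import (balance_gate, covariate_balance,
                                        match_variable_ratio,
                                        representativeness_report,
                                        standardized_difference)


def greedy_replay(scores, arms, ratio_cap, caliper, seed):
    """Independent literal re-execution of the documented greedy procedure:
    seeded target order, rounds of one claim each, nearest available
    comparator within caliper on the logit scale, ties to lower ordinal,
    targets unmatched after round 1 excluded."""
    ls = logit(np.asarray(scores, float))
    width = caliper * float(np.std(ls))
    t_idx = np.nonzero(arms)[0]
    c_idx = np.nonzero(~np.asarray(arms, bool))[0]
    order = np.random.default_rng(seed).permutation(len(t_idx))
    available = list(range(len(c_idx)))
    strata: dict[int, list[int]] = {}
    excluded: set[int] = set()
    for r in range(ratio_cap):
        for oi in order:
            if oi in excluded:
                continue
            v = ls[t_idx[oi]]
            best, best_d = None, None
            for j in available:                 # ascending ordinal
                d = abs(ls[c_idx[j]] - v)
                if d <= width and (best is None or d < best_d):
                    best, best_d = j, d
            if best is None:
                if r == 0:
                    excluded.add(oi)
                continue
            available.remove(best)
            strata.setdefault(oi, []).append(int(c_idx[best]))
    return {int(t_idx[k]): sorted(v) for k, v in strata.items()}


def _as_dict(matched):
    out = {}
    for sid, grp in matched.rows.groupby("stratum_id"):
        t = int(grp.loc[grp["treated"], "person_idx"].iloc[0])
        out[t] = sorted(grp.loc[~grp["treated"], "person_idx"].astype(int))
    return out


class TestMatchVariableRatio:
    def test_single_identical_pair(self):
        m = match_variable_ratio(np.array([0.4, 0.4]),
                                 np.array([True, False]), ratio_cap=1)
        assert m.n_target_matched == 1 and m.n_comparator_matched == 1
        assert set(m.rows["stratum_id"]) == {0}

    def test_target_outside_caliper_excluded(self):
        scores = np.array([0.9, 0.12, 0.1, 0.11, 0.13])
        arms = np.array([True, True, False, False, False])
        m = match_variable_ratio(scores, arms, ratio_cap=2, seed=0)
        assert 0 not in set(m.rows["person_idx"])   # far target dropped
        assert m.n_target_matched == 1

    def test_no_match_possible_raises(self):
        with pytest.raises(ValueError, match="empty matched cohort"):
            match_variable_ratio(np.array([0.95, 0.05]),
                                 np.array([True, False]))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    @pytest.mark.parametrize("ratio_cap", [1, 3, 10])
    def test_matches_literal_replay(self, seed, ratio_cap):
        rng = np.random.default_rng(100 + seed)
        n = 40
        scores = rng.uniform(0.05, 0.95, n)
        arms = rng.random(n) < 0.35
        if not arms.any() or arms.all():
            arms[0], arms[1] = True, False
        try:
            m = match_variable_ratio(scores, arms, ratio_cap=ratio_cap,
                                     seed=seed)
        except ValueError:
            assert greedy_replay(scores, arms, ratio_cap, 0.2, seed) == {}
            return
        assert _as_dict(m) == greedy_replay(scores, arms, ratio_cap, 0.2, seed)

    def test_structural_invariants_exhaustive(self):
        rng = np.random.default_rng(7)
        n = 600
        scores = rng.beta(2, 3, n).clip(0.01, 0.99)
        arms = rng.random(n) < 0.4
        m = match_variable_ratio(scores, arms, ratio_cap=4, seed=11)
        rows = m.rows
        # a person appears in at most one stratum
        assert rows["person_idx"].is_unique
        by_stratum = rows.groupby("stratum_id")["treated"]
        assert (by_stratum.sum() == 1).all()                   # 1 target each
        sizes = by_stratum.count() - 1
        assert sizes.between(1, 4).all()                       # 1..cap comparators
        # every matched pair within the caliper on the logit scale
        ls = logit(scores)
        for _, grp in rows.groupby("stratum_id"):
            t = ls[grp.loc[grp["treated"], "person_idx"].iloc[0]]
            c = ls[grp.loc[~grp["treated"], "person_idx"]]
            assert np.all(np.abs(c - t) <= m.caliper_logit + 1e-12)


class TestStandardizedDifference:
    def test_equal_prevalence_zero(self):
        assert standardized_difference(0.2, 0.2) == 0.0

    def test_hand_value(self):
        assert standardized_difference(0.5, 0.3) == pytest.approx(
            0.2 / np.sqrt(0.23), abs=1e-9)

    def test_degenerate_cases(self):
        assert standardized_difference(0.0, 0.0) == 0.0
        assert standardized_difference(1.0, 1.0) == 0.0
        assert standardized_difference(1.0, 1.0, v1=0.0, v2=0.0) == 0.0

    def test_zero_variance_unequal_means_marks_infinity(self):
        assert standardized_difference(0.3, 0.5, v1=0.0, v2=0.0) == np.inf

    def test_continuous_form(self):
        assert standardized_difference(1.0, 0.0, v1=1.0, v2=1.0) == \
            pytest.approx(1.0)


class TestBalanceGate:
    @pytest.mark.parametrize("d_max,passed", [(0.047, True), (0.105, False),
                                              (0.1, False), (0.0999, True)])
    def test_threshold_strict(self, d_max, passed):
        report = pd.DataFrame({"after_asd": [0.01, d_max]})
        ok, observed = balance_gate(report)
        assert ok is passed and observed == d_max

    def test_empty_report_rejected(self):
        with pytest.raises(ValueError):
            balance_gate(pd.DataFrame({"after_asd": []}))


class TestBalanceAndRepresentativeness:
    def test_matching_reduces_confounder_imbalance(self, small_study,
                                                   small_result):
        bal = small_result["balance"]
        n_conf = small_study.truth["config"]["n_confounders"]
        conf = bal.iloc[:n_conf]
        assert conf["after_asd"].mean() < conf["before_asd"].mean()
        frac_bad_after = (bal["after_asd"] >= 0.1).mean()
        frac_bad_before = (bal["before_asd"] >= 0.1).mean()
        assert frac_bad_after <= frac_bad_before

    def test_identity_cohort_all_zero(self):
        rng = np.random.default_rng(0)
        X = (rng.random((200, 5)) < 0.3).astype(float)
        rows = np.arange(200)
        rep = representativeness_report(X, rows, rows)
        assert np.allclose(rep["asd"], 0.0)

    def test_dropping_carriers_zeroes_prevalence(self):
        X = np.zeros((10, 1))
        X[:3, 0] = 1.0
        rep = representativeness_report(X, np.arange(10), np.arange(3, 10))
        assert rep["analytic_target_prev"].iloc[0] == 0.0

    def test_random_subsample_keeps_asd_small(self):
        rng = np.random.default_rng(42)
        n = 10_000
        X = (rng.random((n, 8)) < rng.uniform(0.05, 0.5, 8)).astype(float)
        sub = rng.choice(n, n // 2, replace=False)
        rep = representativeness_report(X, np.arange(n), sub)
        assert (rep["asd"] < 0.05).all()
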