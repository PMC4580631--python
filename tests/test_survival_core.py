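"""Survival-primitive tests: product-limit hand examples, the Cox fitter
against brute-force and lifelines oracles, time-splitting invariants, and
the proportional-hazards diagnostic."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coxcut.survival_core import (cox_fit, expand_time_split, km_estimate,
                                  ph_diagnostic)
from coxcut.synth_claims import GeneratorConfig, generate_analysis_table


def _rows(times, events, arms):
    return pd.DataFrame({
        "subject_id": [f"P{i}" for i in range(len(times))],
        "followup_days": times, "event": events, "arm_fibrate": arms})


# the six-subject toy used for the exhaustive-grid oracle
TOY = _rows([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 0, 0], [1, 0, 1, 0, 1, 0])


def breslow_loglik_brute(times, events, x, beta):
    """Direct risk-set summation of the Breslow log partial likelihood."""
    ll = 0.0
    for t, d in zip(times, events):
        if d == 1:
            risk = [math.exp(beta * xi)
                    for ti, xi in zip(times, x) if ti >= t]
            i = times.index(t)
            ll += beta * x[i] - math.log(sum(risk))
    return ll


class TestKaplanMeier:
    def test_hand_product_limit(self):
        rows = _rows([1, 2, 3], [1, 1, 0], [0, 0, 0])
        (curve,) = km_estimate(rows)
        assert curve.survival_at(1) == pytest.approx(2 / 3)
        assert curve.survival_at(2) == pytest.approx(1 / 3)
        assert curve.survival_at(2.5) == pytest.approx(1 / 3)

    def test_no_events_flat_curve(self):
        rows = _rows([5, 6, 7], [0, 0, 0], [0, 0, 0])
        (curve,) = km_estimate(rows)
        assert (curve.survival == 1.0).all()

    def test_single_subject_event(self):
        rows = _rows([5], [1], [0])
        (curve,) = km_estimate(rows)
        assert curve.survival_at(5) == 0.0

    def test_survival_nonincreasing_and_grouped(self, small_analysis):
        curves = km_estimate(small_analysis, group_by="arm")
        assert len(curves) == 2
        for c in curves:
            assert (np.diff(c.survival) <= 1e-12).all()
            assert c.survival[0] <= 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="empty"):
            km_estimate(_rows([], [], []))


class TestCoxFit:
    def test_grid_oracle_six_subjects(self):
        """Fitted log HR equals the exhaustive grid maximizer of the
        Breslow partial likelihood."""
        cp = expand_time_split(TOY, "arm_fibrate", [])
        fit = cox_fit(cp, ["arm_fibrate"], ties="breslow")
        grid = np.arange(-3, 3, 1e-4)
        lls = [breslow_loglik_brute([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 0, 0],
                                    [1, 0, 1, 0, 1, 0], b) for b in grid]
        assert abs(fit.coef[0] - grid[int(np.argmax(lls))]) < 1e-4
        assert fit.loglik == pytest.approx(max(lls), abs=1e-6)

    def test_matches_lifelines_counting_process(self, small_analysis):
        from lifelines import CoxTimeVaryingFitter
        sub = small_analysis.copy()
        sub["age_c"] = sub["age"] - 65
        cp = expand_time_split(sub, "arm_fibrate", [540])
        covs = ["arm_fibrate_p1", "arm_fibrate_p2", "age_c", "male",
                "insulin", "depression"]
        fit = cox_fit(cp, covs, ties="efron")
        ctv = CoxTimeVaryingFitter()
        ctv.fit(cp[["subject_id", "start", "stop", "event"] + covs],
                id_col="subject_id", start_col="start", stop_col="stop",
                event_col="event")
        np.testing.assert_allclose(fit.coef, ctv.params_.values, atol=1e-6)
        np.testing.assert_allclose(fit.se, ctv.standard_errors_.values,
                                   atol=1e-5)
        assert fit.loglik == pytest.approx(ctv.log_likelihood_, abs=1e-6)

    def test_breslow_equals_efron_without_ties(self):
        rng = np.random.default_rng(0)
        n = 250
        rows = _rows(list(rng.permutation(n) + 1),
                     list(rng.integers(0, 2, n)),
                     list(rng.integers(0, 2, n)))
        cp = expand_time_split(rows, "arm_fibrate", [])
        fb = cox_fit(cp, ["arm_fibrate"], ties="breslow")
        fe = cox_fit(cp, ["arm_fibrate"], ties="efron")
        assert fb.coef[0] == pytest.approx(fe.coef[0], abs=1e-10)
        assert fb.loglik == pytest.approx(fe.loglik, abs=1e-10)

    def test_loglik_at_optimum_beats_null(self, small_analysis):
        cp = expand_time_split(small_analysis, "arm_fibrate", [300])
        fit = cox_fit(cp, ["arm_fibrate_p1", "arm_fibrate_p2"])
        assert fit.loglik >= fit.loglik_null

    def test_null_effect_recovery(self):
        """Exchangeable arms: |coef| < 3 SE in nearly all replicates."""
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(30):
            n = 400
            t = rng.exponential(300, n).astype(int) + 1
            e = (rng.random(n) < 0.5).astype(int)
            arm = rng.integers(0, 2, n)
            cp = expand_time_split(_rows(list(t), list(e), list(arm)),
                                   "arm_fibrate", [])
            fit = cox_fit(cp, ["arm_fibrate"])
            hits += abs(fit.coef[0]) < 3 * fit.se[0]
        assert hits >= 28

    def test_true_hr_two_recovery_and_coverage(self):
        """True HR 2.0: point estimate near truth at large n; ~95% CI
        coverage across replicates at moderate n."""
        cfg = GeneratorConfig(
            n_subjects=20_000, seed=40, propensity_coefficients={},
            covariate_log_hazards={}, fibrate_share_target=0.5,
            baseline_hazard=1e-4,
            treatment_log_hr_schedule=((0, math.inf, math.log(2.0)),))
        ana, _ = generate_analysis_table(cfg)
        fit = cox_fit(expand_time_split(ana, "arm_fibrate", []),
                      ["arm_fibrate"])
        assert 1.9 <= fit.hr[0] <= 2.1
        covered = 0
        reps = 100
        for i in range(reps):
            ana, _ = generate_analysis_table(cfg.replace(n_subjects=2000,
                                                         seed=500 + i))
            f = cox_fit(expand_time_split(ana, "arm_fibrate", []),
                        ["arm_fibrate"])
            lo, hi = f.ci
            covered += lo[0] <= 2.0 <= hi[0]
        assert 0.88 <= covered / reps <= 0.99

    def test_constant_covariate_error_names_it(self, small_analysis):
        cp = expand_time_split(small_analysis, "arm_fibrate", [])
        cp["flat"] = 1.0
        with pytest.raises(ValueError, match="flat"):
            cox_fit(cp, ["arm_fibrate", "flat"])

    def test_no_events_error(self):
        rows = _rows([3, 4, 5], [0, 0, 0], [1, 0, 1])
        with pytest.raises(ValueError, match="no events"):
            cox_fit(expand_time_split(rows, "arm_fibrate", []),
                    ["arm_fibrate"])

    def test_separation_flagged(self):
        """Events only in one arm: monotone likelihood is flagged."""
        rows = _rows([1, 3, 5, 2, 4, 6], [1, 1, 1, 0, 0, 0],
                     [1, 1, 1, 0, 0, 0])
        fit = cox_fit(expand_time_split(rows, "arm_fibrate", []),
                      ["arm_fibrate"])
        assert "possible_separation" in fit.flags
        assert not fit.converged


class TestTimeSplit:
    def test_two_interval_example(self):
        rows = _rows([700], [1], [1])
        cp = expand_time_split(rows, "arm_fibrate", [540])
        assert len(cp) == 2
        first, second = cp.iloc[0], cp.iloc[1]
        assert (first["start"], first["stop"], first["event"]) == (0, 540, 0)
        assert (first["arm_fibrate_p1"], first["arm_fibrate_p2"]) == (1, 0)
        assert (second["start"], second["stop"], second["event"]) == (540, 700, 1)
        assert (second["arm_fibrate_p1"], second["arm_fibrate_p2"]) == (0, 1)

    def test_short_followup_single_row(self):
        rows = _rows([300, 700], [1, 0], [1, 0])
        cp = expand_time_split(rows, "arm_fibrate", [540])
        sub = cp[cp["subject_id"] == "P0"]
        assert len(sub) == 1
        assert sub["stop"].iloc[0] == 300 and sub["event"].iloc[0] == 1
        assert sub["arm_fibrate_p1"].iloc[0] == 1
        assert "arm_fibrate_p2" in cp.columns

    def test_cutoff_beyond_followup_raises(self):
        rows = _rows([300], [1], [1])
        with pytest.raises(ValueError, match="max follow-up"):
            expand_time_split(rows, "arm_fibrate", [300])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.tuples(st.integers(1, 900), st.booleans(),
                              st.booleans()), min_size=1, max_size=40),
           st.lists(st.integers(1, 899), min_size=0, max_size=4,
                    unique=True))
    def test_conservation_property(self, subjects, cutoffs):
        """Splitting conserves total person-time and events exactly."""
        times = [s[0] for s in subjects]
        cutoffs = sorted(c for c in cutoffs if c < max(times))
        rows = _rows(times, [int(s[1]) for s in subjects],
                     [int(s[2]) for s in subjects])
        cp = expand_time_split(rows, "arm_fibrate", cutoffs)
        assert (cp["stop"] - cp["start"]).sum() == rows["followup_days"].sum()
        assert cp["event"].sum() == rows["event"].sum()
        # rows partition (0, followup] per subject; event on the last row
        for sid, grp in cp.groupby("subject_id"):
            grp = grp.sort_values("start")
            assert grp["start"].iloc[0] == 0
            assert (grp["start"].iloc[1:].to_numpy()
                    == grp["stop"].iloc[:-1].to_numpy()).all()
            assert grp["event"].iloc[:-1].sum() == 0

    @pytest.mark.parametrize("cutoff", [60, 300, 540, 800])
    def test_refinement_invariance(self, small_analysis, cutoff):
        """Fitting one common coefficient on split rows reproduces the
        unsplit fit to high precision."""
        unsplit = cox_fit(expand_time_split(small_analysis, "arm_fibrate", []),
                          ["arm_fibrate"], tol=1e-12)
        split = cox_fit(expand_time_split(small_analysis, "arm_fibrate",
                                          [cutoff]),
                        ["arm_fibrate"], tol=1e-12)
        assert split.coef[0] == pytest.approx(unsplit.coef[0], abs=1e-8)
        assert split.loglik == pytest.approx(unsplit.loglik, abs=1e-8)


class TestPHDiagnostic:
    def test_matches_r_cox_zph_scale(self, small_analysis):
        """Statistic is chi-square(1)-scaled: p in (0,1) and finite."""
        cp = expand_time_split(small_analysis, "arm_fibrate", [])
        fit = cox_fit(cp, ["arm_fibrate"])
        diag = ph_diagnostic(fit, cp)
        assert 0 < diag["p"].iloc[0] <= 1
        assert diag["verdict"].iloc[0] in {"ok", "violated"}

    def test_detects_sign_switch(self):
        """Strong hazard-ratio reversal at day 540 is flagged."""
        cfg = GeneratorConfig(
            n_subjects=20_000, seed=60, fibrate_share_target=0.5,
            treatment_log_hr_schedule=((0, 540, -0.7),
                                       (540, math.inf, 0.7)))
        ana, _ = generate_analysis_table(cfg)
        cp = expand_time_split(ana, "arm_fibrate", [])
        fit = cox_fit(cp, ["arm_fibrate"])
        diag = ph_diagnostic(fit, cp)
        assert diag["verdict"].iloc[0] == "violated"

    def test_under_two_events_undefined(self):
        rows = _rows([5, 6, 7], [1, 0, 0], [1, 0, 1])
        cp = expand_time_split(rows, "arm_fibrate", [])
        fit = cox_fit(cp, ["arm_fibrate"])
        diag = ph_diagnostic(fit, cp)
        assert (diag["verdict"] == "undefined").all()
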