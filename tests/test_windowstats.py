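"""Window mixed models, fast screening fits, and cross-validated selection."""

import numpy as np
import pandas as pd
import pytest

import pupilbreadth as pb
from pupilbreadth._lme import fit_random_intercept_lme
from pupilbreadth.windowstats import (WindowSpec, crossval_select_window,
                                      fit_interaction_lme, fit_window_lme,
                                      per_participant_effect,
                                      window_trial_means)

from conftest import DESK_PREPROC, desk_pupil_params


def _frames_from_means(y_by_pid_ecc):
    """Build minimal samples/trials frames with one in-window sample per trial."""
    rows_s, rows_t = [], []
    trial = 0
    for pid, eccs in y_by_pid_ecc.items():
        for ecc, ys in eccs.items():
            for y in np.atleast_1d(ys):
                trial += 1
                rows_t.append(dict(participant_id=pid, trial_index=trial,
                                   phase="experimental", excluded=False,
                                   cued_ecc=ecc, breadth_type="size"))
                rows_s.append(dict(participant_id=pid, trial_index=trial,
                                   t_ms=2550.0, pupil=float(y)))
    return pd.DataFrame(rows_s), pd.DataFrame(rows_t)


WINDOW = WindowSpec(2500.0, 2600.0)


class TestWindowLme:
    def test_intercepts_only_equals_ols_on_condition_means(self):
        # one observation per participant per condition: the mixed-model
        # eccentricity slope must equal the ordinary least-squares slope
        rng = np.random.default_rng(0)
        data = {f"p{i:02d}": {e: rng.normal(0.1 * c, 0.05)
                              for e, c in [("near", -1), ("medium", 0), ("far", 1)]}
                for i in range(8)}
        samples, trials = _frames_from_means(data)
        res = fit_window_lme(samples, trials, WINDOW, random_slopes=False)
        d = window_trial_means(samples, trials, WINDOW)
        b_ols = np.polyfit(d["ecc_code"], d["y"], 1)[0]
        assert res.b == pytest.approx(b_ols, rel=1e-7)

    def test_fewer_than_two_participants_refused(self):
        samples, trials = _frames_from_means(
            {"p01": {"near": [1, 2], "medium": [2], "far": [3]}})
        with pytest.raises(ValueError, match="2 participants"):
            fit_window_lme(samples, trials, WINDOW)

    def test_profiled_fit_matches_statsmodels_ml(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        g, n = 12, 40
        groups = np.repeat(np.arange(g), n)
        x = np.tile(rng.choice([-1.0, 0.0, 1.0], n), g)
        u = rng.normal(0, 0.5, g)
        y = 0.3 * x + u[groups] + rng.normal(0, 1.0, g * n)
        fast = fit_random_intercept_lme(y, x, groups)
        exog = np.column_stack([np.ones_like(x), x])
        ref = sm.MixedLM(y, exog, groups=groups, exog_re=exog[:, :1]).fit(reml=False)
        assert fast.b == pytest.approx(ref.params[1], rel=1e-4)
        assert fast.se == pytest.approx(ref.bse[1], rel=1e-2)


class TestPerParticipantEffect:
    def test_perfect_linearity_gives_r_one(self):
        samples, trials = _frames_from_means(
            {"p01": {"near": [-0.02, -0.02], "medium": [0.0, 0.0], "far": [0.02, 0.02]},
             "p02": {"near": [0.01], "medium": [0.0], "far": [-0.01]}})
        recs = {r.participant_id: r for r in
                per_participant_effect(samples, trials, WINDOW)}
        assert recs["p01"].r == pytest.approx(1.0)
        assert recs["p02"].r == pytest.approx(-1.0)

    def test_constant_pupil_is_degenerate_zero(self):
        samples, trials = _frames_from_means(
            {"p01": {"near": [0.5, 0.5], "medium": [0.5], "far": [0.5]}})
        rec = per_participant_effect(samples, trials, WINDOW)[0]
        assert rec.r == 0.0 and rec.degenerate

    def test_records_sorted_by_effect(self, desk_processed):
        samples, trials, _ = desk_processed
        recs = per_participant_effect(samples, trials, WINDOW)
        rs = [r.r for r in recs]
        assert rs == sorted(rs)
        assert len(recs) == 10


@pytest.fixture(scope="module")
def exp3_processed():
    pupil = desk_pupil_params()
    samples, trials = pb.generate_dataset(8, "exp3", None, pupil, seed=21,
                                          include_practice=False,
                                          trace_duration_ms=3100.0)
    s, t, _ = pb.run_preprocessing(
        samples, trials, pb.PreprocParams(**DESK_PREPROC))
    return s, t


class TestInteraction:
    def test_terms_and_reference_level(self, exp3_processed):
        s, t = exp3_processed
        res = fit_interaction_lme(s, t, WINDOW)
        assert [r.term for r in res] == [
            "cue_eccentricity", "breadth_type[location]",
            "cue_eccentricity:breadth_type"]
        assert all(r.random_structure == "intercepts_only" for r in res)

    def test_symmetrized_dataset_kills_breadth_type_terms(self, exp3_processed):
        # duplicating every trial with the breadth-type label flipped makes
        # the data exactly symmetric in type: the eccentricity effect is
        # invariant to a further relabeling and the type terms vanish
        s, t = exp3_processed
        flipped = t.copy()
        flipped["breadth_type"] = flipped["breadth_type"].map(
            {"size": "location", "location": "size"})
        flipped["trial_index"] = flipped["trial_index"] + 10_000
        s_f = pd.concat([s, s.assign(trial_index=s["trial_index"] + 10_000)],
                        ignore_index=True)
        t_dup = pd.concat([t, flipped], ignore_index=True)
        res = fit_interaction_lme(s_f, t_dup, WINDOW)
        t_relabel = t_dup.copy()
        t_relabel["breadth_type"] = t_relabel["breadth_type"].map(
            {"size": "location", "location": "size"})
        res2 = fit_interaction_lme(s_f, t_relabel, WINDOW)
        assert res2[0].b == pytest.approx(res[0].b, rel=1e-6)
        assert abs(res[0].stat) == pytest.approx(abs(res2[0].stat), rel=1e-6)
        assert abs(res[2].b) < 1e-8  # interaction exactly zero by symmetry

    def test_single_breadth_type_refused(self, desk_processed):
        samples, trials, _ = desk_processed  # exp1: size only
        with pytest.raises(ValueError, match="both breadth types"):
            fit_interaction_lme(samples, trials, WINDOW)


class TestCrossVal:
    def test_no_leakage_and_window_inside_search(self, desk_processed):
        samples, trials, _ = desk_processed
        cv = crossval_select_window(samples, trials, seed=3)
        assert len(cv.fold_peaks) == 4
        all_pids = set(trials["participant_id"].unique())
        seen = set()
        for held, train in zip(cv.fold_heldout_participants,
                               cv.fold_train_participants):
            assert set(held).isdisjoint(train)
            assert set(held) | set(train) == all_pids
            seen |= set(held)
        assert seen == all_pids
        w = cv.selected_window
        assert 750 <= w.start_ms < w.end_ms <= 3000
        assert w.end_ms - w.start_ms == 100

    def test_crossval_is_seed_deterministic(self, desk_processed):
        samples, trials, _ = desk_processed
        a = crossval_select_window(samples, trials, seed=5)
        b = crossval_select_window(samples, trials, seed=5)
        assert a.selected_window == b.selected_window
        assert a.fold_peaks == b.fold_peaks
        assert a.fulldata_fit == b.fulldata_fit

    def test_too_few_participants_refused(self):
        pupil = desk_pupil_params()
        samples, trials = pb.generate_dataset(4, "exp1", None, pupil, seed=0,
                                              include_practice=False,
                                              max_experimental_trials=24,
                                              trace_duration_ms=3100.0)
        s, t, _ = pb.run_preprocessing(
            samples, trials, pb.PreprocParams(**DESK_PREPROC))
        with pytest.raises(ValueError, match="participants"):
            crossval_select_window(s, t)

    def test_strong_effect_recovers_plateau_window(self):
        pupil = desk_pupil_params(breadth_slope_mm=0.05, slope_sd_between=0.01)
        samples, trials = pb.generate_dataset(12, "exp1", None, pupil, seed=31,
                                              include_practice=False,
                                              trace_duration_ms=3100.0)
        s, t, _ = pb.run_preprocessing(
            samples, trials, pb.PreprocParams(**DESK_PREPROC))
        cv = crossval_select_window(s, t, seed=31)
        # effect ramps to a plateau at 2500 ms; peaks live beyond the ramp
        assert 2000 <= cv.selected_window.start_ms <= 2900
        assert cv.fulldata_fit.p < 0.05
        assert cv.fulldata_fit.b > 0
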