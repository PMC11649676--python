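"""DTA semantics: sustained-crossing rule, censoring conventions, bootstrap
CIs, lag-profile construction and the CTD/TTA arithmetic."""

import numpy as np
import pytest
from scipy.interpolate import PchipInterpolator

from eegdta import anticipation as ant
from eegdta.preprocessing import DEFAULT_LAG_GRID
from eegdta.simulate import Recording, TrialEvent

LAGS = np.asarray(DEFAULT_LAG_GRID)


def profile(tpr, outcomes=None):
    return ant.LagProfile(LAGS, np.asarray(tpr, float),
                          np.full(len(LAGS), 16), outcomes)


def brute_force_dta(lags_s, tpr, k):
    """Independent oracle: dense 1 ms scan of the monotone spline."""
    interp = PchipInterpolator(np.asarray(lags_s) * 1000.0, tpr)
    dta = None
    for ms in range(0, int(lags_s[-1] * 1000) + 1):
        if interp(ms) < k / 100.0:
            return dta, ("undefined" if dta is None else "estimated")
        dta = float(ms)
    return dta, "censored_at_grid_max"


class TestEstimateDta:
    def test_never_dropping_profile_is_censored(self):
        est = ant.estimate_dta(profile(np.ones(11)), 75, n_boot=0)
        assert est.status == "censored_at_grid_max"
        assert est.dta_ms == 1000.0

    def test_below_threshold_at_lag_zero_is_undefined(self):
        tpr = [0.6] + [0.5] * 10
        est = ant.estimate_dta(profile(tpr), 75, n_boot=0)
        assert est.status == "undefined" and est.dta_ms is None

    def test_sustained_rule_blocks_recrossing(self):
        """A dip below k at 500 ms blocks the 0.76 re-crossing at 600 ms."""
        tpr = [0.95, 0.90, 0.85, 0.80, 0.78, 0.74, 0.76, 0.70, 0.65,
               0.60, 0.55]
        est = ant.estimate_dta(profile(tpr), 75, n_boot=0)
        assert est.status == "estimated"
        assert 400 < est.dta_ms < 500
        expected, _ = brute_force_dta(LAGS, tpr, 75)
        assert est.dta_ms == expected

    def test_monotone_profile_crossing_at_knot_returns_knot(self):
        tpr = [0.95, 0.90, 0.85, 0.80, 0.75, 0.70, 0.65, 0.60, 0.55,
               0.50, 0.45]
        est = ant.estimate_dta(profile(tpr), 75, n_boot=0)
        assert est.dta_ms == 400.0 and est.status == "estimated"

    @pytest.mark.parametrize("k", [-1, 0, 100, 150])
    def test_k_out_of_range(self, k):
        with pytest.raises(ValueError):
            ant.estimate_dta(profile(np.ones(11)), k)

    def test_matches_brute_force_oracle_on_random_profiles(self, rng):
        for _ in range(100):
            tpr = np.round(rng.random(11), 3)
            for k in (70, 75, 80):
                est = ant.estimate_dta(profile(tpr), k, n_boot=0)
                dta, status = brute_force_dta(LAGS, tpr, k)
                assert est.status == status
                assert est.dta_ms == dta

    def test_monotone_in_k(self, rng):
        """Raising the consistency requirement can only shorten the DTA."""
        for _ in range(50):
            tpr = rng.random(11)
            vals = []
            for k in (70, 75, 80):
                est = ant.estimate_dta(profile(tpr), k, n_boot=0)
                vals.append(-1.0 if est.status == "undefined"
                            else est.dta_ms)
            assert vals[0] >= vals[1] >= vals[2]

    def test_interpolant_never_overshoots(self, rng):
        for _ in range(20):
            tpr = rng.random(11)
            interp = profile(tpr).interpolant
            for j in range(10):
                dense = interp(np.linspace(LAGS[j], LAGS[j + 1], 50))
                lo, hi = sorted((tpr[j], tpr[j + 1]))
                assert dense.min() >= lo - 1e-9
                assert dense.max() <= hi + 1e-9


class TestBootstrap:
    def test_ci_contains_estimate_and_is_seeded(self, rng):
        outcomes = (rng.random((24, 11)) <
                    np.linspace(0.95, 0.4, 11)).astype(int)
        prof = profile(outcomes.mean(axis=0), outcomes)
        a = ant.estimate_dta(prof, 75, n_boot=200, seed=9)
        b = ant.estimate_dta(prof, 75, n_boot=200, seed=9)
        assert a == b
        if a.status == "estimated":
            assert a.ci_ms[0] <= a.dta_ms <= a.ci_ms[1]

    def test_ci_calibration_on_known_truth(self):
        """The 95% trial-bootstrap CI covers the generating-curve DTA in at
        least 90% of simulated profiles."""
        true_tpr = np.linspace(0.97, 0.45, 11)
        true_dta, status = brute_force_dta(LAGS, true_tpr, 75)
        assert status == "estimated"
        rng = np.random.default_rng(0)
        n_trials, covered, sims = 48, 0, 200
        for s in range(sims):
            outcomes = (rng.random((n_trials, 11)) < true_tpr).astype(int)
            prof = profile(outcomes.mean(axis=0), outcomes)
            est = ant.estimate_dta(prof, 75, n_boot=300, seed=s)
            if est.ci_ms and est.ci_ms[0] <= true_dta <= est.ci_ms[1]:
                covered += 1
        assert covered / sims >= 0.90


class _ConstantClassifier:
    def __init__(self, label=1):
        self.label = label

    def predict(self, X):
        return np.full(len(X), self.label)


class _Channel0MeanClassifier:
    """Analytic rule: anticipation iff channel 0's window mean exceeds 0.5."""

    def predict(self, X):
        return (np.asarray(X)[:, 0, :].mean(axis=1) > 0.5).astype(int)


def _profile_recording(n_trials=16, positive_trials=12):
    srate = 500
    spacing = 3000
    n = 3000 + spacing * n_trials
    data = np.zeros((2, n))
    events = []
    for i in range(n_trials):
        cue = 3000 + i * spacing
        events.append(TrialEvent(cue, cue + 500, "left"))
        if i < positive_trials:
            data[0, cue - 1000: cue + 1000] = 1.0  # covers every lag window
    return Recording(data, srate, ["Cz", "C3"], events)


class TestComputeLagProfile:
    def test_always_positive_classifier_gives_unity(self):
        rec = _profile_recording()
        prof = ant.compute_lag_profile(_ConstantClassifier(1), rec)
        assert np.all(prof.tpr == 1.0)

    def test_tpr_is_exact_fraction(self):
        rec = _profile_recording(16, positive_trials=12)
        prof = ant.compute_lag_profile(_Channel0MeanClassifier(), rec)
        assert np.all(prof.tpr == 0.75)
        assert prof.outcomes.shape == (16, 11)

    def test_trial_subset_restricts_profile(self):
        rec = _profile_recording(16, positive_trials=12)
        prof = ant.compute_lag_profile(_Channel0MeanClassifier(), rec,
                                       trial_subset=np.arange(12))
        assert np.all(prof.tpr == 1.0)
        assert len(prof.outcomes) == 12

    def test_missing_windows_raise(self):
        rec = _profile_recording(4)
        with pytest.raises(ValueError):
            ant.compute_lag_profile(_ConstantClassifier(), rec,
                                    edge_exclude=rec.n_samples // 2)


class TestCtdAndTta:
    def test_identity_pipeline_near_zero(self):
        epochs = np.zeros((4, 2, 100))
        budget = ant.measure_ctd(lambda e: e, lambda e: 1, epochs,
                                 n_reps=20)
        assert 0 <= budget.ctd_ms < 50
        assert budget.ctd_ms == pytest.approx(
            budget.preprocess_mean_ms + budget.inference_mean_ms)

    def test_longer_epochs_not_cheaper(self):
        short = np.random.default_rng(0).standard_normal((4, 8, 2000))
        long = np.random.default_rng(0).standard_normal((4, 8, 4000))
        fn = lambda e: np.fft.rfft(e, axis=-1)
        b_short = ant.measure_ctd(fn, lambda e: 1, short, n_reps=30)
        b_long = ant.measure_ctd(fn, lambda e: 1, long, n_reps=30)
        assert b_long.preprocess_mean_ms >= 0.3 * b_short.preprocess_mean_ms

    def test_few_reps_warns(self):
        with pytest.warns(RuntimeWarning):
            ant.measure_ctd(lambda e: e, lambda e: 1, np.zeros((2, 1, 10)),
                            n_reps=5)

    def test_tta_arithmetic_examples(self):
        est = ant.DtaEstimate(75, 590.0, "estimated")
        tta = ant.compute_tta(est, 422.6)
        assert tta.tta_ms == pytest.approx(167.4)
        assert round(tta.tta_ms, -1) == 170.0
        tta2 = ant.compute_tta(ant.DtaEstimate(75, 290.0, "estimated"),
                               270.1)
        assert tta2.tta_ms == pytest.approx(19.9)
        assert round(tta2.tta_ms, -1) == 20.0

    def test_zero_ctd_passthrough(self):
        est = ant.DtaEstimate(75, 300.0, "estimated")
        assert ant.compute_tta(est, 0.0).tta_ms == 300.0

    def test_censored_or_undefined_dta_rejected(self):
        for status in ("censored_at_grid_max", "undefined"):
            est = ant.DtaEstimate(75, None, status)
            with pytest.raises(ValueError, match="status"):
                ant.compute_tta(est, 100.0)
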