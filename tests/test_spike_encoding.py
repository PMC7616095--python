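"""PSTH z-scoring/smoothing, design-matrix coding rules, Poisson-GLM
recovery and calibration, and the shuffled-baseline window test."""
import numpy as np
import pytest

from dopadist.spike_encoding import (
    REGRESSORS,
    DesignMatrix,
    EncodingFit,
    build_design_matrix,
    classify_encoding,
    compute_psth,
    event_window_rate,
    fit_poisson_encoding_glm,
    gaussian_kernel_5tap,
)
from dopadist.task_synth import (
    PopulationTemplate,
    SessionEvents,
    SpikeTrain,
    TaskConfig,
    generate_session_events,
    simulate_spike_train,
)


def homogeneous_train(rate_hz, duration, seed, unit_id="hom"):
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate_hz * duration)
    return SpikeTrain(unit_id, np.unique(rng.uniform(0, duration, n)))


class TestPSTH:
    def test_window_and_bin_count(self, session_events, dls_train):
        psth = compute_psth(dls_train, session_events)
        assert psth.mean_z.size == 125               # 5 s / 40 ms
        assert psth.bin_edges_s[0] == pytest.approx(-1.0)
        assert np.allclose(np.diff(psth.bin_edges_s), 0.040)

    def test_kernel_unit_sum_and_5_taps(self):
        k = gaussian_kernel_5tap()
        assert k.size == 5
        assert k.sum() == pytest.approx(1.0)

    def test_constant_input_unchanged_by_smoothing(self, session_events):
        train = homogeneous_train(8.0, session_events.session_duration_s, 0)
        psth = compute_psth(train, session_events)
        const = np.full(125, 2.5)
        smoothed = np.convolve(const, psth.kernel, mode="same")
        smoothed /= np.convolve(np.ones(125), psth.kernel, mode="same")
        np.testing.assert_allclose(smoothed, const)

    def test_baseline_z_mean_zero_by_construction(self, session_events):
        train = homogeneous_train(10.0, session_events.session_duration_s, 1)
        psth = compute_psth(train, session_events)
        centers = psth.bin_edges_s[:-1] + 0.020
        base_cols = (centers >= -1.0) & (centers < 0.0)
        assert psth.z_trials[:, base_cols].mean() == pytest.approx(0.0, abs=1e-12)

    def test_homogeneous_unit_post_event_z_small(self, session_events):
        train = homogeneous_train(10.0, session_events.session_duration_s, 2)
        psth = compute_psth(train, session_events)
        centers = psth.bin_edges_s[:-1] + 0.020
        assert np.abs(psth.z_trials[:, centers > 0].mean(axis=0)).mean() < 0.2

    def test_silent_unit_flagged(self, session_events):
        psth = compute_psth(SpikeTrain("mute", np.empty(0)), session_events)
        assert psth.silent and psth.z_trials is None


def _hand_session():
    """One cue at t=10 s with a lick bout engineered for the 75% rule."""
    return SessionEvents(
        cue_onsets_s=np.array([10.0]),
        reward_times_s=np.array([12.0]),
        lick_bouts=[(10.45, 10.72)],
        movement_bouts=[(14.0, 14.4)],
        session_duration_s=20.0,
    )


class TestDesignMatrix:
    def test_cue_coded_for_two_bins_from_onset(self):
        ev = _hand_session()
        dm = build_design_matrix(SpikeTrain("u", np.array([10.1])), ev)
        starts = np.round(dm.bin_starts_s, 6)
        cue = dict(zip(starts, dm.regressors["cue"]))
        assert cue[10.0] == 1 and cue[10.2] == 1 and cue[10.4] == 0
        reward = dict(zip(starts, dm.regressors["reward"]))
        assert reward[12.0] == 1 and reward[12.2] == 1 and reward[12.4] == 0

    def test_lick_75_percent_overlap_rule(self):
        # bout (10.45, 10.72): overlap 0.15 s (=75%) with [10.4, 10.6) -> 1;
        # overlap 0.12 s (=60%) with [10.6, 10.8) -> 0
        ev = _hand_session()
        dm = build_design_matrix(SpikeTrain("u", np.array([10.1])), ev)
        starts = np.round(dm.bin_starts_s, 6)
        lick = dict(zip(starts, dm.regressors["lick"]))
        assert lick[10.4] == 1 and lick[10.6] == 0

    def test_bins_tile_session_and_counts_match(self, session_events, dls_train):
        dm = build_design_matrix(dls_train, session_events)
        # contiguous 200-ms tiling within each trial segment
        gaps = np.diff(dm.bin_starts_s)
        assert np.all(gaps > 0.2 - 1e-9)
        assert dm.counts.sum() <= dls_train.spike_times_s.size
        assert dm.counts.sum() >= 0.9 * dls_train.spike_times_s.size

    def test_bout_outside_session_rejected(self):
        ev = _hand_session()
        ev.lick_bouts = [(19.0, 25.0)]
        with pytest.raises(ValueError):
            build_design_matrix(SpikeTrain("u", np.array([10.1])), ev)

    def test_coding_independent_of_spike_train(self, session_events, dls_train):
        dm1 = build_design_matrix(dls_train, session_events)
        dm2 = build_design_matrix(SpikeTrain("v", np.array([50.0])), session_events)
        for k in REGRESSORS:
            np.testing.assert_array_equal(dm1.regressors[k], dm2.regressors[k])


@pytest.fixture(scope="module")
def session_design(session_events):
    """Design matrix of the shared 100-trial session (counts ignored)."""
    return build_design_matrix(SpikeTrain("tmp", np.array([1.0])), session_events)


def simulate_counts(design, beta, rng, intercept=np.log(2.0)):
    """Bin-level Poisson oracle: counts ~ Poisson(exp(intercept + X beta))."""
    eta = intercept + design.matrix() @ np.asarray(beta, float)
    y = rng.poisson(np.exp(eta) * 1.0)
    return DesignMatrix(design.bin_starts_s, y, design.regressors, design.bin_s)


class TestPoissonGLM:
    def test_reward_coefficient_ci_coverage(self, session_design):
        """beta_reward = ln 2 lies in its 95% Wald CI in ~95% of runs."""
        rng = np.random.default_rng(1234)
        true_beta = {"cue": 0.0, "reward": np.log(2.0), "lick": 0.0, "movement": 0.0}
        beta_vec = [true_beta[k] for k in REGRESSORS]
        hits = 0
        n_runs = 200
        for _ in range(n_runs):
            dm = simulate_counts(session_design, beta_vec, rng, intercept=np.log(10 * 0.2))
            fit = fit_poisson_encoding_glm(dm)
            lo = fit.coef["reward"] - 1.96 * fit.bse["reward"]
            hi = fit.coef["reward"] + 1.96 * fit.bse["reward"]
            hits += lo <= np.log(2.0) <= hi
        assert hits / n_runs >= 0.93

    def test_null_unit_type_i_error_nominal(self, session_design):
        """No modulation: each coefficient rejects at ~5%."""
        rng = np.random.default_rng(99)
        n_runs = 150
        rejections = []
        for _ in range(n_runs):
            dm = simulate_counts(session_design, [0, 0, 0, 0], rng,
                                 intercept=np.log(8 * 0.2))
            fit = fit_poisson_encoding_glm(dm)
            rejections.extend(fit.pvalues[k] < 0.05 for k in REGRESSORS)
        rate = np.mean(rejections)
        assert rate == pytest.approx(0.05, abs=0.025)

    def test_deviance_gof_calibrated_on_well_specified_units(self, session_design):
        """At bin means large enough for the chi-square approximation of the
        deviance, well-specified units are rejected at ~ the nominal rate."""
        rng = np.random.default_rng(7)
        rejects = 0
        n_runs = 100
        for _ in range(n_runs):
            dm = simulate_counts(session_design, [0.3, 0.5, 0.2, -0.2], rng,
                                 intercept=np.log(30.0))
            fit = fit_poisson_encoding_glm(dm)
            rejects += fit.gof_p < 0.05
        assert rejects / n_runs == pytest.approx(0.05, abs=0.06)

    def test_saturated_fit_zero_deviance(self):
        # every unique regressor pattern carries a constant count
        starts = np.arange(8) * 0.2
        reg = {"cue": np.array([1, 1, 0, 0, 0, 0, 0, 0], float),
               "reward": np.array([0, 0, 1, 1, 0, 0, 0, 0], float),
               "lick": np.zeros(8), "movement": np.zeros(8)}
        counts = np.array([4, 4, 6, 6, 2, 2, 2, 2])
        fit = fit_poisson_encoding_glm(DesignMatrix(starts, counts, reg))
        assert fit.deviance == pytest.approx(0.0, abs=1e-8)

    def test_all_zero_counts_rejected(self, session_design):
        dm = DesignMatrix(session_design.bin_starts_s,
                          np.zeros_like(session_design.counts),
                          session_design.regressors)
        with pytest.raises(ValueError):
            fit_poisson_encoding_glm(dm)


class TestClassification:
    def test_dominant_by_absolute_coefficient(self):
        fit = EncodingFit(
            intercept=1.0,
            coef={"cue": 0.2, "reward": -0.5, "lick": 0.1, "movement": 0.0},
            bse={k: 0.1 for k in REGRESSORS},
            pvalues={"cue": 0.01, "reward": 0.001, "lick": 0.3, "movement": 0.9},
            deviance=10.0, df_resid=100, gof_p=0.5)
        cls = classify_encoding(fit)
        assert cls.significant == {"cue", "reward"}
        assert cls.dominant == "reward"
        assert cls.multiplexing_count == 2

    def test_no_significant_means_none(self):
        fit = EncodingFit(
            intercept=1.0, coef={k: 0.1 for k in REGRESSORS},
            bse={k: 1.0 for k in REGRESSORS},
            pvalues={k: 0.5 for k in REGRESSORS},
            deviance=10.0, df_resid=100, gof_p=0.5)
        assert classify_encoding(fit).dominant == "none"

    def test_dms_cohort_rarely_flags_reward(self):
        """Ground-truth recovery: DMS units (no reward modulation) should
        almost never include 'reward' in their significant set."""
        from dopadist.task_synth import build_population_session
        cfg = TaskConfig(n_trials=60, seed=31)
        sess = build_population_session("DMS", 10, cfg)
        flagged = 0
        for train in sess.spike_trains:
            dm = build_design_matrix(train, sess.events)
            cls = classify_encoding(fit_poisson_encoding_glm(dm))
            flagged += "reward" in cls.significant
        assert flagged <= 1                          # >= 90% exclude reward


class TestEventWindowRate:
    def test_empty_train_rate_zero(self, short_events):
        rate, _ = event_window_rate(SpikeTrain("e", np.empty(0)), short_events,
                                    rng=np.random.default_rng(0), shuffles=100)
        assert rate == 0.0

    def test_homogeneous_rate_and_null_p_uniform(self, short_events):
        dur = short_events.session_duration_s
        ps = []
        rates = []
        for seed in range(60):
            train = homogeneous_train(10.0, dur, seed + 100)
            r, p = event_window_rate(train, short_events, "reward",
                                     shuffles=200, rng=np.random.default_rng(seed))
            ps.append(p)
            rates.append(r)
        assert np.mean(rates) == pytest.approx(10.0, rel=0.05)
        assert np.mean(np.asarray(ps) < 0.05) == pytest.approx(0.05, abs=0.06)

    def test_reward_gain_detected_in_most_seeds(self, short_events):
        from dopadist.task_synth import EventModulation
        tmpl = PopulationTemplate(
            population="VLS", tonic_rate_hz=6.0,
            reward=EventModulation(3.0, 0.04, 0.2))
        hits = 0
        for seed in range(20):
            train = simulate_spike_train(tmpl, short_events,
                                         np.random.default_rng(seed))
            _, p = event_window_rate(train, short_events, "reward",
                                     shuffles=200, rng=np.random.default_rng(seed))
            hits += p < 0.05
        assert hits >= 19

    def test_too_few_shuffles_rejected(self, short_events, dls_train):
        with pytest.raises(ValueError):
            event_window_rate(dls_train, short_events, shuffles=10)
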