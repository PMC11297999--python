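import numpy as np
import pytest
from dataclasses import replace

from multiscale_rc import (
    EchoStateNetwork,
    TimeSeries,
    check_convergence,
    estimate_psd,
    grid_search,
    infer_stable_states,
    psd_distance,
)
from multiscale_rc.tuning import StableStates
from multiscale_rc.experiments import reservoir_config_from


def test_square_wave_centers_are_exact():
    vals = np.concatenate([np.full(120, -1.0), np.full(120, 1.0), np.full(120, -1.0)])
    states = infer_stable_states(TimeSeries(vals[:, None], dt=1.0))
    np.testing.assert_allclose(np.sort(states.centers.ravel()), [-1.0, 1.0])


def test_constant_series_single_center():
    states = infer_stable_states(TimeSeries(np.full((60, 1), 3.7), dt=1.0))
    assert states.k == 1
    assert states.centers.ravel()[0] == pytest.approx(3.7)


def test_double_well_centers_near_wells(eq9_series):
    states = infer_stable_states(eq9_series)
    assert states.k == 2
    centers = np.sort(states.centers.ravel())
    assert abs(centers[0] + 1.0) < 0.15
    assert abs(centers[1] - 1.0) < 0.15


def test_no_surviving_segment_is_an_error():
    rng = np.random.default_rng(0)
    vals = rng.standard_normal((40, 1)) * np.where(np.arange(40) % 2, 1, 100)[:, None]
    with pytest.raises(ValueError, match="threshold"):
        infer_stable_states(TimeSeries(vals, dt=1.0), jump_threshold=1e-6,
                            min_segment=30)


def test_scale_equivariance(eq9_series):
    base = infer_stable_states(eq9_series)
    scaled = infer_stable_states(
        TimeSeries(eq9_series.values * 3.0, dt=eq9_series.dt),
        jump_threshold=base.jump_threshold * 3.0,
    )
    np.testing.assert_allclose(scaled.centers, 3.0 * base.centers, atol=1e-9)


# -- convergence score --------------------------------------------------

class _EulerMapModel:
    """A stand-in slow model that applies the exact Euler map of the well."""

    class _Cfg:
        n_nodes = 1

    config = _Cfg()
    n_inputs = 1
    is_trained = True
    input_range = (np.array([-2.0]), np.array([2.0]))

    def step(self, r, u):
        return np.asarray(u, dtype=float)

    def readout(self, r):
        u = r[0]
        return np.array([u + 0.01 * (-5.0) * (-u + u ** 3)])


def test_exact_euler_map_scores_one():
    states = StableStates(centers=np.array([[-1.0], [1.0]]), jump_threshold=0.0,
                          segment_count=2)
    assert check_convergence(_EulerMapModel(), states, horizon=2000) == 1.0


def test_zero_readout_scores_zero(small_config, eq9_series):
    esn = EchoStateNetwork(small_config, n_inputs=1)
    esn.set_input_scale(eq9_series.values)
    esn.W_out = np.zeros((1, small_config.n_nodes))
    states = StableStates(centers=np.array([[-1.0], [1.0]]), jump_threshold=0.0,
                          segment_count=2)
    assert check_convergence(esn, states, horizon=200) == 0.0


def test_trained_fixture_converges(example1_esn):
    states = StableStates(centers=np.array([[-1.0], [1.0]]), jump_threshold=0.0,
                          segment_count=2)
    score = check_convergence(example1_esn, states,
                              start_range=(np.array([-2.0]), np.array([2.0])))
    assert score >= 0.9


# -- PSD ----------------------------------------------------------------

def test_sinusoid_peak_lands_in_the_right_bin():
    t = np.arange(8192) * 0.01
    f0 = 3.0
    series = TimeSeries(np.sin(2 * np.pi * f0 * t)[:, None], dt=0.01)
    spec = estimate_psd(series)
    peak = spec.frequencies[np.argmax(spec.power[:, 0])]
    df = spec.frequencies[1] - spec.frequencies[0]
    assert abs(peak - f0) <= df


def test_white_noise_spectrum_is_flat():
    rng = np.random.default_rng(1)
    series = TimeSeries(rng.standard_normal((100_000, 1)), dt=1.0)
    spec = estimate_psd(series)
    n = len(spec.frequencies)
    central = spec.power[n // 10: -n // 10, 0]
    assert central.max() / central.min() < 10


def test_constant_series_has_no_ac_power():
    series = TimeSeries(np.full((4096, 1), 2.5), dt=1.0)
    spec = estimate_psd(series)
    # the DC line leaks only into the adjacent bin of the tapered estimate
    assert np.all(spec.power[1:] < 1e-20)


def test_short_series_rejected():
    with pytest.raises(ValueError):
        estimate_psd(TimeSeries(np.zeros((100, 1)) + np.arange(100)[:, None], dt=1.0))


def test_psd_distance_closed_forms():
    t = np.arange(4096) * 0.1
    series = TimeSeries(np.sin(t)[:, None] + 0.1, dt=0.1)
    spec = estimate_psd(series)
    assert psd_distance(spec, spec) == 0.0
    scaled = estimate_psd(TimeSeries(series.values * np.sqrt(10), dt=0.1))
    assert psd_distance(scaled, spec) == pytest.approx(1.0, abs=1e-9)


def test_psd_grid_mismatch_rejected():
    a = estimate_psd(TimeSeries(np.random.default_rng(0).standard_normal((2048, 1)), dt=1.0))
    b = estimate_psd(TimeSeries(np.random.default_rng(0).standard_normal((512, 1)), dt=1.0))
    with pytest.raises(ValueError):
        psd_distance(a, b)


def test_trained_model_beats_random_readout_on_psd(example1_esn, eq9_series,
                                                   example1_noise):
    from multiscale_rc import NoiseModel, rolling_predict

    ref = estimate_psd(eq9_series)

    def prediction_distance(esn):
        fc = rolling_predict(esn, example1_noise, eq9_series.values[-1], 5000, seed=3,
                             dt=eq9_series.dt)
        spec = estimate_psd(fc.prediction, nperseg=ref.settings["nperseg"])
        ref5 = estimate_psd(eq9_series.window(0, 5001), nperseg=ref.settings["nperseg"])
        return psd_distance(spec, ref5)

    good = prediction_distance(example1_esn)

    import copy
    bad_esn = copy.copy(example1_esn)
    rng = np.random.default_rng(12)
    bad_esn.W_out = rng.standard_normal(example1_esn.W_out.shape) * 0.01
    bad = prediction_distance(bad_esn)
    assert good < bad


# -- grid search --------------------------------------------------------

def test_grid_search_single_candidate(eq9_series, example1_config):
    config = reservoir_config_from(example1_config, seed=5)
    ranked = grid_search([config], eq9_series.window(0, 3001), criterion="convergence")
    assert len(ranked) == 1
    assert 0.0 <= ranked[0][1] <= 1.0


def test_grid_search_identical_candidates_tie(eq9_series, example1_config):
    config = reservoir_config_from(example1_config, seed=5)
    ranked = grid_search([config, config], eq9_series.window(0, 3001))
    assert ranked[0][1] == ranked[1][1]


def test_fixture_outranks_fast_leak_variant(eq9_series, example1_config):
    """The printed leak rate beats a badly mismatched (too slow) one."""
    good = reservoir_config_from(example1_config, seed=5)
    slow = replace(good, leak_rate=0.01)
    ranked = grid_search([slow, good], eq9_series, criterion="convergence")
    assert ranked[0][0].leak_rate == good.leak_rate
    assert ranked[0][1] > ranked[1][1]
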