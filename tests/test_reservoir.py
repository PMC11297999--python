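import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from multiscale_rc import EchoStateNetwork, ReservoirConfig, TimeSeries, fit_readout


def test_construction_contract(small_config):
    esn = EchoStateNetwork(small_config, n_inputs=2)
    N, D = small_config.n_nodes, small_config.degree
    nnz = esn.A.nnz
    mean, sd = N * D, np.sqrt(N * D)
    assert abs(nnz - mean) < 3 * sd
    radius = np.abs(np.linalg.eigvals(esn.A.toarray())).max()
    assert radius == pytest.approx(small_config.spectral_radius, rel=1e-6)
    assert np.all(np.abs(esn.W_in) <= small_config.input_scaling)
    assert np.array_equal(esn.r, np.zeros(N))


def test_zero_spectral_radius_gives_zero_matrix():
    config = ReservoirConfig(n_nodes=50, degree=3, spectral_radius=0.0, leak_rate=0.5)
    esn = EchoStateNetwork(config, n_inputs=1)
    assert esn.A.nnz == 0


def test_degree_larger_than_size_rejected():
    with pytest.raises(ValueError):
        ReservoirConfig(n_nodes=10, degree=11)


def test_example1_fixture_values(example1_config):
    r = example1_config["reservoir"]
    assert (r["n_nodes"], r["input_scaling"], r["degree"]) == (800, 4.0, 4.0)
    assert r["spectral_radius"] == pytest.approx(1.2e-3)
    assert r["leak_rate"] == 0.2
    assert r["ridge_beta"] == pytest.approx(1e-8)


def test_step_frozen_reservoir_limit(small_config):
    from dataclasses import replace
    esn = EchoStateNetwork(replace(small_config, leak_rate=1e-12), n_inputs=1)
    r = np.random.default_rng(0).standard_normal(small_config.n_nodes)
    out = esn.step(r, np.array([0.7]))
    np.testing.assert_allclose(out, r, atol=1e-10)


def test_step_definition_case(small_config):
    esn = EchoStateNetwork(small_config, n_inputs=1)
    a = small_config.leak_rate
    u = np.array([0.45])
    out = esn.step(np.zeros(small_config.n_nodes), u)
    expected = a * np.tanh(esn.W_in @ (u / esn.input_scale))
    np.testing.assert_allclose(out, expected, atol=1e-14)


def test_step_is_bounded(small_config):
    esn = EchoStateNetwork(small_config, n_inputs=1)
    a = small_config.leak_rate
    r = np.random.default_rng(1).uniform(-1, 1, small_config.n_nodes)
    out = esn.step(r, np.array([100.0]))
    assert np.all(np.abs(out) <= (1 - a) * np.abs(r) + a + 1e-12)


def test_collect_states_boundary_count(small_config):
    from dataclasses import replace
    config = replace(small_config, washout=5)
    esn = EchoStateNetwork(config, n_inputs=1)
    series = TimeSeries(np.linspace(0, 1, 7)[:, None], dt=1.0)
    esn.set_input_scale(series.values)
    R, U = esn.collect_states(series)
    assert R.shape[1] == 1 and U.shape[1] == 1

    with pytest.raises(ValueError):
        esn.collect_states(series.window(0, 6))


def test_constant_input_zero_recurrence_converges(small_config):
    from dataclasses import replace
    config = replace(small_config, spectral_radius=0.0, washout=50)
    esn = EchoStateNetwork(config, n_inputs=1)
    series = TimeSeries(np.full((120, 1), 0.8), dt=1.0)
    esn.set_input_scale(np.array([[1.0], [-1.0]]))
    R, _ = esn.collect_states(series)
    assert np.abs(R - R[:, -1:]).max() < 1e-8


def test_echo_state_property_on_example1_fixture(example1_esn, eq9_series):
    """Two different initial states forget their past under the same input."""
    esn = example1_esn
    inputs = eq9_series.values[:1200]
    rng = np.random.default_rng(5)
    r1 = np.zeros(esn.config.n_nodes)
    r2 = rng.uniform(-1, 1, esn.config.n_nodes)
    for u in inputs:
        r1 = esn.step(r1, u)
        r2 = esn.step(r2, u)
    assert np.linalg.norm(r1 - r2) < 1e-6


def test_twin_states_contract_monotonically(example1_esn, eq9_series):
    esn = example1_esn
    rng = np.random.default_rng(8)
    r1 = np.zeros(esn.config.n_nodes)
    r2 = rng.uniform(-0.5, 0.5, esn.config.n_nodes)
    gaps = []
    for u in eq9_series.values[:80]:
        r1, r2 = esn.step(r1, u), esn.step(r2, u)
        gaps.append(np.linalg.norm(r1 - r2))
    assert all(b <= a for a, b in zip(gaps[50:], gaps[51:]))


# -- readout ------------------------------------------------------------

def test_self_fit_recovers_identity():
    rng = np.random.default_rng(2)
    R = rng.standard_normal((6, 6)) + np.eye(6)
    W = fit_readout(R, R, beta=0.0)
    np.testing.assert_allclose(W, np.eye(6), atol=1e-8)


def test_heavy_regularisation_shrinks_readout():
    rng = np.random.default_rng(3)
    R = rng.standard_normal((5, 30))
    U = rng.standard_normal((2, 30))
    W = fit_readout(R, U, beta=1e12)
    assert np.linalg.norm(W) < 1e-6 * np.linalg.norm(U @ R.T)


def test_singular_gram_with_zero_beta_raises():
    R = np.zeros((4, 10))
    U = np.ones((1, 10))
    with pytest.raises(np.linalg.LinAlgError):
        fit_readout(R, U, beta=0.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_ridge_matches_normal_equations_oracle(seed):
    """fit_readout agrees with an independent normal-equations solve."""
    rng = np.random.default_rng(seed)
    R = rng.standard_normal((5, 20))
    U = rng.standard_normal((2, 20))
    beta = 0.1
    W = fit_readout(R, U, beta)
    oracle = (U @ R.T) @ np.linalg.inv(R @ R.T + beta * np.eye(5))
    np.testing.assert_allclose(W, oracle, atol=1e-10)


def test_ridge_solution_is_loss_minimiser():
    """The returned readout beats 100 random perturbations on the ridge loss."""
    rng = np.random.default_rng(11)
    R = rng.standard_normal((5, 40))
    U = rng.standard_normal((2, 40))
    beta = 0.5

    def loss(W):
        return np.sum((U - W @ R) ** 2) + beta * np.sum(W ** 2)

    W = fit_readout(R, U, beta)
    base = loss(W)
    for _ in range(100):
        delta = rng.standard_normal(W.shape) * rng.choice([1e-3, 1e-1, 1.0])
        assert loss(W + delta) >= base


def test_gradient_descent_reaches_same_minimum():
    rng = np.random.default_rng(13)
    R = rng.standard_normal((5, 20))
    U = rng.standard_normal((2, 20))
    beta = 0.3
    W = np.zeros((2, 5))
    lr = 0.25 / (np.linalg.norm(R @ R.T, 2) + beta)
    for _ in range(20000):
        grad = 2 * ((W @ R - U) @ R.T + beta * W)
        W = W - lr * grad
    np.testing.assert_allclose(W, fit_readout(R, U, beta), atol=1e-6)


def test_readout_trivial_cases(small_config):
    esn = EchoStateNetwork(small_config, n_inputs=1)
    with pytest.raises(RuntimeError):
        esn.readout(np.zeros(small_config.n_nodes))
    esn.W_out = np.zeros((1, small_config.n_nodes))
    assert esn.readout(np.ones(small_config.n_nodes)) == np.array([0.0])
    esn.W_out = np.eye(small_config.n_nodes)
    r = np.random.default_rng(0).standard_normal(small_config.n_nodes)
    np.testing.assert_array_equal(esn.readout(r), r)


def test_save_load_roundtrip_bit_exact(tmp_path, small_config, eq9_series):
    esn = EchoStateNetwork(small_config, n_inputs=1)
    esn.train(eq9_series.window(0, 500))
    path = tmp_path / "esn.npz"
    esn.save(path)
    back = EchoStateNetwork.load(path)
    assert np.array_equal(back.W_in, esn.W_in)
    assert np.array_equal(back.W_out, esn.W_out)
    assert np.array_equal(back.A.toarray(), esn.A.toarray())
    assert np.array_equal(back.r, esn.r)
    assert np.array_equal(back.input_scale, esn.input_scale)
    assert back.config == esn.config


def test_seed_determinism_of_construction(small_config):
    a = EchoStateNetwork(small_config, n_inputs=3)
    b = EchoStateNetwork(small_config, n_inputs=3)
    assert np.array_equal(a.W_in, b.W_in)
    assert np.array_equal(a.A.toarray(), b.A.toarray())
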