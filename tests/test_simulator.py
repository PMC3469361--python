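import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sabm.effects import CenteringConstants, EffectSpec, ModelSpec, compute_centering
from sabm.simulator import (
    SimOptions,
    SimState,
    behavior_choice_probabilities,
    network_choice_probabilities,
    replicate_seed,
    simulate_period,
    write_trace,
)

from oracles import softmax


def _cov(n):
    return pd.DataFrame(index=pd.Index([f"a{i}" for i in range(n)], name="actor_id"))


CEN = CenteringConstants(behavior_mean=3.0)


def _net_model(beta_density):
    return ModelSpec([EffectSpec("density", "network", parameter=beta_density)], [])


def _beh_model(**params):
    effs = [
        EffectSpec("linear_shape", "behavior", parameter=params.get("linear", 0.0)),
        EffectSpec("quadratic_shape", "behavior", parameter=params.get("quad", 0.0)),
    ]
    return ModelSpec([EffectSpec("density", "network")], effs,
                     network_rate=params.get("lam_n", 1.0),
                     behavior_rate=params.get("lam_b", 1.0))


# ---------------------------------------------------------------------------
# Choice probabilities: hand-computed vectors


def test_network_probabilities_uniform_when_all_betas_zero():
    state = SimState(np.zeros((3, 3), dtype=int), np.full(3, 3))
    p = network_choice_probabilities(0, state, _net_model(0.0), CEN, _cov(3))
    assert np.allclose(p, 1 / 3)


def test_network_probabilities_density_ln2_no_ties():
    # creating a tie gains ln 2 of utility: softmax over (0, ln2, ln2)
    state = SimState(np.zeros((3, 3), dtype=int), np.full(3, 3))
    p = network_choice_probabilities(0, state, _net_model(np.log(2)), CEN, _cov(3))
    assert np.allclose(p, [0.2, 0.4, 0.4])
    assert np.allclose(p, softmax([0.0, np.log(2), np.log(2)]))


def test_network_probabilities_density_ln2_full_out_ties():
    x = np.array([[0, 1, 1], [0, 0, 0], [0, 0, 0]])
    state = SimState(x, np.full(3, 3))
    p = network_choice_probabilities(0, state, _net_model(np.log(2)), CEN, _cov(3))
    assert np.allclose(p, [0.5, 0.25, 0.25])


def test_network_probabilities_shift_invariance_and_normalization():
    rng = np.random.default_rng(0)
    n = 6
    x = (rng.random((n, n)) < 0.3).astype(np.int8)
    np.fill_diagonal(x, 0)
    z = rng.integers(1, 7, n)
    m1 = ModelSpec(
        [EffectSpec("density", "network", parameter=-1.2),
         EffectSpec("reciprocity", "network", parameter=0.8)], []
    )
    state = SimState(x, z)
    for i in range(n):
        p = network_choice_probabilities(i, state, m1, CEN, _cov(n))
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert (p > 0).all()


def test_out_degree_cap_removes_creation_options():
    x = np.zeros((4, 4), dtype=np.int8)
    x[0, 1] = x[0, 2] = 1
    state = SimState(x, np.full(4, 3))
    p = network_choice_probabilities(0, state, _net_model(0.0), CEN, _cov(4),
                                     out_degree_cap=2)
    assert p[3] == 0.0  # creating a third tie is excluded
    assert p.sum() == pytest.approx(1.0)


def test_behavior_probabilities_interior_and_boundary():
    x = np.zeros((3, 3), dtype=int)
    m = _beh_model()
    opts, p = behavior_choice_probabilities(0, SimState(x, np.array([3, 3, 3])), m, CEN, _cov(3))
    assert opts.tolist() == [2, 3, 4] and np.allclose(p, 1 / 3)
    opts, p = behavior_choice_probabilities(0, SimState(x, np.array([6, 3, 3])), m, CEN, _cov(3))
    assert opts.tolist() == [5, 6] and np.allclose(p, 0.5)
    opts, p = behavior_choice_probabilities(0, SimState(x, np.array([1, 3, 3])), m, CEN, _cov(3))
    assert opts.tolist() == [1, 2] and np.allclose(p, 0.5)


def test_positive_linear_shape_favors_up_moves():
    x = np.zeros((3, 3), dtype=int)
    m = _beh_model(linear=1.5)
    opts, p = behavior_choice_probabilities(0, SimState(x, np.array([3, 3, 3])), m, CEN, _cov(3))
    p_down, p_stay, p_up = p
    assert p_up > p_stay > p_down


# ---------------------------------------------------------------------------
# Period simulation


def test_zero_rates_leave_state_unchanged(random_panel_factory):
    p = random_panel_factory(n=8, seed=1)
    cen = compute_centering(p)
    m = ModelSpec([EffectSpec("density", "network", parameter=-1.0)], [],
                  network_rate=0.0)
    state, _ = simulate_period(p.wave1, p.behavior1, p.covariates, m, cen,
                               rng=np.random.default_rng(0))
    assert np.array_equal(state.ties, p.wave1)
    assert np.array_equal(state.behavior, p.behavior1)


def test_identical_seeds_give_identical_states(random_panel_factory):
    p = random_panel_factory(n=10, seed=2)
    cen = compute_centering(p)
    m = _beh_model(linear=-0.3, lam_n=2.0, lam_b=1.0)
    a, _ = simulate_period(p.wave1, p.behavior1, p.covariates, m, cen,
                           rng=np.random.default_rng(99))
    b, _ = simulate_period(p.wave1, p.behavior1, p.covariates, m, cen,
                           rng=np.random.default_rng(99))
    assert np.array_equal(a.ties, b.ties)
    assert np.array_equal(a.behavior, b.behavior)


def test_trace_path_matches_compiled_path(random_panel_factory, tmp_path):
    """The pure-Python trace-recording loop and the compiled kernel follow
    the same micro-step path from the same seed."""
    p = random_panel_factory(n=12, seed=4)
    cen = compute_centering(p)
    m = ModelSpec(
        [EffectSpec("density", "network", parameter=-1.5),
         EffectSpec("reciprocity", "network", parameter=1.0),
         EffectSpec("transitive_triplets", "network", parameter=0.3)],
        [EffectSpec("linear_shape", "behavior", parameter=-0.2),
         EffectSpec("quadratic_shape", "behavior", parameter=0.05)],
        network_rate=2.0, behavior_rate=1.0,
    )
    for seed in (0, 1, 2):
        fast, _ = simulate_period(p.wave1, p.behavior1, p.covariates, m, cen,
                                  rng=np.random.default_rng(seed))
        slow, trace = simulate_period(
            p.wave1, p.behavior1, p.covariates, m, cen,
            options=SimOptions(record_trace=True), rng=np.random.default_rng(seed),
        )
        assert np.array_equal(fast.ties, slow.ties)
        assert np.array_equal(fast.behavior, slow.behavior)
    assert trace, "expected micro-steps to be recorded"
    out = tmp_path / "trace.tsv"
    write_trace(trace, out)
    df = pd.read_csv(out, sep="\t")
    assert list(df.columns) == ["event_index", "clock", "side", "actor", "option"]
    assert df["clock"].is_monotonic_increasing


def test_chain_respects_state_invariants(random_panel_factory):
    p = random_panel_factory(n=10, seed=6)
    cen = compute_centering(p)
    m = _beh_model(linear=0.5, quad=0.2, lam_n=4.0, lam_b=4.0)
    for seed in range(5):
        state, _ = simulate_period(p.wave1, p.behavior1, p.covariates, m, cen,
                                   rng=np.random.default_rng(seed))
        assert np.all(np.diag(state.ties) == 0)
        assert state.behavior.min() >= 1 and state.behavior.max() <= 6


def test_zero_behavior_rate_freezes_behavior(random_panel_factory):
    p = random_panel_factory(n=10, seed=8)
    cen = compute_centering(p)
    m = _beh_model(linear=1.0, lam_n=3.0, lam_b=0.0)
    state, _ = simulate_period(p.wave1, p.behavior1, p.covariates, m, cen,
                               rng=np.random.default_rng(3))
    assert np.array_equal(state.behavior, p.behavior1)
    assert not np.array_equal(state.ties, p.wave1)


def test_zero_utility_chain_reaches_uniform_density():
    """With all betas 0 every toggle is as likely as its reverse, so the
    stationary tie distribution is uniform: expected density 1/2."""
    n = 5
    x0 = np.zeros((n, n), dtype=np.int8)
    z0 = np.full(n, 3)
    m = ModelSpec([EffectSpec("density", "network", parameter=0.0)], [],
                  network_rate=40.0)
    cen = CenteringConstants(behavior_mean=3.0)
    dens = []
    for r in range(400):
        state, _ = simulate_period(x0, z0, _cov(n), m, cen, rng=replicate_seed(123, r))
        dens.append(state.ties.sum() / (n * (n - 1)))
    mc_se = np.std(dens) / np.sqrt(len(dens))
    assert abs(np.mean(dens) - 0.5) < 4 * mc_se + 0.01


def test_micro_step_counts_are_poisson():
    """Event counts over replicate periods follow Poisson(n*(lam_n+lam_b))."""
    n, lam = 6, 3.0
    x0 = np.zeros((n, n), dtype=np.int8)
    m = ModelSpec([EffectSpec("density", "network")], [], network_rate=lam)
    cen = CenteringConstants(behavior_mean=3.0)
    counts = []
    for r in range(300):
        _, trace = simulate_period(
            x0, np.full(n, 3), _cov(n), m, cen,
            options=SimOptions(record_trace=True), rng=replicate_seed(7, r),
        )
        counts.append(len(trace))
    counts = np.asarray(counts)
    mean = n * lam
    # chi-square goodness of fit on binned counts
    edges = stats.poisson.ppf([0.0, 0.2, 0.4, 0.6, 0.8, 1.0], mean)
    edges[0], edges[-1] = -0.5, np.inf
    observed, _ = np.histogram(counts, bins=edges)
    probs = np.diff(stats.poisson.cdf(edges, mean))
    chi2 = (((observed - len(counts) * probs) ** 2) / (len(counts) * probs)).sum()
    assert chi2 < stats.chi2.ppf(0.999, df=len(observed) - 1)
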