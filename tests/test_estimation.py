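import numpy as np
import pandas as pd
import pytest

from sabm.effects import EffectSpec, ModelSpec, compute_centering
from sabm.estimation import (
    DegenerateDataError,
    FitOptions,
    IllConditionedError,
    _score_derivative,
    _simulate_scored,
    estimate_derivative,
    fit_school,
    initial_theta,
    observed_targets,
    simulate_targets,
    two_sided_p,
)
from sabm.synthetic import SyntheticConfig, generate_school_panel

from conftest import make_panel


def _network_model(**params):
    return ModelSpec(
        [EffectSpec("density", "network", parameter=params.get("density", 0.0)),
         EffectSpec("reciprocity", "network", parameter=params.get("reciprocity", 0.0))],
        [],
        network_rate=params.get("lam", 1.0),
    )


def _full_model():
    return ModelSpec(
        [EffectSpec("density", "network"),
         EffectSpec("reciprocity", "network"),
         EffectSpec("similarity", "network", "alcohol")],
        [EffectSpec("linear_shape", "behavior"),
         EffectSpec("quadratic_shape", "behavior"),
         EffectSpec("average_alter", "behavior")],
    )


# ---------------------------------------------------------------------------
# Observed targets


def test_observed_targets_counts_and_density(tiny_panel):
    model = _network_model()
    t = observed_targets(tiny_panel, model)
    # one tie formed (0->2), one dissolved (1->2): rate target 2
    assert t[0] == 2.0
    # density target: total wave-2 out-degree
    assert t[1] == tiny_panel.wave2.sum()


def test_observed_targets_identical_waves_degenerate():
    w = np.zeros((4, 4), dtype=int)
    w[0, 1] = w[1, 0] = w[2, 3] = 1
    p = make_panel(w, w.copy(), [1, 2, 3, 1], [1, 2, 3, 1])
    with pytest.raises(DegenerateDataError):
        observed_targets(p, _network_model())


def test_observed_targets_constant_behavior_degenerate(tiny_panel):
    p = tiny_panel.copy()
    p.behavior2 = p.behavior1.copy()
    with pytest.raises(DegenerateDataError):
        observed_targets(p, _full_model())


def test_single_formed_tie_gives_rate_target_one():
    w1 = np.zeros((4, 4), dtype=int)
    w1[0, 1] = 1
    w2 = w1.copy()
    w2[2, 3] = 1
    p = make_panel(w1, w2, [1, 2, 3, 1], [1, 2, 3, 1])
    assert observed_targets(p, _network_model())[0] == 1.0


def test_imputed_rows_never_enter_targets(random_panel_factory):
    """Replacing a non-responder's carried-forward row with arbitrary values
    leaves every observed target unchanged."""
    from sabm.panel import impute_locf

    p = impute_locf(random_panel_factory(n=12, seed=13, p_nonresponse=0.3))
    model = _full_model()
    base = observed_targets(p, model)
    vandal = p.copy()
    nonresp = ~vandal.responded_wave2
    assert nonresp.any()
    rng = np.random.default_rng(0)
    vandal.wave2[nonresp] = (rng.random((nonresp.sum(), p.n_actors)) < 0.5).astype(np.int8)
    np.fill_diagonal(vandal.wave2, 0)
    assert np.allclose(observed_targets(vandal, model), base)


def test_target_order_matches_parameter_names(tiny_panel):
    model = _full_model()
    t = observed_targets(tiny_panel, model)
    assert t.size == len(model.parameter_names)


# ---------------------------------------------------------------------------
# Derivative estimation


@pytest.fixture(scope="module")
def small_school():
    cfg = SyntheticConfig(
        n_schools=1, school_sizes=(40,),
        theta_true=ModelSpec(
            [EffectSpec("density", "network", parameter=-2.0),
             EffectSpec("reciprocity", "network", parameter=1.2)],
            [],
            network_rate=3.0,
        ),
        size_adjust_density=False,
        attrition_intercept=-40.0, attrition_heavy_uplift=0.0, seed=5,
    )
    return generate_school_panel(cfg, 0, 77)


def test_derivative_density_diagonal_positive(small_school):
    model = _network_model(density=-1.5, lam=2.0)
    d = estimate_derivative(small_school, model, model.theta, n1=8, seed=1,
                            check_conditioning=False)
    names = model.parameter_names
    k = names.index("net:density")
    assert d[k, k] > 0  # raising the density parameter raises expected tie counts
    assert d[0, 0] > 0  # raising the rate raises expected change counts


def test_common_random_numbers_beat_independent_seeds(small_school):
    """Paired +eps/-eps simulation with shared seeds has far smaller
    difference variance than independent draws."""
    from sabm.estimation import _simulate_once
    from sabm.simulator import replicate_seed

    model = _network_model(density=-1.5, lam=2.0)
    cen = compute_centering(small_school)
    eps = 0.3
    tp = model.theta.copy(); tp[1] += eps
    tm = model.theta.copy(); tm[1] -= eps
    mp, mm = model.with_theta(tp), model.with_theta(tm)
    crn, indep = [], []
    for r in range(25):
        a = _simulate_once(small_school, mp, cen, replicate_seed(3, r))
        b = _simulate_once(small_school, mm, cen, replicate_seed(3, r))
        crn.append(a - b)
        c = _simulate_once(small_school, mp, cen, replicate_seed(4, 1000 + r))
        d = _simulate_once(small_school, mm, cen, replicate_seed(5, 2000 + r))
        indep.append(c - d)
    v_crn = np.var(np.asarray(crn), axis=0)
    v_ind = np.var(np.asarray(indep), axis=0)
    assert (v_crn < v_ind).all()


def test_ill_conditioned_effect_set_rejected(small_school):
    # a constant covariate makes the ego column identically zero
    p = small_school.copy()
    p.covariates["flat"] = 1.0
    model = ModelSpec(
        [EffectSpec("density", "network", parameter=-1.5),
         EffectSpec("ego", "network", "flat")],
        [],
        network_rate=2.0,
    )
    with pytest.raises(IllConditionedError):
        estimate_derivative(p, model, model.theta, n1=8, seed=1)


def test_score_derivative_agrees_with_finite_differences(small_school):
    """The likelihood-ratio (score) estimate and central finite differences
    estimate the same sensitivity matrix."""
    model = _network_model(density=-1.5, reciprocity=0.8, lam=2.5)
    cen = compute_centering(small_school)
    d_fd = estimate_derivative(small_school, model, model.theta, n1=40, seed=11,
                               centering=cen, eps=0.3, check_conditioning=False)
    targets, scores = _simulate_scored(small_school, model, cen, 3000, 11)
    d_sc = _score_derivative(targets, scores)
    diag_fd, diag_sc = np.diag(d_fd), np.diag(d_sc)
    assert np.all(np.sign(diag_fd) == np.sign(diag_sc))
    rel = np.abs(diag_sc - diag_fd) / np.abs(diag_fd)
    assert rel.max() < 0.5


# ---------------------------------------------------------------------------
# Fitting


def test_fit_recovers_network_parameters(small_school):
    """A network-only fit on data with known generating values lands within
    3 SEs and satisfies the moment equation."""
    model = _network_model()
    fit = fit_school(small_school, model, FitOptions.scaled(), seed=3)
    assert fit.converged
    true = {"rate_network": 3.0, "net:density": -2.0, "net:reciprocity": 1.2}
    for name, th, se in zip(fit.parameter_names, fit.theta_hat, fit.se):
        assert abs(th - true[name]) < 3 * se, (name, th, se)
    n_rates = 1
    assert np.nanmax(np.abs(fit.t_conv[n_rates:])) < 0.10


def test_fit_report_frame(small_school):
    model = _network_model()
    fit = fit_school(small_school, model, FitOptions.scaled(), seed=3)
    frame = fit.to_frame()
    assert list(frame.columns) == ["school_id", "effect", "beta", "se", "t_conv", "converged"]
    assert len(frame) == len(model.parameter_names)


def test_initial_theta_layout(tiny_panel):
    model = _full_model()
    th = initial_theta(tiny_panel, model)
    names = model.parameter_names
    assert th[names.index("net:density")] == -1.0
    assert th[names.index("net:reciprocity")] == 0.0
    assert th[0] > 0 and th[1] > 0


def test_simulate_targets_replicate_seed_independence(small_school):
    model = _network_model(density=-1.5, lam=2.0)
    a = simulate_targets(small_school, model, 5, seed=9)
    singles = np.vstack([
        simulate_targets(small_school, model, 1, seed=9, seed_offset=r) for r in range(5)
    ])
    assert np.allclose(a, singles)


# ---------------------------------------------------------------------------
# p-values


def test_two_sided_p_examples():
    from sabm.estimation import SchoolFit

    fit = SchoolFit(
        school_id="s", parameter_names=["rate_network", "net:density", "net:reciprocity"],
        theta_hat=np.array([2.0, 0.0, 1.96]), se=np.array([0.5, 1.0, 1.0]),
        t_conv=np.zeros(3), converged=True,
        n_phase2_iterations=0, n_phase3_replicates=0, seed=0,
    )
    table = two_sided_p(fit)
    row_zero = table[table.effect == "net:density"].iloc[0]
    assert row_zero.p_two_sided == pytest.approx(1.0)
    row_196 = table[table.effect == "net:reciprocity"].iloc[0]
    assert row_196.p_two_sided == pytest.approx(0.05, abs=0.001)
    assert np.allclose(table.p_right + table.p_left, 1.0)
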