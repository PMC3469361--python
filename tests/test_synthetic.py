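import numpy as np
import pytest

from sabm.effects import EffectSpec, ModelSpec, compute_centering
from sabm.panel import jaccard_counts, jaccard_index, read_panel, write_panel
from sabm.synthetic import (
    SyntheticConfig,
    default_theta_true,
    generate_covariates,
    generate_initial_behavior,
    generate_school_panel,
    generate_study,
    generate_wave1_network,
    school_theta,
)


@pytest.fixture(scope="module")
def default_study():
    return generate_study(SyntheticConfig(seed=20120806))


# ---------------------------------------------------------------------------
# Covariates


def test_covariate_marginals_match_configuration():
    cfg = SyntheticConfig()
    cov = generate_covariates(10_000, cfg, np.random.default_rng(1))
    assert abs(cov["male"].mean() - 0.508) < 0.02
    assert abs(cov["minority"].mean() - 0.391) < 0.02
    assert abs(cov["age"].mean() - 15.8) < 0.15
    assert cov["age"].between(12, 18).all()
    assert abs((cov["family_bonding"] >= 4).mean() - 0.60) < 0.02
    assert abs((cov["parent_drinking"] == 1).mean() - 0.562) < 0.02


def test_covariates_deterministic_under_seed():
    cfg = SyntheticConfig()
    a = generate_covariates(50, cfg, np.random.default_rng(9))
    b = generate_covariates(50, cfg, np.random.default_rng(9))
    assert a.equals(b)


def test_degenerate_all_male_config():
    cfg = SyntheticConfig(male_p=1.0)
    cov = generate_covariates(200, cfg, np.random.default_rng(2))
    assert (cov["male"] == 1).all()


def test_invalid_probability_vector_rejected():
    with pytest.raises(ValueError):
        SyntheticConfig(behavior_init_probs=(0.5, 0.5, 0.5, 0, 0, 0))


def test_behavior_init_distribution():
    cfg = SyntheticConfig()
    z = generate_initial_behavior(20_000, cfg, np.random.default_rng(3))
    assert abs((z == 1).mean() - 0.496) < 0.02  # about half abstain


# ---------------------------------------------------------------------------
# Wave-1 network


def test_wave1_mean_out_degree_near_configured():
    cfg = SyntheticConfig(n_schools=1, school_sizes=(500,))
    rng = np.random.default_rng(4)
    cov = generate_covariates(500, cfg, rng)
    z = generate_initial_behavior(500, cfg, rng)
    x = generate_wave1_network(cov, cfg, rng, behavior=z)
    assert abs(x.sum(axis=1).mean() - 2.04) < 0.15


def test_wave1_out_degree_capped():
    cfg = SyntheticConfig(n_schools=1, school_sizes=(200,), wave1_degree_mean=9.0)
    rng = np.random.default_rng(5)
    cov = generate_covariates(200, cfg, rng)
    x = generate_wave1_network(cov, cfg, rng)
    assert x.sum(axis=1).max() <= 10


def test_wave1_no_self_ties_and_reciprocity_boost():
    cfg = SyntheticConfig(n_schools=1, school_sizes=(400,))
    rng = np.random.default_rng(6)
    cov = generate_covariates(400, cfg, rng)
    z = generate_initial_behavior(400, cfg, rng)
    x = generate_wave1_network(cov, cfg, rng, behavior=z)
    assert np.all(np.diag(x) == 0)
    recip = (x * x.T).sum() / x.sum()
    assert 0.12 < recip < 0.35  # mutual-tie share near the survey's ~23%


def test_wave1_zero_homophily_is_uniform():
    """With all homophily weights zero, same-gender tie share matches the
    chance expectation."""
    cfg = SyntheticConfig(
        n_schools=1, school_sizes=(600,),
        homophily_age=0.0, homophily_gender=0.0,
        homophily_race=0.0, homophily_alcohol=0.0,
        reciprocity_boost=0.0,
    )
    rng = np.random.default_rng(7)
    cov = generate_covariates(600, cfg, rng)
    x = generate_wave1_network(cov, cfg, rng)
    male = cov["male"].to_numpy()
    src, dst = np.nonzero(x)
    same = (male[src] == male[dst]).mean()
    pm = male.mean()
    expected = pm**2 + (1 - pm) ** 2
    assert abs(same - expected) < 0.04


def test_wave1_homophily_raises_same_gender_share():
    cfg = SyntheticConfig(n_schools=1, school_sizes=(600,), homophily_gender=2.0)
    rng = np.random.default_rng(8)
    cov = generate_covariates(600, cfg, rng)
    x = generate_wave1_network(cov, cfg, rng)
    male = cov["male"].to_numpy()
    src, dst = np.nonzero(x)
    assert (male[src] == male[dst]).mean() > 0.70


# ---------------------------------------------------------------------------
# School panels


def test_zero_attrition_yields_full_response():
    cfg = SyntheticConfig(
        n_schools=1, school_sizes=(60,),
        attrition_intercept=-40.0, attrition_heavy_uplift=0.0, seed=1,
    )
    p = generate_school_panel(cfg, 0, 11)
    assert p.responded_wave2.all()
    assert not p.imputed_tie_mask.any()


def test_selection_strength_raises_wave2_tie_similarity():
    """At the same seed, generating with a strong alcohol-similarity
    preference produces more drinking-alike friendships at wave 2 than the
    zero-similarity counterfactual."""
    base = default_theta_true()
    strong = ModelSpec(
        [e if e.label != "alcohol_similarity" else
         EffectSpec("similarity", "network", "alcohol", parameter=1.5)
         for e in base.network_effects],
        [EffectSpec(e.name, "behavior", e.covariate, e.parameter)
         for e in base.behavior_effects],
        network_rate=base.network_rate, behavior_rate=base.behavior_rate,
    )
    null = ModelSpec(
        [e if e.label != "alcohol_similarity" else
         EffectSpec("similarity", "network", "alcohol", parameter=0.0)
         for e in base.network_effects],
        [EffectSpec(e.name, "behavior", e.covariate, e.parameter)
         for e in base.behavior_effects],
        network_rate=base.network_rate, behavior_rate=base.behavior_rate,
    )

    def mean_tie_similarity(theta):
        cfg = SyntheticConfig(
            n_schools=1, school_sizes=(150,), theta_true=theta,
            attrition_intercept=-40.0, attrition_heavy_uplift=0.0, seed=21,
        )
        sims = []
        for rep in range(6):
            p = generate_school_panel(cfg, 0, 500 + rep)
            src, dst = np.nonzero(p.wave2)
            sims.append((1 - np.abs(p.behavior2[src] - p.behavior2[dst]) / 5.0).mean())
        return np.mean(sims)

    assert mean_tie_similarity(strong) > mean_tie_similarity(null)


def test_influence_strength_raises_friend_behavior_correlation():
    """A strong average-alter influence effect makes friends' wave-2
    drinking more correlated than the zero-influence counterfactual."""
    base = default_theta_true()

    def with_influence(val):
        return ModelSpec(
            [EffectSpec(e.name, "network", e.covariate, e.parameter)
             for e in base.network_effects],
            [e if e.name != "average_alter" else
             EffectSpec("average_alter", "behavior", parameter=val)
             for e in base.behavior_effects],
            network_rate=base.network_rate, behavior_rate=2.5,
        )

    def friend_corr(theta):
        cfg = SyntheticConfig(
            n_schools=1, school_sizes=(150,), theta_true=theta,
            attrition_intercept=-40.0, attrition_heavy_uplift=0.0, seed=22,
        )
        cors = []
        for rep in range(6):
            p = generate_school_panel(cfg, 0, 900 + rep)
            src, dst = np.nonzero(p.wave2)
            if src.size > 10:
                cors.append(np.corrcoef(p.behavior2[src], p.behavior2[dst])[0, 1])
        return np.mean(cors)

    assert friend_corr(with_influence(1.2)) > friend_corr(with_influence(0.0))


def test_school_theta_size_adjustment():
    cfg = SyntheticConfig()
    small = school_theta(cfg, 48)
    big = school_theta(cfg, 987)
    d_small = [e for e in small.network_effects if e.name == "density"][0].parameter
    d_big = [e for e in big.network_effects if e.name == "density"][0].parameter
    assert d_small > d_big  # smaller school, fewer candidates, milder penalty
    assert d_small - d_big == pytest.approx(np.log(987 / 48))


# ---------------------------------------------------------------------------
# Whole-study generation


def test_default_study_shape_and_sizes(default_study):
    assert len(default_study.panels) == 13
    sizes = [p.n_actors for p in default_study.panels]
    assert min(sizes) >= 48 and max(sizes) <= 987
    assert sum(sizes) == 2563


def test_default_study_retention_near_observed(default_study):
    from sabm.panel import attrition_summary

    att = attrition_summary(default_study.panels)
    assert abs(att.retention_pct - 89.6) < 1.5


def test_default_study_attrition_targets_heavier_drinkers(default_study):
    z1 = np.concatenate([p.behavior1 for p in default_study.panels])
    resp = np.concatenate([p.responded_wave2 for p in default_study.panels])
    heavy_lost = (z1[~resp] >= 5).mean()
    heavy_kept = (z1[resp] >= 5).mean()
    assert heavy_lost > heavy_kept  # lost to follow-up skews toward weekly+ drinkers


def test_default_study_jaccard_bracket(default_study):
    js = [jaccard_index(jaccard_counts(p)) for p in default_study.panels]
    assert min(js) >= 0.15 and max(js) <= 0.45


def test_generated_panels_round_trip_through_reader(default_study, tmp_path):
    p = default_study.panels[0]
    paths = write_panel(p, tmp_path)
    back = read_panel((paths["wave1"], paths["wave2"]), paths["covariates"],
                      school_id=p.school_id)
    assert back.n_actors == p.n_actors
    assert np.array_equal(back.wave1, p.wave1)


def test_manifest_reproducibility_and_hash():
    cfg = SyntheticConfig(n_schools=2, school_sizes=(30, 40), seed=77)
    a = generate_study(cfg)
    b = generate_study(SyntheticConfig(n_schools=2, school_sizes=(30, 40), seed=77))
    assert a.manifest == b.manifest
    for pa, pb in zip(a.panels, b.panels):
        assert np.array_equal(pa.wave2, pb.wave2)
        assert np.array_equal(pa.behavior2, pb.behavior2)
    changed = SyntheticConfig(n_schools=2, school_sizes=(30, 40), seed=78)
    assert changed.config_hash() != cfg.config_hash()
    same = SyntheticConfig(n_schools=2, school_sizes=(30, 40), seed=77)
    assert same.config_hash() == cfg.config_hash()


def test_small_school_size_rejected():
    with pytest.raises(ValueError):
        SyntheticConfig(n_schools=1, school_sizes=(10,))
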