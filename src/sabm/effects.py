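"""Effect statistics for the actor-based co-evolution model.

Each actor *i* evaluates candidate states through a linear objective
function f_i = sum_k beta_k * s_ik(x, z, v), where x is the directed tie
relation, z the ordinal behavior, and v actor covariates.  This module is
the catalog of the statistics s_ik on both sides of the model:

* network side — structural effects (density, reciprocity, transitive
  triplets, 3-cycles, degree popularity/activity) and covariate-driven
  selection effects (ego, alter, similarity, same), with the behavior
  variable itself usable as a covariate ("alcohol use ego/alter/similarity");
* behavior side — linear and quadratic shape, the average-alter peer
  influence statistic, and covariate effects on behavior change.

Similarity between actors on a covariate v is sim_ij = 1 - |v_i - v_j| /
range(v): 1 for identical values, 0 for maximally different ones.
Covariates and behavior are centered at fixed per-school constants
(:class:`CenteringConstants`) so that parameters keep their conventional
interpretation across simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import BEHAVIOR_MAX, BEHAVIOR_MIN, SchoolPanel

NETWORK_STRUCTURAL_EFFECTS = (
    "density",
    "reciprocity",
    "transitive_triplets",
    "three_cycles",
    "in_degree_popularity",
    "out_degree_popularity",
    "out_degree_activity",
)
NETWORK_COVARIATE_EFFECTS = ("ego", "alter", "similarity", "same")
BEHAVIOR_EFFECTS = ("linear_shape", "quadratic_shape", "average_alter",
                    "average_similarity", "covariate_effect")

#: Name under which the behavior variable enters network selection effects.
BEHAVIOR_COVARIATE = "alcohol"


class EffectError(ValueError):
    """Unknown effect name or invalid effect/covariate combination."""


@dataclass
class EffectSpec:
    """One named effect statistic with its parameter beta_k.

    ``covariate`` is required for ego/alter/similarity/same and for
    covariate effects on behavior (use :data:`BEHAVIOR_COVARIATE` for the
    behavior variable itself on the network side), and must be absent for
    purely structural effects and the shape/average-alter effects.
    """

    name: str
    side: str  # "network" | "behavior"
    covariate: str | None = None
    parameter: float = 0.0

    def __post_init__(self) -> None:
        if self.side == "network":
            if self.name in NETWORK_STRUCTURAL_EFFECTS:
                if self.covariate is not None:
                    raise EffectError(f"{self.name}: structural effect takes no covariate")
            elif self.name in NETWORK_COVARIATE_EFFECTS:
                if self.covariate is None:
                    raise EffectError(f"{self.name}: covariate reference required")
            else:
                raise EffectError(f"unknown network effect {self.name!r}")
        elif self.side == "behavior":
            if self.name not in BEHAVIOR_EFFECTS:
                raise EffectError(f"unknown behavior effect {self.name!r}")
            needs_cov = self.name == "covariate_effect"
            if needs_cov and self.covariate is None:
                raise EffectError("covariate_effect: covariate reference required")
            if not needs_cov and self.covariate is not None:
                raise EffectError(f"{self.name}: takes no covariate")
        else:
            raise EffectError(f"unknown side {self.side!r}")

    @property
    def label(self) -> str:
        if self.covariate is None:
            return self.name
        return f"{self.covariate}_{self.name}"


@dataclass
class ModelSpec:
    """The full parameterized model: both effect lists plus change rates.

    Rates are the expected number of change opportunities per actor over the
    (unit-length) period between waves.  The density effect and the linear +
    quadratic shape pair anchor their respective sides and are required
    whenever that side is modeled.
    """

    network_effects: list[EffectSpec]
    behavior_effects: list[EffectSpec]
    network_rate: float = 1.0
    behavior_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.network_rate < 0 or self.behavior_rate < 0:
            raise EffectError("rates must be non-negative")
        for effs, side in ((self.network_effects, "network"), (self.behavior_effects, "behavior")):
            labels = [e.label for e in effs]
            if len(set(labels)) != len(labels):
                raise EffectError(f"duplicate {side} effect labels: {labels}")
            for e in effs:
                if e.side != side:
                    raise EffectError(f"effect {e.label} declared on wrong side")
        if self.network_effects and "density" not in [e.name for e in self.network_effects]:
            raise EffectError("network side requires the density effect")
        if self.behavior_effects:
            names = [e.name for e in self.behavior_effects]
            if "linear_shape" not in names or "quadratic_shape" not in names:
                raise EffectError("behavior side requires linear and quadratic shape effects")

    # -- parameter-vector view (rates first, then network, then behavior betas)

    @property
    def parameter_names(self) -> list[str]:
        names = ["rate_network"]
        if self.behavior_effects:
            names.append("rate_behavior")
        names += [f"net:{e.label}" for e in self.network_effects]
        names += [f"beh:{e.label}" for e in self.behavior_effects]
        return names

    @property
    def n_rates(self) -> int:
        return 1 + (1 if self.behavior_effects else 0)

    @property
    def theta(self) -> np.ndarray:
        vals = [self.network_rate]
        if self.behavior_effects:
            vals.append(self.behavior_rate)
        vals += [e.parameter for e in self.network_effects]
        vals += [e.parameter for e in self.behavior_effects]
        return np.array(vals, dtype=float)

    def with_theta(self, theta: np.ndarray) -> "ModelSpec":
        theta = np.asarray(theta, dtype=float)
        if theta.size != len(self.parameter_names):
            raise EffectError("theta length mismatch")
        k = self.n_rates
        net = [replace(e, parameter=float(v))
               for e, v in zip(self.network_effects, theta[k:k + len(self.network_effects)])]
        beh = [replace(e, parameter=float(v))
               for e, v in zip(self.behavior_effects, theta[k + len(self.network_effects):])]
        return ModelSpec(
            network_effects=net,
            behavior_effects=beh,
            network_rate=float(theta[0]),
            behavior_rate=float(theta[1]) if k == 2 else self.behavior_rate,
        )


@dataclass
class CenteringConstants:
    """Fixed per-school centering constants, computed once and reused.

    ``cov_means``/``cov_ranges``/``cov_mean_sim`` are keyed by covariate
    name; behavior uses the grand mean over both observed waves, the fixed
    scale range (6 - 1 = 5) and the mean wave-1 pairwise similarity.
    """

    cov_means: dict = field(default_factory=dict)
    cov_ranges: dict = field(default_factory=dict)
    cov_mean_sim: dict = field(default_factory=dict)
    behavior_mean: float = 0.0
    behavior_range: float = float(BEHAVIOR_MAX - BEHAVIOR_MIN)
    behavior_mean_sim: float = 0.0

    def mean(self, covariate: str) -> float:
        if covariate == BEHAVIOR_COVARIATE:
            return self.behavior_mean
        return self.cov_means[covariate]

    def range(self, covariate: str) -> float:
        if covariate == BEHAVIOR_COVARIATE:
            return self.behavior_range
        return self.cov_ranges[covariate]

    def mean_sim(self, covariate: str) -> float:
        if covariate == BEHAVIOR_COVARIATE:
            return self.behavior_mean_sim
        return self.cov_mean_sim[covariate]


def _pairwise_mean_similarity(v: np.ndarray, rng: float) -> float:
    # mean of sim_ij over ordered pairs i != j
    n = v.size
    sim = 1.0 - np.abs(v[:, None] - v[None, :]) / rng
    return float(sim[~np.eye(n, dtype=bool)].mean())


def compute_centering(panel: SchoolPanel) -> CenteringConstants:
    """Centering constants for one school.

    Numeric covariates are centered at their school mean; similarity scores
    at the mean wave-1 pairwise similarity; behavior at the grand mean over
    both waves, excluding carried-forward wave-2 entries.  A covariate with
    zero range cannot enter a similarity effect (checked at evaluation time).
    """
    cen = CenteringConstants()
    for name in panel.covariates.columns:
        col = panel.covariates[name]
        if not pd.api.types.is_numeric_dtype(col):
            continue
        v = col.to_numpy(dtype=float)
        cen.cov_means[name] = float(v.mean())
        rng = float(v.max() - v.min())
        cen.cov_ranges[name] = rng
        if rng > 0 and len(v) > 1:
            cen.cov_mean_sim[name] = _pairwise_mean_similarity(v, rng)
    z1 = panel.behavior1.astype(float)
    z2 = panel.behavior2.astype(float)[~panel.behavior2_imputed]
    cen.behavior_mean = float(np.concatenate([z1, z2]).mean())
    if panel.n_actors > 1:
        cen.behavior_mean_sim = _pairwise_mean_similarity(z1, cen.behavior_range)
    return cen


def covariate_values(
    effect: EffectSpec, behavior: np.ndarray, covariates: pd.DataFrame
) -> np.ndarray:
    """Resolve the value vector an effect's covariate reference points to."""
    if effect.covariate == BEHAVIOR_COVARIATE:
        return np.asarray(behavior, dtype=float)
    col = covariates[effect.covariate]
    if effect.name == "same":
        return col.to_numpy()  # may be categorical; only equality is used
    if not pd.api.types.is_numeric_dtype(col):
        raise EffectError(f"covariate {effect.covariate!r} must be numeric for {effect.name}")
    return col.to_numpy(dtype=float)


def similarity_matrix(v: np.ndarray, rng: float) -> np.ndarray:
    if rng <= 0:
        raise EffectError("similarity undefined for a covariate with zero range")
    return 1.0 - np.abs(v[:, None] - v[None, :]) / rng


# ---------------------------------------------------------------------------
# Per-actor statistic vectors (value of s_ik for every actor i at once).


def network_actor_statistics(
    effect: EffectSpec,
    ties: np.ndarray,
    behavior: np.ndarray,
    covariates: pd.DataFrame,
    centering: CenteringConstants,
) -> np.ndarray:
    """Vector of s_ik over all actors i for one network effect."""
    x = np.asarray(ties, dtype=float)
    outdeg = x.sum(axis=1)
    name = effect.name
    if name == "density":
        return outdeg
    if name == "reciprocity":
        return (x * x.T).sum(axis=1)
    if name == "transitive_triplets":
        return ((x @ x) * x).sum(axis=1)
    if name == "three_cycles":
        return np.einsum("ij,jh,hi->i", x, x, x)
    if name == "in_degree_popularity":
        return x @ x.sum(axis=0)
    if name == "out_degree_popularity":
        return x @ outdeg
    if name == "out_degree_activity":
        return outdeg**2
    if name in NETWORK_COVARIATE_EFFECTS:
        v = covariate_values(effect, behavior, covariates)
        if name == "same":
            return (x * (v[:, None] == v[None, :])).sum(axis=1)
        vbar = centering.mean(effect.covariate)
        if name == "ego":
            return (v - vbar) * outdeg
        if name == "alter":
            return x @ (v - vbar)
        if name == "similarity":
            sim = similarity_matrix(v, centering.range(effect.covariate))
            return (x * (sim - centering.mean_sim(effect.covariate))).sum(axis=1)
    raise EffectError(f"unknown network effect {name!r}")


def behavior_actor_statistics(
    effect: EffectSpec,
    ties: np.ndarray,
    behavior: np.ndarray,
    covariates: pd.DataFrame,
    centering: CenteringConstants,
) -> np.ndarray:
    """Vector of s_ik over all actors i for one behavior effect."""
    x = np.asarray(ties, dtype=float)
    zc = np.asarray(behavior, dtype=float) - centering.behavior_mean
    name = effect.name
    if name == "linear_shape":
        return zc
    if name == "quadratic_shape":
        return zc**2
    if name == "average_alter":
        outdeg = x.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            avg = np.where(outdeg > 0, (x @ zc) / np.maximum(outdeg, 1), 0.0)
        return zc * avg
    if name == "average_similarity":
        outdeg = x.sum(axis=1)
        z = np.asarray(behavior, dtype=float)
        sim = similarity_matrix(z, centering.behavior_range)
        tot = (x * (sim - centering.behavior_mean_sim)).sum(axis=1)
        return np.where(outdeg > 0, tot / np.maximum(outdeg, 1), 0.0)
    if name == "covariate_effect":
        v = covariate_values(effect, behavior, covariates)
        return zc * (v - centering.mean(effect.covariate))
    raise EffectError(f"unknown behavior effect {name!r}")


def network_effect_statistic(effect, actor, ties, behavior, covariates, centering) -> float:
    """s_ik for one focal actor on the network side."""
    return float(network_actor_statistics(effect, ties, behavior, covariates, centering)[actor])


def behavior_effect_statistic(effect, actor, ties, behavior, covariates, centering) -> float:
    """s_ik for one focal actor on the behavior side."""
    return float(behavior_actor_statistics(effect, ties, behavior, covariates, centering)[actor])


def objective(
    side: str,
    model: ModelSpec,
    actor: int,
    ties: np.ndarray,
    behavior: np.ndarray,
    covariates: pd.DataFrame,
    centering: CenteringConstants,
) -> float:
    """The focal actor's objective f_i = sum_k beta_k s_ik on one side."""
    effs = model.network_effects if side == "network" else model.behavior_effects
    stat = network_effect_statistic if side == "network" else behavior_effect_statistic
    return sum(
        e.parameter * stat(e, actor, ties, behavior, covariates, centering) for e in effs
    )


# ---------------------------------------------------------------------------
# Default catalogs: the full selection and influence effect lists.


def default_network_effects() -> list[EffectSpec]:
    """The 19-effect network-selection list: structure, demographics, alcohol."""
    E = EffectSpec
    return [
        E("density", "network"),
        E("reciprocity", "network"),
        E("transitive_triplets", "network"),
        E("three_cycles", "network"),
        E("in_degree_popularity", "network"),
        E("out_degree_popularity", "network"),
        E("out_degree_activity", "network"),
        E("ego", "network", "age"),
        E("alter", "network", "age"),
        E("similarity", "network", "age"),
        E("ego", "network", "male"),
        E("alter", "network", "male"),
        E("same", "network", "male"),
        E("ego", "network", "minority"),
        E("alter", "network", "minority"),
        E("same", "network", "race"),
        E("ego", "network", BEHAVIOR_COVARIATE),
        E("alter", "network", BEHAVIOR_COVARIATE),
        E("similarity", "network", BEHAVIOR_COVARIATE),
    ]


def default_behavior_effects() -> list[EffectSpec]:
    """The 8-effect behavior-evolution list: shape, peer influence, controls."""
    E = EffectSpec
    return [
        E("linear_shape", "behavior"),
        E("quadratic_shape", "behavior"),
        E("average_alter", "behavior"),
        E("covariate_effect", "behavior", "age"),
        E("covariate_effect", "behavior", "male"),
        E("covariate_effect", "behavior", "minority"),
        E("covariate_effect", "behavior", "parent_drinking"),
        E("covariate_effect", "behavior", "family_bonding"),
    ]
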