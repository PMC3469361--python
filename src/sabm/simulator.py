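"""Continuous-time micro-step simulation of network/behavior co-evolution.

Between the two observation waves the model evolves as a continuous-time
Markov chain.  Change opportunities arrive with total intensity
n * (lambda_net + lambda_beh) over the unit-length period; at each
opportunity a uniformly random actor either toggles one outgoing tie
(network micro-step) or moves its behavior one level (behavior micro-step),
with the side drawn proportionally to the rates.  The actor chooses among
its options by a multinomial logit on the objective-function values — the
closed form that results from adding independent standard-Gumbel noise to
each option's objective ("myopic stochastic optimization").

The inner loop uses change statistics: for each candidate toggle i->j the
difference in f_i is computed in closed form and vectorized over j, which
is algebraically identical to evaluating f_i at every post-toggle state
(the logit is shift-invariant).  All randomness is pre-drawn from one numpy
Generator (event count, sides, actors, one choice uniform per event), so a
run is reproducible bit-for-bit; the event loop itself runs in a compiled
kernel, with an equivalent pure-Python path used when a micro-step trace is
requested.

A simulation can also accumulate the score of its own path — the exact
gradient of the log path probability in the model parameters — whose
cross-covariance with the end-of-period statistics estimates the moment
sensitivity matrix (likelihood-ratio derivative identity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .effects import (
    BEHAVIOR_COVARIATE,
    CenteringConstants,
    EffectError,
    EffectSpec,
    ModelSpec,
    covariate_values,
)
from .panel import BEHAVIOR_MAX, BEHAVIOR_MIN

try:  # compiled event loop; the pure-Python path remains available
    from ._kernel import run_chain as _run_chain

    _HAVE_KERNEL = True
except ImportError:  # pragma: no cover
    _HAVE_KERNEL = False


@dataclass
class SimState:
    """Network + behavior at an intermediate time point of the period."""

    ties: np.ndarray
    behavior: np.ndarray
    clock: float = 0.0


@dataclass
class SimOptions:
    seed: int = 0
    record_trace: bool = False
    out_degree_cap: int | None = None


@dataclass
class TraceRecord:
    event_index: int
    clock: float
    side: str
    actor: int
    option: int  # alter index / new level; == actor means "no change"


_NET_CODES = {
    "density": 0, "reciprocity": 1, "transitive_triplets": 2, "three_cycles": 3,
    "in_degree_popularity": 4, "out_degree_popularity": 5, "out_degree_activity": 6,
    "ego": 7, "alter": 8, "similarity": 9, "same": 10,
}
_BEH_CODES = {
    "linear_shape": 0, "quadratic_shape": 1, "average_alter": 2,
    "average_similarity": 3, "covariate_effect": 4,
}


def _numeric_codes(values: np.ndarray) -> np.ndarray:
    """Categorical covariates (e.g. race) as float codes for equality tests."""
    if values.dtype.kind in "fiub":
        return np.asarray(values, dtype=np.float64)
    codes, _ = pd.factorize(values)
    return codes.astype(np.float64)


class SimContext:
    """Mutable simulation state with packed per-effect covariate payloads.

    Each network effect is (code, parameter, kind, value vector, c1, c2):
    kind 1 marks the behavior variable used as a covariate; c1 holds the
    centering mean (ego/alter) or the mean similarity (similarity), c2 the
    covariate range.  Memory stays O(K n) per school.
    """

    def __init__(
        self,
        ties: np.ndarray,
        behavior: np.ndarray,
        covariates: pd.DataFrame,
        model: ModelSpec,
        centering: CenteringConstants,
        keep_all_effects: bool = False,
    ) -> None:
        self.n = int(ties.shape[0])
        if self.n < 2:
            raise EffectError("simulation requires at least 2 actors")
        self.x = np.asarray(ties, dtype=np.float64).copy()
        np.fill_diagonal(self.x, 0)
        self.z = np.asarray(behavior, dtype=np.int64).copy()
        self.outdeg = self.x.sum(axis=1)
        self.indeg = self.x.sum(axis=0)
        self.model = model
        self.centering = centering
        self.covariates = covariates
        self.zbar = float(centering.behavior_mean)
        self.zrange = float(centering.behavior_range)
        self.znsim = float(centering.behavior_mean_sim)

        # zero-parameter effects do not move utilities; they are compiled
        # only when per-effect statistics are needed (score accumulation)
        net_effs = [e for e in model.network_effects if keep_all_effects or e.parameter != 0.0]
        beh_effs = [e for e in model.behavior_effects if keep_all_effects or e.parameter != 0.0]
        kn, kb, n = len(net_effs), len(beh_effs), self.n
        self.net_code = np.empty(kn, dtype=np.int64)
        self.net_param = np.empty(kn)
        self.net_kind = np.zeros(kn, dtype=np.int64)
        self.net_vec = np.zeros((kn, n))
        self.net_c1 = np.zeros(kn)
        self.net_c2 = np.ones(kn)
        for k, e in enumerate(net_effs):
            self.net_code[k] = _NET_CODES[e.name]
            self.net_param[k] = e.parameter
            if e.covariate == BEHAVIOR_COVARIATE:
                self.net_kind[k] = 1
            elif e.covariate is not None:
                v = _numeric_codes(np.asarray(covariate_values(e, self.z, covariates)))
                self.net_vec[k] = v
                if e.name in ("ego", "alter"):
                    self.net_c1[k] = centering.mean(e.covariate)
                elif e.name == "similarity":
                    rng_v = centering.range(e.covariate)
                    if rng_v <= 0:
                        raise EffectError(
                            f"similarity undefined for zero-range covariate {e.covariate!r}"
                        )
                    self.net_c1[k] = centering.mean_sim(e.covariate)
                    self.net_c2[k] = rng_v
        self.beh_code = np.empty(kb, dtype=np.int64)
        self.beh_param = np.empty(kb)
        self.beh_vec = np.zeros((kb, n))
        for k, e in enumerate(beh_effs):
            self.beh_code[k] = _BEH_CODES[e.name]
            self.beh_param[k] = e.parameter
            if e.name == "covariate_effect":
                v = np.asarray(covariate_values(e, self.z, covariates), dtype=np.float64)
                self.beh_vec[k] = v - centering.mean(e.covariate)

    # -- network side -------------------------------------------------------

    def network_delta_matrix(self, i: int) -> np.ndarray:
        """Per-effect change statistics for toggling i->j, shape (K, n).

        Row k holds s_ik(post-toggle) - s_ik(current) for effect k, for every
        candidate alter j; column i is zero (the "no change" option).
        """
        x = self.x
        xi = x[i]
        d = 1.0 - 2.0 * xi
        mat = np.empty((self.net_code.size, self.n))
        for k in range(self.net_code.size):
            code = self.net_code[k]
            if code == 0:
                mat[k] = d
            elif code == 1:
                mat[k] = d * x[:, i]
            elif code == 2:
                mat[k] = d * (x @ xi + xi @ x)
            elif code == 3:
                mat[k] = d * (x @ x[:, i])
            elif code == 4:
                mat[k] = d * self.indeg + (d + 1.0) * 0.5
            elif code == 5:
                mat[k] = d * self.outdeg
            elif code == 6:
                mat[k] = 2.0 * self.outdeg[i] * d + 1.0
            elif code == 7:  # ego
                vi = (self.z[i] - self.zbar) if self.net_kind[k] == 1 else (
                    self.net_vec[k, i] - self.net_c1[k]
                )
                mat[k] = d * vi
            elif code == 8:  # alter
                va = (self.z - self.zbar) if self.net_kind[k] == 1 else (
                    self.net_vec[k] - self.net_c1[k]
                )
                mat[k] = d * va
            elif code == 9:  # similarity
                if self.net_kind[k] == 1:
                    s = 1.0 - np.abs(self.z - self.z[i]) / self.zrange - self.znsim
                else:
                    s = (
                        1.0
                        - np.abs(self.net_vec[k] - self.net_vec[k, i]) / self.net_c2[k]
                        - self.net_c1[k]
                    )
                mat[k] = d * s
            else:  # same
                v = self.z if self.net_kind[k] == 1 else self.net_vec[k]
                vi = v[i]
                mat[k] = d * (v == vi)
        mat[:, i] = 0.0
        return mat

    def network_delta_utilities(self, i: int) -> np.ndarray:
        """u[j] = f_i(post-toggle of i->j) - f_i(current); u[i] = 0."""
        if self.net_code.size == 0:
            return np.zeros(self.n)
        return self.net_param @ self.network_delta_matrix(i)

    def network_probabilities(self, i: int, cap: int | None = None) -> np.ndarray:
        """Choice probabilities; slot j = toggle i->j, slot i = no change."""
        u = self.network_delta_utilities(i)
        if cap is not None and self.outdeg[i] >= cap:
            u = u.copy()
            u[self.x[i] == 0] = -np.inf
            u[i] = 0.0
        u = u - u.max()
        w = np.exp(u)
        return w / w.sum()

    def toggle(self, i: int, j: int) -> None:
        new = 1.0 - self.x[i, j]
        self.x[i, j] = new
        d = 2.0 * new - 1.0
        self.outdeg[i] += d
        self.indeg[j] += d

    # -- behavior side ------------------------------------------------------

    def behavior_options(self, i: int) -> np.ndarray:
        zi = int(self.z[i])
        opts = [v for v in (zi - 1, zi, zi + 1) if BEHAVIOR_MIN <= v <= BEHAVIOR_MAX]
        return np.array(opts, dtype=np.int64)

    def behavior_stat_matrix(self, i: int, opts: np.ndarray) -> np.ndarray:
        """Per-effect statistics at each candidate level, shape (K, n_opts)."""
        kb = self.beh_code.size
        mat = np.empty((kb, opts.size))
        od = self.outdeg[i]
        alt_sum = float(self.x[i] @ (self.z - self.zbar)) if od > 0 else 0.0
        for k in range(kb):
            code = self.beh_code[k]
            for c, zc in enumerate(opts):
                zcen = zc - self.zbar
                if code == 0:
                    s = zcen
                elif code == 1:
                    s = zcen * zcen
                elif code == 2:
                    s = zcen * alt_sum / od if od > 0 else 0.0
                elif code == 3:
                    if od > 0:
                        sim = 1.0 - np.abs(self.z - zc) / self.zrange - self.znsim
                        s = float(self.x[i] @ sim) / od
                    else:
                        s = 0.0
                else:
                    s = zcen * self.beh_vec[k, i]
                mat[k, c] = s
        return mat

    def behavior_objective(self, i: int, zi: int) -> float:
        """f_i^Z with actor i's behavior set to zi, others unchanged."""
        opts = np.array([zi], dtype=np.int64)
        return float(self.beh_param @ self.behavior_stat_matrix(i, opts))

    def behavior_probabilities(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        opts = self.behavior_options(i)
        if self.beh_code.size:
            u = self.beh_param @ self.behavior_stat_matrix(i, opts)
        else:
            u = np.zeros(opts.size)
        u = u - u.max()
        w = np.exp(u)
        return opts, w / w.sum()


# ---------------------------------------------------------------------------
# Public operations.


def network_choice_probabilities(
    actor: int,
    state: SimState,
    model: ModelSpec,
    centering: CenteringConstants,
    covariates: pd.DataFrame,
    out_degree_cap: int | None = None,
) -> np.ndarray:
    """Multinomial-logit probabilities for one network micro-step.

    Returns a length-n vector; entry j != actor is the probability of
    toggling the tie actor->j, entry ``actor`` the probability of keeping
    the current network.
    """
    ctx = SimContext(state.ties, state.behavior, covariates, model, centering)
    return ctx.network_probabilities(actor, cap=out_degree_cap)


def behavior_choice_probabilities(
    actor: int,
    state: SimState,
    model: ModelSpec,
    centering: CenteringConstants,
    covariates: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray]:
    """Admissible new levels and their probabilities for one behavior
    micro-step; moves outside the behavior scale are truncated away."""
    ctx = SimContext(state.ties, state.behavior, covariates, model, centering)
    return ctx.behavior_probabilities(actor)


def _python_chain(ctx: SimContext, sides, actors, u_choice, cap, score, times, trace):
    """Reference event loop; mirrors the compiled kernel operation by
    operation and records a trace when requested."""
    kn = ctx.net_code.size
    n_net = n_beh = 0
    for ev in range(sides.size):
        i = int(actors[ev])
        if sides[ev]:
            n_net += 1
            mat = ctx.network_delta_matrix(i)
            u = ctx.net_param @ mat if kn else np.zeros(ctx.n)
            if cap > 0 and ctx.outdeg[i] >= cap:
                u[ctx.x[i] == 0] = -1.0e30
                u[i] = 0.0
            w = np.exp(u - u.max())
            tot = w.sum()
            jsel = int(np.searchsorted(np.cumsum(w), u_choice[ev] * tot, side="right"))
            jsel = min(jsel, ctx.n - 1)
            if score is not None:
                score[:kn] += mat[:, jsel] - (mat @ w) / tot
            if jsel != i:
                ctx.toggle(i, jsel)
            side, opt = "network", jsel
        else:
            n_beh += 1
            opts = ctx.behavior_options(i)
            mat = ctx.behavior_stat_matrix(i, opts)
            u = ctx.beh_param @ mat if ctx.beh_code.size else np.zeros(opts.size)
            w = np.exp(u - u.max())
            tot = w.sum()
            csel = int(np.searchsorted(np.cumsum(w), u_choice[ev] * tot, side="right"))
            csel = min(csel, opts.size - 1)
            if score is not None:
                score[kn:] += mat[:, csel] - (mat @ w) / tot
            ctx.z[i] = opts[csel]
            side, opt = "behavior", int(ctx.z[i])
        if trace is not None:
            trace.append(TraceRecord(ev, float(times[ev]), side, i, opt))
    return n_net, n_beh


def simulate_period(
    ties: np.ndarray,
    behavior: np.ndarray,
    covariates: pd.DataFrame,
    model: ModelSpec,
    centering: CenteringConstants,
    options: SimOptions | None = None,
    rng: np.random.Generator | None = None,
    compute_score: bool = False,
):
    """Simulate one between-wave period of micro-steps.

    The number of opportunities is Poisson with mean n*(rate_net +
    rate_beh); identical seed and inputs give bit-identical output.
    Returns ``(state, trace)``, or ``(state, trace, score)`` when
    ``compute_score`` is set.  The score is the exact gradient of the log
    path probability in the parameter vector (rates first): for a beta it
    accumulates "statistic of the chosen option minus its
    choice-probability expectation" over the micro-steps of its side; for a
    rate it is the Poisson count identity N_side / rate - n.
    """
    options = options or SimOptions()
    if rng is None:
        rng = np.random.default_rng(options.seed)
    ctx = SimContext(ties, behavior, covariates, model, centering,
                     keep_all_effects=compute_score)
    lam_n = model.network_rate
    lam_b = model.behavior_rate if model.behavior_effects else 0.0
    total = ctx.n * (lam_n + lam_b)
    trace: list[TraceRecord] = []
    n_rates = model.n_rates
    kn_all = len(model.network_effects)
    score = None
    if compute_score:
        score = np.zeros(n_rates + kn_all + len(model.behavior_effects))
    n_net = n_beh = 0
    if total > 0:
        n_events = int(rng.poisson(total))
        sides = rng.random(n_events) < (lam_n / (lam_n + lam_b))
        actors = rng.integers(0, ctx.n, size=n_events)
        u_choice = rng.random(n_events)
        # event times drawn last so that recording a trace does not perturb
        # the choice stream: same seed gives the same path with or without it
        times = np.sort(rng.random(n_events)) if options.record_trace else None
        cap = int(options.out_degree_cap or 0)
        eff_score = score[n_rates:] if compute_score else None
        if _HAVE_KERNEL and not options.record_trace:
            n_net, n_beh = _run_chain(
                ctx.x, ctx.z, ctx.outdeg, ctx.indeg,
                ctx.net_code, ctx.net_param, ctx.net_kind,
                ctx.net_vec, ctx.net_c1, ctx.net_c2,
                ctx.beh_code, ctx.beh_param, ctx.beh_vec,
                ctx.zbar, ctx.zrange, ctx.znsim,
                sides, actors, u_choice,
                cap, compute_score,
                eff_score if eff_score is not None else np.zeros(0),
                BEHAVIOR_MIN, BEHAVIOR_MAX,
            )
        else:
            n_net, n_beh = _python_chain(
                ctx, sides, actors, u_choice, cap, eff_score, times,
                trace if options.record_trace else None,
            )
    if compute_score:
        score[0] = n_net / lam_n - ctx.n if lam_n > 0 else 0.0
        if n_rates == 2:
            score[1] = n_beh / lam_b - ctx.n if lam_b > 0 else 0.0
    state = SimState(ties=ctx.x.astype(np.int8), behavior=ctx.z.copy(), clock=1.0)
    if compute_score:
        return state, trace, score
    return state, trace


def write_trace(trace: list[TraceRecord], path) -> None:
    """Export a micro-step trace as delimited text."""
    df = pd.DataFrame(
        [
            {
                "event_index": t.event_index,
                "clock": t.clock,
                "side": t.side,
                "actor": t.actor,
                "option": t.option,
            }
            for t in trace
        ],
        columns=["event_index", "clock", "side", "actor", "option"],
    )
    df.to_csv(path, sep="\t", index=False)


def replicate_seed(master_seed: int, replicate: int) -> np.random.Generator:
    """Deterministic per-replicate generator, independent of replicate order."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(replicate,)))
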