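"""Method-of-Moments estimation via Robbins-Monro stochastic approximation.

For each parameter the model supplies a target statistic: the sum over
responding actors of the effect statistic evaluated at the wave-2 state for
evaluation effects, and the observed amount of change (tie toggles, behavior
level steps) for the rate parameters.  Estimation finds the theta at which
the expected simulated targets equal the observed ones:

* Phase 1 estimates the sensitivity matrix D = dE[S]/dtheta at the starting
  point by common-random-number central finite differences.
* Phase 2 runs Robbins-Monro subphases: one simulation per iteration,
  update theta <- theta - a * D^-1 (S_sim - S_obs) using the diagonal of D,
  gain halved per subphase, theta averaged over each subphase's trajectory
  (Polyak style).  A damped Newton polish on replicate means then drives
  the moment equation the last stretch, with the full D estimated by the
  likelihood-ratio identity D = Cov(S, dlogP/dtheta) from the same
  replicates.
* Phase 3 freezes theta, simulates a large replicate set for convergence
  t-ratios t_k = mean(S_k - s_obs,k)/sd(S_k), estimates D at the solution
  from those replicates' scores, and forms the delta-method covariance
  D^-1 Sigma D^-T.

Cells belonging to wave-2 non-responders are non-informative: their
outgoing rows are zeroed before statistics are evaluated and their per-actor
contributions are excluded from every target sum, for observed and simulated
states alike, so imputed data never enter the moment conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .effects import (
    CenteringConstants,
    ModelSpec,
    behavior_actor_statistics,
    compute_centering,
    network_actor_statistics,
)
from .panel import SchoolPanel
from .simulator import replicate_seed, simulate_period

logger = logging.getLogger(__name__)


class DegenerateDataError(ValueError):
    """No observed change on a modeled side: the rate is unidentifiable."""


class IllConditionedError(RuntimeError):
    """The sensitivity matrix is numerically singular.

    Usually a sign that the effect set is too rich for the data; consider
    removing near-collinear effects.
    """


@dataclass
class FitOptions:
    """Phase sizes and gains for the stochastic-approximation fit.

    The phase-3 replicate count sets the resolution of the convergence
    t-ratios: with n3 replicates the Monte-Carlo noise floor of each t-ratio
    is about 1/sqrt(n3), so declaring max |t| < 0.10 meaningfully requires
    n3 on the order of a thousand.
    """

    n1: int = 15                 # phase-1 derivative replicates
    n_subphases: int = 3
    n2_base: int = 30            # iterations in the first subphase (doubles per subphase)
    a0: float = 0.1              # initial Robbins-Monro gain
    n3: int = 2500               # phase-3 replicates
    n3_deriv: int = 20           # CRN replicates for full derivative estimates
    n_sub_deriv: int = 6         # CRN replicates for per-subphase diagonal refresh
    max_restarts: int = 3
    n_polish: int = 12           # damped Newton polish steps after phase 2
    eps: float = 0.3             # finite-difference step (absolute)
    out_degree_cap: int | None = None
    conv_limit: float = 0.10     # max |t-ratio| for convergence

    @property
    def polish_sims(self) -> list[int]:
        """Escalating replicate counts for the Newton polish steps."""
        n = self.n3
        base = [max(100, n // 8), max(200, n // 4), max(400, n // 2)]
        return (base + [n] * max(0, self.n_polish - 3))[: self.n_polish]

    @classmethod
    def scaled(cls) -> "FitOptions":
        """Reduced phase sizes for quick runs and continuous testing."""
        return cls(n1=12, n2_base=25, n3=2000, n_polish=10)


@dataclass
class SchoolFit:
    """Per-school estimate: theta, SEs, convergence diagnostics, provenance."""

    school_id: str
    parameter_names: list[str]
    theta_hat: np.ndarray
    se: np.ndarray
    t_conv: np.ndarray
    converged: bool
    n_phase2_iterations: int
    n_phase3_replicates: int
    seed: int
    model: ModelSpec = None  # type: ignore[assignment]
    sim_targets: np.ndarray | None = None  # phase-3 target archive (replicates x p)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "school_id": self.school_id,
                "effect": self.parameter_names,
                "beta": self.theta_hat,
                "se": self.se,
                "t_conv": self.t_conv,
                "converged": self.converged,
            }
        )


# ---------------------------------------------------------------------------
# Targets


def _target_statistics(
    panel: SchoolPanel,
    model: ModelSpec,
    centering: CenteringConstants,
    ties_end: np.ndarray,
    z_end: np.ndarray,
) -> np.ndarray:
    """Target vector at an end-of-period state (observed or simulated)."""
    resp = panel.responded_wave2
    x = np.asarray(ties_end, dtype=np.float64).copy()
    x[~resp, :] = 0.0  # non-responder rows are non-informative
    vals = [float(np.abs(x[resp] - panel.wave1[resp]).sum())]
    if model.behavior_effects:
        vals.append(float(np.abs(z_end[resp] - panel.behavior1[resp]).sum()))
    for eff in model.network_effects:
        s = network_actor_statistics(eff, x, z_end, panel.covariates, centering)
        vals.append(float(s[resp].sum()))
    for eff in model.behavior_effects:
        s = behavior_actor_statistics(eff, x, z_end, panel.covariates, centering)
        vals.append(float(s[resp].sum()))
    return np.array(vals)


def observed_targets(
    panel: SchoolPanel, model: ModelSpec, centering: CenteringConstants | None = None
) -> np.ndarray:
    """Deterministic target statistics of the wave-2 observation.

    Raises :class:`DegenerateDataError` when a modeled side shows zero
    observed change (its rate parameter would be unidentifiable).
    """
    centering = centering or compute_centering(panel)
    t = _target_statistics(panel, model, centering, panel.wave2, panel.behavior2)
    if t[0] == 0:
        raise DegenerateDataError(
            f"school {panel.school_id!r}: no observed tie change among responders"
        )
    if model.behavior_effects and t[1] == 0:
        raise DegenerateDataError(
            f"school {panel.school_id!r}: no observed behavior change among responders"
        )
    return t


def _simulate_once(
    panel: SchoolPanel,
    model: ModelSpec,
    centering: CenteringConstants,
    rng: np.random.Generator,
    cap: int | None = None,
) -> np.ndarray:
    from .simulator import SimOptions

    state, _ = simulate_period(
        panel.wave1,
        panel.behavior1,
        panel.covariates,
        model,
        centering,
        options=SimOptions(out_degree_cap=cap),
        rng=rng,
    )
    return _target_statistics(panel, model, centering, state.ties, state.behavior)


def simulate_targets(
    panel: SchoolPanel,
    model: ModelSpec,
    n_replicates: int,
    seed: int,
    centering: CenteringConstants | None = None,
    seed_offset: int = 0,
    cap: int | None = None,
) -> np.ndarray:
    """Monte-Carlo target matrix: one row of end-of-period statistics per
    replicate, with per-replicate seeds derived deterministically from the
    master seed (row multiset independent of replicate order)."""
    centering = centering or compute_centering(panel)
    rows = [
        _simulate_once(panel, model, centering, replicate_seed(seed, seed_offset + r), cap)
        for r in range(n_replicates)
    ]
    return np.vstack(rows)


def _simulate_scored(
    panel: SchoolPanel,
    model: ModelSpec,
    centering: CenteringConstants,
    n_replicates: int,
    seed: int,
    seed_offset: int = 0,
    cap: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Targets plus path scores, one row per replicate."""
    from .simulator import SimOptions

    t_rows, s_rows = [], []
    for r in range(n_replicates):
        state, _, score = simulate_period(
            panel.wave1, panel.behavior1, panel.covariates, model, centering,
            options=SimOptions(out_degree_cap=cap),
            rng=replicate_seed(seed, seed_offset + r),
            compute_score=True,
        )
        t_rows.append(_target_statistics(panel, model, centering, state.ties, state.behavior))
        s_rows.append(score)
    return np.vstack(t_rows), np.vstack(s_rows)


def _score_derivative(targets: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Likelihood-ratio sensitivity estimate D[k, l] = cov(S_k, score_l).

    Unbiased for dE[S_k]/dtheta_l because E[score] = 0 and
    dE[S]/dtheta = E[S * dlogP/dtheta]; computed from the same replicates
    that provide the target means, at no extra simulation cost.
    """
    tc = targets - targets.mean(axis=0)
    sc = scores - scores.mean(axis=0)
    return tc.T @ sc / (targets.shape[0] - 1)


# ---------------------------------------------------------------------------
# Derivative estimation


def estimate_derivative(
    panel: SchoolPanel,
    model: ModelSpec,
    theta: np.ndarray,
    n1: int,
    seed: int,
    centering: CenteringConstants | None = None,
    eps: float = 0.1,
    seed_offset: int = 0,
    cap: int | None = None,
    check_conditioning: bool = True,
) -> np.ndarray:
    """Finite-difference sensitivity matrix D[k, l] = dE[S_k]/dtheta_l.

    Central differences with common random numbers: for each parameter the
    +eps and -eps simulations reuse the identical seed, which cancels most
    Monte-Carlo noise in the paired difference.  The step is halved when a
    perturbed simulation produces non-finite targets.
    """
    centering = centering or compute_centering(panel)
    theta = np.asarray(theta, dtype=float)
    p = theta.size
    if check_conditioning and n1 < p + 3:
        logger.warning("derivative replicates n1=%d < p+3=%d", n1, p + 3)
    acc = np.zeros((p, p))
    n_rates = model.n_rates
    for l in range(p):
        e = eps
        # keep rate parameters positive under perturbation
        if l < n_rates:
            e = min(eps, 0.45 * theta[l]) if theta[l] > 0 else eps
        for _attempt in range(6):
            col = np.zeros(p)
            ok = True
            for r in range(n1):
                tp, tm = theta.copy(), theta.copy()
                tp[l] += e
                tm[l] -= e
                sp = _simulate_once(panel, model.with_theta(tp), centering,
                                    replicate_seed(seed, seed_offset + r), cap)
                sm = _simulate_once(panel, model.with_theta(tm), centering,
                                    replicate_seed(seed, seed_offset + r), cap)
                d = (sp - sm) / (2.0 * e)
                if not np.all(np.isfinite(d)):
                    ok = False
                    break
                col += d
            if ok:
                acc[:, l] = col / n1
                break
            e *= 0.5
        else:
            raise IllConditionedError(f"derivative for parameter {l} did not stabilize")
    if check_conditioning and np.linalg.cond(acc) > 1e8:
        raise IllConditionedError(
            "sensitivity matrix is ill-conditioned (cond > 1e8); "
            "consider reducing the effect set"
        )
    return acc


# ---------------------------------------------------------------------------
# The fit


def initial_theta(panel: SchoolPanel, model: ModelSpec) -> np.ndarray:
    """Starting point: density -1, all other betas 0, rates from the
    observed per-actor change counts."""
    resp = panel.responded_wave2
    n_resp = max(int(resp.sum()), 1)
    tie_changes = float(np.abs(panel.wave2[resp] - panel.wave1[resp]).sum())
    theta = []
    theta.append(max(tie_changes / n_resp, 0.5))
    if model.behavior_effects:
        beh_changes = float(np.abs(panel.behavior2[resp] - panel.behavior1[resp]).sum())
        theta.append(max(beh_changes / n_resp, 0.5))
    for e in model.network_effects:
        theta.append(-1.0 if e.name == "density" else 0.0)
    theta.extend(0.0 for _ in model.behavior_effects)
    return np.array(theta)


def _safe_inverse(dmat: np.ndarray) -> np.ndarray:
    """Inverse with a ridge fallback for noisy finite-difference matrices."""
    if np.linalg.cond(dmat) > 1e8:
        scale = float(np.mean(np.abs(np.diag(dmat)))) or 1.0
        dmat = dmat + 0.05 * scale * np.eye(dmat.shape[0])
    return np.linalg.inv(dmat)


def _clip_theta(theta: np.ndarray, n_rates: int) -> np.ndarray:
    theta = theta.copy()
    theta[:n_rates] = np.clip(theta[:n_rates], 0.05, 30.0)
    theta[n_rates:] = np.clip(theta[n_rates:], -12.0, 12.0)
    return theta


def _phase2(
    panel, model, centering, theta, dmat, s_obs, options: FitOptions, seed, seed_offset, cap
):
    """Robbins-Monro subphases with Polyak trajectory averaging.

    Updates use only the diagonal of the sensitivity matrix: the diagonal of
    the common-random-number estimate is accurate, while its off-diagonal
    entries are noisy, and a noisy inverse can flip the update direction for
    near-collinear effects (the linear/quadratic/average-alter trio in
    particular) and send the iteration running away.  The full matrix is
    reserved for the Newton polish and the covariance, where it is estimated
    at the solution with more replicates.  The diagonal is refreshed at the
    start of each subphase; the gain halves per subphase while the iteration
    count doubles.
    """
    n_rates = model.n_rates
    count = 0
    for sub in range(options.n_subphases):
        if sub > 0:
            try:
                dmat = estimate_derivative(
                    panel, model, theta, options.n_sub_deriv,
                    seed, centering, eps=options.eps,
                    seed_offset=seed_offset + 700_000 + sub * 10_000, cap=cap,
                    check_conditioning=False,
                )
            except IllConditionedError:
                pass  # keep the previous subphase's matrix
        dinv = np.diag(1.0 / np.clip(np.diag(dmat), 1e-3, None))
        a = options.a0 / (2.0**sub)
        n_iter = options.n2_base * (2**sub)
        history = np.empty((n_iter, theta.size))
        for it in range(n_iter):
            s = _simulate_once(
                panel, model.with_theta(theta), centering,
                replicate_seed(seed, seed_offset + count), cap,
            )
            step = a * (dinv @ (s - s_obs))
            norm = np.linalg.norm(step)
            if norm > 1.0:  # guard against runaway updates early in a subphase
                step /= norm
            theta = _clip_theta(theta - step, n_rates)
            history[it] = theta
            count += 1
        theta = _clip_theta(history.mean(axis=0), n_rates)
    return theta, count, dmat


def _lm_polish(
    panel, model, centering, theta, dmat, s_obs, options: FitOptions, seed,
    base_offset, cap,
):
    """Damped weighted Newton iteration on simulated moment means.

    Solves the weighted normal equations (A'A + lam*diag(A'A)) step = A'b
    with A the sd-weighted sensitivity matrix; a candidate step is accepted
    only if it does not worsen the max absolute t-ratio, otherwise the
    damping is increased (classic Levenberg-Marquardt control, adapted to a
    noisy objective).
    """
    n_rates = model.n_rates
    lam = 0.3
    m0 = options.polish_sims[0]
    sims, scores = _simulate_scored(
        panel, model.with_theta(theta), centering, m0, seed,
        seed_offset=base_offset + 900_000, cap=cap,
    )
    r = sims.mean(axis=0) - s_obs
    sd = np.clip(sims.std(axis=0, ddof=1), 1e-9, None)
    cur = float(np.linalg.norm(r / sd))
    best = (float(np.max(np.abs(r / sd))), theta, sims, scores)
    for k, m in enumerate(options.polish_sims):
        if best[0] < 0.7 * options.conv_limit:
            break
        dmat = _score_derivative(sims, scores)
        w = 1.0 / sd
        amat = w[:, None] * dmat
        b = w * r
        hess = amat.T @ amat
        dh = np.diag(np.clip(np.diag(hess), 1e-9, None))
        step = np.linalg.solve(hess + lam * dh, amat.T @ b)
        cand = _clip_theta(theta - step, n_rates)
        sims2, scores2 = _simulate_scored(
            panel, model.with_theta(cand), centering, m, seed,
            seed_offset=base_offset + 910_000 + k * 20_000, cap=cap,
        )
        r2 = sims2.mean(axis=0) - s_obs
        sd2 = np.clip(sims2.std(axis=0, ddof=1), 1e-9, None)
        new = float(np.linalg.norm(r2 / sd2))
        max2 = float(np.max(np.abs(r2 / sd2)))
        if m >= options.n3 // 2 and max2 < best[0]:
            best = (max2, cand, sims2, scores2)
        if new <= cur:  # monotone acceptance in the weighted residual norm
            theta, r, sd, cur = cand, r2, sd2, new
            sims, scores = sims2, scores2
            lam = max(lam / 3.0, 0.01)
        else:
            lam = min(lam * 5.0, 1e3)
    if best[0] < float(np.max(np.abs(r / sd))):
        theta, sims, scores = best[1], best[2], best[3]
    return theta, _score_derivative(sims, scores)


def fit_school(
    panel: SchoolPanel,
    model: ModelSpec,
    options: FitOptions | None = None,
    seed: int = 0,
) -> SchoolFit:
    """Fit one school's co-evolution model by simulated Method of Moments.

    Returns a :class:`SchoolFit`; ``converged`` is True when every
    evaluation-effect convergence t-ratio is below the threshold in absolute
    value.  Non-convergence after the allowed restarts returns the fit with
    ``converged=False`` rather than raising.
    """
    options = options or FitOptions()
    centering = compute_centering(panel)
    s_obs = observed_targets(panel, model, centering)
    theta = initial_theta(panel, model)
    cap = options.out_degree_cap
    n_rates = model.n_rates
    p = theta.size

    dmat = estimate_derivative(
        panel, model, theta, options.n1, seed, centering,
        eps=options.eps, seed_offset=0, cap=cap,
    )
    total_phase2 = 0
    se = np.full(p, np.nan)
    t_conv = np.full(p, np.nan)
    sims = None
    converged = False
    best = (np.inf, theta, None, t_conv, dmat)
    for attempt in range(options.max_restarts + 1):
        # restarts re-enter phase 2 from the current estimate: the averaged
        # stochastic iteration can pull a trapped point back into the main
        # basin before the deterministic polish resumes.  A badly stuck
        # estimate (well above the convergence limit) restarts from the
        # initial point instead - a fresh basin is more promising than the
        # neighborhood of a trapped one.
        if attempt >= 2 and best[0] > 2.5 * options.conv_limit:
            theta = initial_theta(panel, model)
        theta, n_iter, dmat = _phase2(
            panel, model, centering, theta, dmat, s_obs, options, seed,
            seed_offset=100_000 + attempt * 1_000_000, cap=cap,
        )
        total_phase2 += n_iter
        # Damped (Levenberg-Marquardt) polish with escalating replicate
        # counts: full-matrix steps on increasingly accurate replicate means
        # drive the moment equation the last stretch that noisy single-
        # simulation updates cannot.  Damping plus step acceptance protects
        # against the near-flat directions of the moment map (collinear
        # effects), whose finite-difference gains are too noisy for a plain
        # Newton step.
        theta, dmat = _lm_polish(
            panel, model, centering, theta, dmat, s_obs, options, seed,
            base_offset=800_000 + attempt * 1_000_000, cap=cap,
        )
        sims, scores = _simulate_scored(
            panel, model.with_theta(theta), centering, options.n3, seed,
            seed_offset=300_000 + attempt * 1_000_000, cap=cap,
        )
        dmat = _score_derivative(sims, scores)
        mean = sims.mean(axis=0)
        sd = sims.std(axis=0, ddof=1)
        t_conv = np.where(sd > 0, (mean - s_obs) / np.where(sd > 0, sd, 1.0), np.inf)
        max_t = float(np.max(np.abs(t_conv[n_rates:])))
        converged = max_t < options.conv_limit
        if max_t < best[0]:
            best = (max_t, theta, sims, t_conv, dmat)
        if converged:
            break
        logger.info("school %s: restart %d, max|t|=%.3f", panel.school_id, attempt + 1, max_t)
    if not converged:
        _, theta, sims, t_conv, dmat = best
    dinv = _safe_inverse(dmat)
    sigma = np.cov(sims.T)
    cov_theta = dinv @ sigma @ dinv.T
    diag = np.diag(cov_theta)
    se = np.sqrt(np.where(diag > 0, diag, np.nan))
    return SchoolFit(
        school_id=panel.school_id,
        parameter_names=model.parameter_names,
        theta_hat=theta,
        se=se,
        t_conv=t_conv,
        converged=converged,
        n_phase2_iterations=total_phase2,
        n_phase3_replicates=options.n3,
        seed=seed,
        model=model.with_theta(theta),
        sim_targets=sims,
    )


def two_sided_p(fit: SchoolFit) -> pd.DataFrame:
    """Normal-approximation p-values per parameter.

    right-sided p = 1 - Phi(theta/se), left-sided p = Phi(theta/se),
    two-sided p = 2 * min(right, left).
    """
    if np.any(fit.se[~np.isnan(fit.se)] <= 0):
        raise ValueError("standard error must be positive")
    z = fit.theta_hat / fit.se
    right = 1.0 - stats.norm.cdf(z)
    left = stats.norm.cdf(z)
    return pd.DataFrame(
        {
            "effect": fit.parameter_names,
            "beta": fit.theta_hat,
            "se": fit.se,
            "z": z,
            "p_right": right,
            "p_left": left,
            "p_two_sided": 2.0 * np.minimum(right, left),
        }
    )
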