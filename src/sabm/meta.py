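"""Cross-school pooling of per-school model estimates.

Schools are fitted independently; each effect is then pooled across schools
two ways.  The Snijders-Baerveldt two-stage test treats the per-school
estimates as draws theta_j = mu + U_j + E_j with between-school variance
sigma^2 and known sampling variances se_j^2, and makes inference about mu in
the population of schools.  Fisher's combination procedure pools the
per-school one-sided p-values, -2 * sum(ln p_j) ~ chi^2(2N), separately for
the right-sided (effect positive somewhere) and left-sided tests, and speaks
only about the schools at hand.  The decision rule declares an effect
significant when either Fisher tail is at or below 0.025 (the halved level
controls for testing both tails) or the Snijders-Baerveldt two-sided p is
below 0.05; when the two procedures disagree, the Fisher verdict is treated
as decisive because schools vary widely in size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

P_FLOOR = 1e-12


@dataclass
class MetaResult:
    """Pooled inference for one effect across schools."""

    effect: str
    mu_hat: float
    se_mu: float
    p_two_sided: float
    sigma_between: float
    fisher_right_p: float
    fisher_left_p: float
    n_schools: int
    significant: bool = False
    note: str = ""


def snijders_baerveldt_test(
    estimates: np.ndarray, ses: np.ndarray
) -> tuple[float, float, float, float]:
    """Two-stage random-effects pooling of per-school estimates.

    Iterates weighted least squares with weights 1/(se_j^2 + sigma^2),
    updating sigma^2 by method of moments on the weighted residual statistic
    (truncated at zero) until it stabilizes.  With sigma^2 = 0 this collapses
    to fixed-effect inverse-variance pooling.  The two-sided p uses a t
    reference with N - 1 degrees of freedom.

    Returns ``(mu_hat, se_mu, p_two_sided, sigma_between)``.
    """
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    n = est.size
    if n < 2:
        raise ValueError("at least 2 schools are required")
    if np.any(~np.isfinite(se)) or np.any(se <= 0):
        raise ValueError("all standard errors must be positive and finite")

    def _q(sigma2: float) -> tuple[float, float, float]:
        w = 1.0 / (se**2 + sigma2)
        mu = float(np.sum(w * est) / np.sum(w))
        q = float(np.sum(w * (est - mu) ** 2))
        return mu, q, float(np.sum(w))

    sigma2 = 0.0
    mu, q, wsum = _q(0.0)
    if q > n - 1:  # residual dispersion exceeds sampling noise: sigma^2 > 0
        sigma2 = max(float(np.var(est, ddof=1)) - float(np.mean(se**2)), 1e-10)
        for _ in range(100):
            mu, q, wsum = _q(sigma2)
            new = sigma2 * q / (n - 1)
            if abs(new - sigma2) < 1e-8:
                sigma2 = new
                break
            sigma2 = max(new, 0.0)
            if sigma2 == 0.0:
                break
        mu, q, wsum = _q(sigma2)
    se_mu = float(np.sqrt(1.0 / wsum))
    t = mu / se_mu
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return mu, se_mu, p, float(np.sqrt(sigma2))


def fisher_combination(one_sided_ps, side: str = "right") -> tuple[float, int, float]:
    """Fisher's combination of per-school one-sided p-values.

    T = -2 * sum(ln p_j) referred to chi-square with 2N degrees of freedom;
    p-values are clamped below at 1e-12 (with a logged warning) because a
    numerically zero p would make T infinite.

    Returns ``(T, 2N, combined_p)``.
    """
    p = np.asarray(one_sided_ps, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((p <= 0) | (p > 1)):
        if np.any(p > 1) or np.any(p < 0):
            raise ValueError("p-values must lie in (0, 1]")
        logger.warning("clamping %d zero p-value(s) at %.0e", int((p <= 0).sum()), P_FLOOR)
    if side not in ("right", "left"):
        raise ValueError("side must be 'right' or 'left'")
    p = np.clip(p, P_FLOOR, 1.0)
    t = float(-2.0 * np.sum(np.log(p)))
    df = 2 * p.size
    return t, df, float(stats.chi2.sf(t, df))


def significance_verdict(
    meta: MetaResult, alpha_fisher: float = 0.025, alpha_sb: float = 0.05
) -> tuple[bool, str]:
    """Combined decision rule with provenance note.

    Significant iff either Fisher tail p <= alpha_fisher (boundary
    inclusive) or the Snijders-Baerveldt two-sided p < alpha_sb.  The note
    records which test(s) fired; on conflict the Fisher result is decisive.
    """
    fisher_hit = (
        meta.fisher_right_p <= alpha_fisher or meta.fisher_left_p <= alpha_fisher
    )
    sb_hit = meta.p_two_sided < alpha_sb
    significant = fisher_hit or sb_hit
    if fisher_hit and sb_hit:
        note = "significant by both Fisher combination and Snijders-Baerveldt tests"
    elif fisher_hit:
        note = (
            "significant by Fisher combination only; Fisher taken as decisive "
            "given the variation in school sizes"
        )
    elif sb_hit:
        note = (
            "significant by Snijders-Baerveldt only; Fisher taken as decisive "
            "given the variation in school sizes"
        )
    else:
        note = "not significant by either test"
    return significant, note


def selection_odds_ratio(beta: float, se: float | None = None):
    """Odds-ratio reading of a selection coefficient.

    exp(beta) compares the odds of a friendship nomination between two
    actors identical on the covariate against two maximally different ones
    (similarity 1 vs 0), so exp(-beta) is exactly the reciprocal.  Reports
    round it to two decimals; the optional interval exp(beta +/- 1.96 se)
    is a normal-approximation interval.
    """
    or_ = float(np.exp(beta))
    if se is None:
        return or_
    lo = float(np.exp(beta - 1.96 * se))
    hi = float(np.exp(beta + 1.96 * se))
    return or_, (lo, hi)


def meta_analyze(
    fits, alpha_fisher: float = 0.025, alpha_sb: float = 0.05
) -> list[MetaResult]:
    """Pool a list of converged :class:`~sabm.estimation.SchoolFit` objects
    effect by effect (rate parameters are school-specific and not pooled)."""
    from .estimation import two_sided_p

    if len(fits) < 2:
        raise ValueError("meta-analysis requires at least 2 schools")
    names = fits[0].parameter_names
    n_rates = fits[0].model.n_rates if fits[0].model is not None else 1
    for f in fits[1:]:
        if f.parameter_names != names:
            raise ValueError("all fits must share the same effect list")
    tables = [two_sided_p(f) for f in fits]
    results = []
    for k, name in enumerate(names):
        if k < n_rates:
            continue
        est = np.array([f.theta_hat[k] for f in fits])
        ses = np.array([f.se[k] for f in fits])
        mu, se_mu, p2, sig_b = snijders_baerveldt_test(est, ses)
        _, _, p_r = fisher_combination([t["p_right"].iloc[k] for t in tables], "right")
        _, _, p_l = fisher_combination([t["p_left"].iloc[k] for t in tables], "left")
        m = MetaResult(
            effect=name,
            mu_hat=mu,
            se_mu=se_mu,
            p_two_sided=p2,
            sigma_between=sig_b,
            fisher_right_p=p_r,
            fisher_left_p=p_l,
            n_schools=len(fits),
        )
        m.significant, m.note = significance_verdict(m, alpha_fisher, alpha_sb)
        results.append(m)
    return results


def meta_table(results: list[MetaResult]) -> pd.DataFrame:
    """Meta results as a table in the conventional column layout."""
    return pd.DataFrame(
        {
            "effect": [m.effect for m in results],
            "beta": [m.mu_hat for m in results],
            "se": [m.se_mu for m in results],
            "p_value": [m.p_two_sided for m in results],
            "between_school_sd": [m.sigma_between for m in results],
            "fisher_right": [m.fisher_right_p for m in results],
            "fisher_left": [m.fisher_left_p for m in results],
            "significant": [m.significant for m in results],
        }
    )
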