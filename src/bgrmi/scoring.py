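"""Closed-form Bayesian scoring of one candidate regulator subset.

A regulation model M_k for gene i is the linear lagged regression of
the gene's expression on an intercept, its own lagged expression, and
the lagged expressions of the subset's regulators.  Its marginal
likelihood integrates the Gaussian likelihood against conjugate
priors: a flat (Jeffreys) prior on the intercept, the Jeffreys prior
p(sigma^2) ∝ 1/sigma^2 on the noise variance, and a Zellner g-prior

    beta | sigma^2  ~  N(0, c * sigma^2 * (X'X)^{-1})

on the non-intercept coefficients, with X mean-centred (the flat
intercept makes the marginal depend on the data only through centred
quantities).  Integrating alpha, beta and sigma^2 gives, in logs,

    log p(y | M_k) = log Gamma((n-1)/2) - ((n-1)/2) log(pi)
                     - (1/2) log(n) - (p/2) log(1 + c)
                     - ((n-1)/2) log( c/(1+c) * SSE + 1/(1+c) * TSS )

where p counts the g-prior regressors (self-lag plus subset), SSE is
the residual sum of squares of the ordinary least-squares fit, and
TSS the centred total sum of squares of y.  The Zellner constant
follows the Fernandez-Ley-Steel benchmark c = max(n, p_total^2) with
p_total the gene's total candidate count.

Every probability is carried as a natural log; constants common to
all models of a gene cancel in posterior ratios but are kept so the
value is a genuine log marginal density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .design import RegressionDesign

__all__ = [
    "GeneModelScore",
    "SingularModelError",
    "fit_ols",
    "zellner_g",
    "log_marginal_likelihood",
    "log_posterior",
    "score_model",
    "SSE_FLOOR_REL",
]

# Relative floor on SSE: perfect fits are capped at this fraction of
# ||y||^2 so that degenerate interpolating models stay finite.
SSE_FLOOR_REL = 1e-12


class SingularModelError(ValueError):
    """The design matrix for a subset is rank-deficient."""


@dataclass
class GeneModelScore:
    """One candidate regulator subset with its fit and posterior mass."""

    target_id: str
    regulator_subset: tuple[str, ...]
    p: int
    n: int
    sse: float
    log_marginal: float
    log_prior: float
    log_posterior_unnorm: float
    beta_hat: np.ndarray  # [intercept, self-lag, subset coefficients]
    g: float

    def coefficient(self, regulator_id: str) -> float:
        """Maximum-likelihood regulation coefficient of one member TF."""
        return float(self.beta_hat[2 + self.regulator_subset.index(regulator_id)])


def fit_ols(design: RegressionDesign, subset: tuple[str, ...]) -> tuple[np.ndarray, float]:
    """Least-squares fit of [intercept, self-lag, subset] via SVD.

    Returns (beta_hat, sse).  Raises SingularModelError when the
    design is rank-deficient (e.g. duplicated candidate columns), which
    the search treats as an inadmissible model.
    """
    X = design.columns_for(subset)
    n, k = X.shape
    if n <= k + 1:
        raise SingularModelError(
            f"{design.target_id}: n={n} too small for {k} coefficients"
        )
    beta, _, rank, _ = np.linalg.lstsq(X, design.y, rcond=None)
    if rank < k:
        raise SingularModelError(
            f"{design.target_id}: rank-deficient design for subset {subset}"
        )
    resid = design.y - X @ beta
    return beta, float(resid @ resid)


def zellner_g(n: int, p_total: int) -> float:
    """Fernandez-Ley-Steel benchmark prior-covariance multiplier.

    Under beta ~ N(0, c * sigma^2 (X'X)^{-1}) the recommended constant
    is c = max(n, p_total^2), with p_total the total number of
    candidate regressors for the gene (a dataset-level quantity, not
    the per-model size).
    """
    if n < 1 or p_total < 1:
        raise ValueError("n and p_total must be >= 1")
    return float(max(n, p_total * p_total))


def log_marginal_likelihood(
    design: RegressionDesign,
    subset: tuple[str, ...],
    g: float,
    sse: float | None = None,
) -> float:
    """Natural-log g-prior marginal likelihood of one subset.

    ``sse`` may be supplied to reuse an existing fit.  SSE is floored
    at SSE_FLOOR_REL * ||y||^2.  A rank-deficient subset propagates
    SingularModelError.
    """
    if sse is None:
        _, sse = fit_ols(design, subset)
    y = design.y
    n = design.n
    p = len(subset) + 1  # self-lag is under the g-prior too
    tss = float(np.sum((y - y.mean()) ** 2))
    floor = SSE_FLOOR_REL * float(y @ y)
    sse = max(sse, floor)
    q = (g / (1.0 + g)) * sse + (1.0 / (1.0 + g)) * tss
    if q <= 0.0:
        # constant response: no information, treat as inadmissible
        return -np.inf
    return float(
        gammaln((n - 1) / 2.0)
        - ((n - 1) / 2.0) * np.log(np.pi)
        - 0.5 * np.log(n)
        - (p / 2.0) * np.log1p(g)
        - ((n - 1) / 2.0) * np.log(q)
    )


def log_posterior(log_marginal: float, log_prior: float) -> float:
    """Unnormalized log posterior of a model: log marginal + log prior."""
    return log_marginal + log_prior


def score_model(
    design: RegressionDesign,
    subset: tuple[str, ...],
    g: float,
    log_prior: float,
) -> GeneModelScore:
    """Fit and score one regulator subset; -inf posterior if singular."""
    subset = tuple(subset)
    try:
        beta, sse = fit_ols(design, subset)
    except SingularModelError:
        return GeneModelScore(
            target_id=design.target_id,
            regulator_subset=subset,
            p=len(subset) + 1,
            n=design.n,
            sse=np.nan,
            log_marginal=-np.inf,
            log_prior=log_prior,
            log_posterior_unnorm=-np.inf,
            beta_hat=np.full(len(subset) + 2, np.nan),
            g=g,
        )
    lml = log_marginal_likelihood(design, subset, g, sse=sse)
    return GeneModelScore(
        target_id=design.target_id,
        regulator_subset=subset,
        p=len(subset) + 1,
        n=design.n,
        sse=sse,
        log_marginal=lml,
        log_prior=log_prior,
        log_posterior_unnorm=log_posterior(lml, log_prior),
        beta_hat=beta,
        g=g,
    )
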