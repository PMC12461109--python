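"""Maximum-likelihood estimation of Pagel's lambda for a single trait.

The trait is modeled as multivariate normal over species with covariance
``sigma2 * (lam * C + (1 - lam) * I)``; the root state (GLS mean) and the
Brownian rate sigma2 are profiled in closed form for each lambda, and lambda
itself is optimized on [0, 1] by a grid-seeded bounded search.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .tree import PhyloCorrelation

__all__ = ["LambdaFit", "fit_pagel_lambda", "profile_loglik", "fit_lambda_trees"]


@dataclass
class LambdaFit:
    """Result of a Pagel's-lambda maximum-likelihood fit."""

    lambda_hat: float
    sigma2_hat: float
    root_state: float
    loglik: float


def profile_loglik(trait: np.ndarray, C: PhyloCorrelation, lam: float):
    """Log-likelihood at ``lam`` with root state and sigma2 profiled by GLS.

    Returns ``(loglik, root_state, sigma2)``.
    """
    y = np.asarray(trait, dtype=float)
    n = y.size
    V = lam * C.matrix + (1.0 - lam) * np.eye(n)
    try:
        cf = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"singular lambda-transformed covariance at lambda={lam}"
        ) from exc
    ones = np.ones(n)
    Vi1 = cho_solve(cf, ones)
    Viy = cho_solve(cf, y)
    mu = (ones @ Viy) / (ones @ Vi1)
    r = y - mu
    s2 = (r @ cho_solve(cf, r)) / n
    s2 = max(s2, 1e-300)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    ll = -0.5 * (n * np.log(2.0 * np.pi * s2) + logdet + n)
    return ll, mu, s2


def fit_pagel_lambda(trait, C: PhyloCorrelation, grid_points: int = 21) -> LambdaFit:
    """ML fit of Pagel's lambda on [0, 1] for one continuous trait.

    A ``grid_points``-point grid seeds a bounded 1-D derivative-free search
    (the profile likelihood can be multimodal in lambda). When the likelihood
    is flat in lambda within numerical tolerance, lambda = 0 is returned.
    """
    y = np.asarray(trait, dtype=float)
    if y.size < 4:
        raise ValueError("need at least 4 species to estimate lambda")
    if y.size != C.n:
        raise ValueError(f"trait length {y.size} != {C.n} species in C")
    if np.var(y) <= 0:
        raise ValueError("trait is constant; lambda is not estimable")

    grid = np.linspace(0.0, 1.0, grid_points)
    lls = np.array([profile_loglik(y, C, lam)[0] for lam in grid])
    best = int(np.argmax(lls))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid_points - 1)]
    if hi > lo:
        res = minimize_scalar(
            lambda lam: -profile_loglik(y, C, lam)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        lam_hat, ll_hat = float(res.x), -float(res.fun)
        if lls[best] > ll_hat:
            lam_hat, ll_hat = float(grid[best]), float(lls[best])
    else:
        lam_hat, ll_hat = float(grid[best]), float(lls[best])

    ll0 = lls[0]
    if ll_hat - ll0 <= 1e-9:  # flat or boundary tie: prefer no signal
        lam_hat = 0.0
    ll, mu, s2 = profile_loglik(y, C, lam_hat)
    return LambdaFit(lambda_hat=lam_hat, sigma2_hat=s2, root_state=mu, loglik=ll)


def fit_lambda_trees(trait, correlations) -> tuple[list[LambdaFit], float]:
    """Fit lambda on each correlation matrix in a tree set.

    Returns the per-tree fits and the mean of the lambda estimates.
    """
    fits = [fit_pagel_lambda(trait, C) for C in correlations]
    mean_lambda = float(np.mean([f.lambda_hat for f in fits]))
    return fits, mean_lambda
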