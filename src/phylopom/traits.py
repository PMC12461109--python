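"""Species trait tables and phylogenetic imputation of missing values.

Missing entries are replaced by conditional expectations under a
multivariate Brownian-motion model: the joint covariance across all
(species, trait) cells is the Kronecker product of the across-trait
covariance with the phylogenetic correlation matrix. The across-trait
covariance and the ancestral (GLS) means are re-estimated from the completed
table by iterated conditional expectation until the update is smaller than a
tolerance.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .tree import PhyloCorrelation

__all__ = ["TraitMatrix", "ImputationResult", "impute_traits"]


@dataclass
class TraitMatrix:
    """Species-by-trait table; np.nan marks a missing value."""

    species: list
    traits: list
    values: np.ndarray  # (n_species, n_traits) float

    def __post_init__(self):
        self.species = list(self.species)
        self.traits = list(self.traits)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.species), len(self.traits)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.species)} species x {len(self.traits)} traits"
            )
        self.validate()

    def validate(self) -> None:
        mask = self.mask
        for t, name in enumerate(self.traits):
            if mask[:, t].all():
                raise ValueError(f"trait {name!r} is entirely missing")
        for name in self.binary_traits:
            pass  # binary detection itself enforces the {0,1,missing} domain

    @property
    def mask(self) -> np.ndarray:
        """Boolean missingness mask, True where the value is missing."""
        return np.isnan(self.values)

    @property
    def binary_traits(self) -> list:
        """Traits whose observed values are all in {0, 1}."""
        out = []
        for t, name in enumerate(self.traits):
            obs = self.values[~np.isnan(self.values[:, t]), t]
            if obs.size and np.isin(obs, (0.0, 1.0)).all():
                out.append(name)
        return out

    def column(self, trait) -> np.ndarray:
        return self.values[:, self.traits.index(trait)].copy()

    def zscored(self, traits=None) -> np.ndarray:
        """Matrix of z-scored trait columns (population SD); requires no NaN."""
        traits = list(traits) if traits is not None else list(self.traits)
        cols = []
        for name in traits:
            x = self.column(name)
            if np.isnan(x).any():
                raise ValueError(f"trait {name!r} has missing values; impute first")
            sd = x.std()
            if sd <= 0:
                raise ValueError(f"trait {name!r} is constant")
            cols.append((x - x.mean()) / sd)
        return np.column_stack(cols)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_csv(cls, path) -> "TraitMatrix":
        df = pd.read_csv(path)
        if df.columns[0] != "species":
            raise ValueError("trait CSV must start with a 'species' column")
        species = df["species"].astype(str).tolist()
        traits = [c for c in df.columns if c != "species"]
        values = df[traits].to_numpy(dtype=float)
        return cls(species, traits, values)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=self.traits)
        df.insert(0, "species", self.species)
        df.to_csv(path, index=False)

    def copy(self) -> "TraitMatrix":
        return TraitMatrix(self.species, self.traits, self.values.copy())


@dataclass
class ImputationResult:
    """Continuous-scale imputations plus a 0.5-thresholded view of binary traits."""

    raw: TraitMatrix
    thresholded: TraitMatrix
    imputed_mask: np.ndarray
    n_iterations: int

    @property
    def values(self) -> np.ndarray:
        return self.raw.values


def _gls_mean_and_cov(X: np.ndarray, Cinv_chol, n: int):
    ones = np.ones(n)
    Ci1 = cho_solve(Cinv_chol, ones)
    denom = ones @ Ci1
    a = (Ci1 @ X) / denom
    R = X - a
    S = (R.T @ cho_solve(Cinv_chol, R)) / n
    return a, S


def impute_traits(tm: TraitMatrix, C: PhyloCorrelation,
                  tol: float = 1e-8, max_iter: int = 500) -> ImputationResult:
    """Fill missing trait values by their Brownian-motion conditional means.

    Requires each trait to be observed for at least 3 species with a missing
    fraction below 50%. Observed entries are never modified. Binary traits
    are imputed on the continuous scale and additionally reported thresholded
    at 0.5.
    """
    if tm.species != list(C.labels):
        C = C.reorder(tm.species)
    n, T = tm.values.shape
    miss = tm.mask
    for t, name in enumerate(tm.traits):
        n_obs = int((~miss[:, t]).sum())
        if n_obs < 3:
            raise ValueError(f"trait {name!r} observed for only {n_obs} species (need >= 3)")
        if miss[:, t].mean() >= 0.5:
            raise ValueError(f"trait {name!r} missing for >= 50% of species")

    binary = tm.binary_traits
    if not miss.any():
        raw = tm.copy()
        return ImputationResult(raw, _threshold(raw, binary), miss, 0)

    cf = cho_factor(C.matrix, lower=True)
    X = tm.values.copy()
    col_means = np.nanmean(tm.values, axis=0)
    for t in range(T):
        X[miss[:, t], t] = col_means[t]

    # flattened trait-major ordering: cell (species i, trait t) -> t * n + i
    flat_miss = np.where(miss.T.ravel())[0]
    flat_obs = np.where(~miss.T.ravel())[0]
    x_obs = tm.values.T.ravel()[flat_obs]

    n_iter = 0
    delta = np.inf
    for n_iter in range(1, max_iter + 1):
        a, S = _gls_mean_and_cov(X, cf, n)
        S = S + 1e-10 * np.eye(T)
        K = np.kron(S, C.matrix)
        mu = np.repeat(a, n)
        Koo = K[np.ix_(flat_obs, flat_obs)]
        Kmo = K[np.ix_(flat_miss, flat_obs)]
        cond = mu[flat_miss] + Kmo @ np.linalg.solve(Koo, x_obs - mu[flat_obs])
        flat = X.T.ravel()
        delta = float(np.max(np.abs(flat[flat_miss] - cond))) if flat_miss.size else 0.0
        flat[flat_miss] = cond
        X = flat.reshape(T, n).T
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"phylogenetic imputation did not converge after {max_iter} "
            f"iterations (last delta {delta:.3e})"
        )

    raw = TraitMatrix(tm.species, tm.traits, X)
    return ImputationResult(raw, _threshold(raw, binary), miss, n_iter)


def _threshold(tm: TraitMatrix, binary_traits) -> TraitMatrix:
    out = tm.values.copy()
    for name in binary_traits:
        t = tm.traits.index(name)
        out[:, t] = (out[:, t] >= 0.5).astype(float)
    return TraitMatrix(tm.species, tm.traits, out)
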