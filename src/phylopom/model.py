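"""Bayesian fitting of the phylogenetic community occupancy model.

Two model variants share one sampler: without traits the slope prior mean
is a community hypermean per covariate; with traits the mean is a linear
function of z-scored species traits (trait-environment interactions). Each
covariate's Pagel's lambda carries an independent spike-and-slab prior
(point mass at 0, uniform slab), phylogenetic uncertainty is integrated by
resampling the working tree with a Metropolis move each iteration, and
evidence for signal is summarized as a Bayes factor from the posterior
spike/slab occupancy.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _engine
from .survey import DetectionDataset, SiteCovariates
from .traits import TraitMatrix
from .tree import PhyloCorrelation, PhyloTree, correlation_from_tree

__all__ = [
    "CommunityModelSpec",
    "ModelState",
    "PosteriorSamples",
    "BayesFactor",
    "fit_pom",
    "init_state",
    "gibbs_update_Z",
    "update_regression_params",
    "update_lambda_spike_slab",
    "update_tree_index",
    "occupancy_detection_loglik",
    "bayes_factor",
    "gelman_rubin",
    "summarize",
    "summarize_draws",
]

DEFAULT_COVARIATES = ("temperature", "precipitation", "forest_cover")


@dataclass
class CommunityModelSpec:
    """Model and MCMC configuration.

    Desk-scale defaults (3 chains x 20,000 iterations, burn-in 10,000,
    thinning 10) stand in for production-scale runs, which are reachable by
    raising ``iterations``/``burn_in``/``thinning``.
    """

    covariates: tuple = DEFAULT_COVARIATES
    include_traits: bool = False
    trait_names: tuple = ()
    hypermean_scale: float = 5.0
    sd_scale: float = 2.0
    detection_scale: float = 5.0
    spike_mass: float = 0.5
    chains: int = 3
    iterations: int = 20000
    burn_in: int = 10000
    thinning: int = 10
    seed: int = 0
    prior_only: bool = False

    def __post_init__(self):
        self.covariates = tuple(self.covariates)
        self.trait_names = tuple(self.trait_names)
        if not (0.0 < self.spike_mass < 1.0):
            raise ValueError("spike_mass must lie in (0, 1)")
        if not self.burn_in < self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.include_traits and not self.trait_names:
            raise ValueError("include_traits requires trait_names")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in + self.thinning - 1) // self.thinning


def _prepare_inputs(data: DetectionDataset, covariates: SiteCovariates,
                    trees, traits: TraitMatrix | None, spec: CommunityModelSpec):
    for name in spec.covariates:
        if name not in covariates.standardized:
            raise ValueError(
                f"covariate {name!r} must be standardized before fitting"
            )
    if covariates.sites != data.sites:
        raise ValueError("site order differs between detections and covariates")
    X = covariates.matrix(spec.covariates)
    species = data.species
    Cs = []
    for t in trees:
        C = t if isinstance(t, PhyloCorrelation) else correlation_from_tree(t, species)
        if list(C.labels) != species:
            C = C.reorder(species)
        Cs.append(C.matrix)
    Cs = np.ascontiguousarray(np.stack(Cs))
    evals, evecs = np.linalg.eigh(Cs)
    evals = np.ascontiguousarray(evals)
    evecs = np.ascontiguousarray(evecs)
    if spec.include_traits:
        if traits is None:
            raise ValueError("include_traits=True but no trait table supplied")
        if traits.species != species:
            raise ValueError("trait table species order must match detections")
        U = np.column_stack([np.ones(len(species)),
                             traits.zscored(spec.trait_names)])
    else:
        U = np.ones((len(species), 1))
    return X, Cs, evals, evecs, np.ascontiguousarray(U)


@dataclass
class ModelState:
    """Current values of every sampler quantity, for single-step operations."""

    alpha: np.ndarray
    beta: np.ndarray
    gam: np.ndarray
    mean: np.ndarray
    sig: np.ndarray
    hyp: np.ndarray          # [mu_alpha, sig_alpha]
    lam: np.ndarray
    etaD: np.ndarray
    mup: np.ndarray
    sigp: np.ndarray
    Z: np.ndarray
    tree_state: np.ndarray
    Vinv: np.ndarray
    logdetV: np.ndarray
    X: np.ndarray
    U: np.ndarray
    spec: CommunityModelSpec
    ls_block: np.ndarray = None
    ls_eta: np.ndarray = None
    ls_sig: np.ndarray = None
    ls_siga: np.ndarray = None
    ls_sigp: np.ndarray = None
    ls_lam: np.ndarray = None

    @property
    def psi(self) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(self.alpha[None, :] + self.X @ self.beta)))

    def detection_prob(self) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.etaD))


def init_state(data: DetectionDataset, covariates: SiteCovariates, trees,
               traits=None, spec: CommunityModelSpec | None = None,
               seed: int = 0) -> ModelState:
    """Build a ModelState at the sampler's initialization point."""
    spec = spec or CommunityModelSpec()
    X, Cs, evals, evecs, U = _prepare_inputs(data, covariates, trees, traits, spec)
    K, I, J = data.n_species, data.n_sites, X.shape[1]
    M = len(data.methods)
    _engine.seed_rng(seed)
    state = ModelState(
        alpha=np.zeros(K), beta=np.zeros((J, K)),
        gam=np.zeros((J, U.shape[1])), mean=np.zeros((J, K)),
        sig=np.ones(J), hyp=np.array([0.0, 1.0]),
        lam=np.full(J, 0.5), etaD=np.zeros((M, K)),
        mup=np.zeros(M), sigp=np.ones(M),
        Z=np.asarray(data.detected_any, dtype=np.int64).copy(),
        tree_state=np.zeros(1, dtype=np.int64),
        Vinv=np.zeros((J, K, K)), logdetV=np.zeros(J),
        X=X, U=U, spec=spec,
        ls_block=np.full(K, np.log(0.3)),
        ls_eta=np.full((M, K), np.log(0.5)),
        ls_sig=np.full(J, np.log(0.4)),
        ls_siga=np.full(1, np.log(0.4)),
        ls_sigp=np.full(M, np.log(0.4)),
        ls_lam=np.full(J, np.log(0.15)),
    )
    state._Cs = Cs
    state._evals = evals
    state._evecs = evecs
    for j in range(J):
        _engine._refresh_V_cache(j, evals[0], evecs[0], state.lam[j],
                                 state.Vinv, state.logdetV)
    return state


def _forced(data: DetectionDataset) -> np.ndarray:
    return np.ascontiguousarray(data.detected_any)


def _lp_cache(state: ModelState):
    LP = state.alpha[None, :] + state.X @ state.beta
    L1 = np.logaddexp(0.0, LP)
    return np.ascontiguousarray(LP), np.ascontiguousarray(L1)


def gibbs_update_Z(state: ModelState, data: DetectionDataset) -> ModelState:
    """One exact Gibbs draw of the latent occupancy matrix (in place)."""
    LP, _ = _lp_cache(state)
    _engine.update_Z(state.Z, LP, state.etaD,
                     data.N, data.Y, data.mask, _forced(data),
                     state.spec.prior_only)
    return state


def update_regression_params(state: ModelState, data: DetectionDataset) -> ModelState:
    """One sweep of species blocks, community hypers, and detection updates."""
    spec = state.spec
    LP, L1 = _lp_cache(state)
    _engine.update_species_blocks(
        state.alpha, state.beta, state.Z, state.X, LP, L1, state.mean,
        state.Vinv, state.sig, state.hyp, state.ls_block, spec.prior_only,
        False, 0.0)
    _engine.update_hypers(
        state.alpha, state.beta, state.gam, state.mean, state.sig, state.hyp,
        state.U, state.Vinv, spec.hypermean_scale, spec.sd_scale,
        state.ls_sig, state.ls_siga, False, 0.0)
    _engine.update_detection(
        state.etaD, data.Y, data.N, state.Z, data.mask, state.mup, state.sigp,
        state.ls_eta, state.ls_sigp, spec.detection_scale, spec.sd_scale,
        spec.prior_only, False, 0.0)
    return state


def update_lambda_spike_slab(state: ModelState) -> ModelState:
    """One spike-and-slab Metropolis-Hastings move per covariate."""
    t = state.tree_state[0]
    _engine.update_lambda(state.lam, state.beta, state.mean, state.sig,
                          state._evals[t], state._evecs[t], state.Vinv,
                          state.logdetV, state.spec.spike_mass, state.ls_lam,
                          False, 0.0)
    return state


def update_tree_index(state: ModelState) -> ModelState:
    """Metropolis refresh of the working-tree index."""
    _engine.update_tree(state.tree_state, state.lam, state.beta, state.mean,
                        state.sig, state._evals, state._evecs,
                        state.Vinv, state.logdetV)
    return state


def occupancy_detection_loglik(state: ModelState, data: DetectionDataset) -> float:
    """Joint log-likelihood of (Y, Z): binomial detections over both methods
    plus the Bernoulli occupancy mass of the latent states."""
    from scipy.stats import binom

    p = state.detection_prob()
    if not np.all((p >= 0) & (p <= 1)):
        raise ValueError("detection probabilities escaped [0, 1]")
    psi = state.psi
    Z = state.Z
    ll = float(np.sum(Z * np.log(psi) + (1 - Z) * np.log1p(-psi)))
    for m in range(len(data.methods)):
        for k in range(data.n_species):
            if not data.mask[m, k]:
                continue
            for i in range(data.n_sites):
                n = data.N[m, i]
                if n == 0:
                    continue
                pe = p[m, k] * Z[i, k]
                ll += float(binom.logpmf(data.Y[m, i, k], n, pe))
    if not np.isfinite(ll):
        return -np.inf
    return ll


@dataclass
class BayesFactor:
    """Posterior spike/slab odds for lambda, scaled by the prior odds."""

    value: float
    capped: bool
    n_draws: int

    def __str__(self) -> str:
        return f"BF > {self.n_draws}" if self.capped else f"BF = {self.value:.3g}"


def bayes_factor(lam_draws, prior_mass: float = 0.5) -> BayesFactor:
    """Ratio of positive to zero posterior lambda draws times the prior odds."""
    draws = np.asarray(lam_draws, dtype=float)
    if draws.size == 0:
        raise ValueError("no lambda draws supplied")
    n_pos = int((draws > 0).sum())
    n_zero = int((draws == 0).sum())
    prior_odds = prior_mass / (1.0 - prior_mass)
    if n_zero == 0:
        return BayesFactor(float(draws.size) * prior_odds, True, draws.size)
    return BayesFactor(n_pos / n_zero * prior_odds, False, draws.size)


def gelman_rubin(chains) -> float:
    """Split-chain potential scale reduction factor for one scalar parameter."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of draws")
    n = chains.shape[1]
    if n < 10:
        raise ValueError("need >= 10 draws per chain")
    half = n // 2
    split = np.concatenate([chains[:, :half], chains[:, half: 2 * half]], axis=0)
    m, n = split.shape
    means = split.mean(axis=1)
    W = split.var(axis=1, ddof=1).mean()
    if W <= 0:
        return 1.0
    B = n * means.var(ddof=1)
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


class PosteriorSamples:
    """Retained draws of every model parameter across chains.

    Array shapes lead with (chains, draws); scalar views for diagnostics and
    summaries are exposed through :meth:`scalar_draws`.
    """

    def __init__(self, spec, species, sites, covariate_names, trait_names,
                 arrays, acceptance):
        self.spec = spec
        self.species = list(species)
        self.sites = list(sites)
        self.covariate_names = list(covariate_names)
        self.trait_names = list(trait_names)
        self.arrays = arrays
        self.acceptance = acceptance
        self.rhat = self._compute_rhat()
        self.converged = all(v <= 1.1 for v in self.rhat.values())

    # -- access ------------------------------------------------------------

    def scalar_names(self):
        return list(self._scalar_map().keys())

    def _scalar_map(self):
        out = {}
        cov = self.covariate_names
        arr = self.arrays
        K = len(self.species)
        for k, sp in enumerate(self.species):
            out[f"alpha[{sp}]"] = arr["alpha"][:, :, k]
        for j, cj in enumerate(cov):
            for k, sp in enumerate(self.species):
                out[f"beta[{cj},{sp}]"] = arr["beta"][:, :, j, k]
        P = arr["gam"].shape[-1]
        gnames = ["intercept"] + list(self.trait_names)
        for j, cj in enumerate(cov):
            for t in range(P):
                nm = f"mu[{cj}]" if P == 1 else f"gamma[{cj},{gnames[t]}]"
                out[nm] = arr["gam"][:, :, j, t]
        for j, cj in enumerate(cov):
            out[f"sigma[{cj}]"] = arr["sig"][:, :, j]
            out[f"lambda[{cj}]"] = arr["lam"][:, :, j]
        out["mu_alpha"] = arr["hyp"][:, :, 0]
        out["sigma_alpha"] = arr["hyp"][:, :, 1]
        for m, meth in enumerate(("mist_net", "aru")):
            out[f"mu_p[{meth}]"] = arr["mup"][:, :, m]
            out[f"sigma_p[{meth}]"] = arr["sigp"][:, :, m]
            for k, sp in enumerate(self.species):
                out[f"p_logit[{meth},{sp}]"] = arr["eta"][:, :, m, k]
        return out

    def draws(self, name) -> np.ndarray:
        """All post-burn-in draws of one scalar parameter, chains pooled."""
        return self._scalar_map()[name].ravel()

    def scalar_draws(self, name) -> np.ndarray:
        return self._scalar_map()[name]

    @property
    def z_draws(self) -> np.ndarray:
        """(chains, draws, sites, species) latent occupancy draws."""
        return self.arrays["Z"]

    @property
    def n_draws(self) -> int:
        a = self.arrays["alpha"]
        return a.shape[0] * a.shape[1]

    # -- diagnostics -------------------------------------------------------

    def _compute_rhat(self):
        out = {}
        if self.arrays["alpha"].shape[0] < 2:
            return out
        for name, draws in self._scalar_map().items():
            if name.startswith("p_logit"):
                continue  # per-species detection logits: summarized, not gated
            out[name] = gelman_rubin(draws)
        return out

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values()) if self.rhat else float("nan")

    def bayes_factors(self) -> dict:
        return {
            cj: bayes_factor(self.draws(f"lambda[{cj}]"), self.spec.spike_mass)
            for cj in self.covariate_names
        }

    # -- summaries ---------------------------------------------------------

    def summarize(self) -> pd.DataFrame:
        rows = []
        for name, draws in self._scalar_map().items():
            rows.append(summarize_draws(draws.ravel(), name))
        df = pd.DataFrame(rows).set_index("parameter")
        return df

    def to_long_frame(self, names=None) -> pd.DataFrame:
        smap = self._scalar_map()
        names = list(names) if names is not None else list(smap)
        rows = []
        for name in names:
            d = smap[name]
            for c in range(d.shape[0]):
                for s in range(d.shape[1]):
                    rows.append((c, s, name, d[c, s]))
        return pd.DataFrame(rows, columns=["chain", "draw", "parameter", "value"])


def summarize_draws(draws, name="param") -> dict:
    """Posterior mean, central 95% interval, and a sign-support flag."""
    draws = np.asarray(draws, dtype=float)
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return {
        "parameter": name,
        "mean": float(draws.mean()),
        "q2.5": float(lo),
        "q97.5": float(hi),
        "support": bool(lo > 0) or bool(hi < 0),
    }


def summarize(samples: PosteriorSamples) -> pd.DataFrame:
    return samples.summarize()


def fit_pom(data: DetectionDataset, covariates: SiteCovariates, trees,
            traits: TraitMatrix | None = None,
            spec: CommunityModelSpec | None = None) -> PosteriorSamples:
    """Fit the community occupancy model by Metropolis-within-Gibbs MCMC.

    ``trees`` is a sequence of :class:`PhyloTree` or precomputed
    :class:`PhyloCorrelation`; with more than one, the working tree is
    resampled each iteration. Returns retained, thinned draws with split
    R-hat diagnostics; a run with any R-hat above 1.1 is flagged (warning,
    not an error).
    """
    spec = spec or CommunityModelSpec()
    X, Cs, evals, evecs, U = _prepare_inputs(data, covariates, trees, traits, spec)
    K, I = data.n_species, data.n_sites
    J, M = X.shape[1], len(data.methods)
    P = U.shape[1]
    S = spec.n_retained
    forced = _forced(data)

    names = ("alpha", "beta", "gam", "sig", "hyp", "lam", "eta",
             "mup", "sigp", "Z", "tree")
    shapes = dict(alpha=(S, K), beta=(S, J, K), gam=(S, J, P), sig=(S, J),
                  hyp=(S, 2), lam=(S, J), eta=(S, M, K), mup=(S, M),
                  sigp=(S, M), Z=(S, I, K), tree=(S,))
    chains = {nm: [] for nm in names}
    acceptance = []
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
             for s in np.random.SeedSequence(spec.seed).spawn(spec.chains)]
    for c in range(spec.chains):
        outs = {nm: np.zeros(shapes[nm],
                             dtype=np.int8 if nm == "Z"
                             else (np.int64 if nm == "tree" else float))
                for nm in names}
        acc = np.zeros(2)
        _engine.run_chain(
            seeds[c],
            np.ascontiguousarray(data.Y), np.ascontiguousarray(data.N),
            np.ascontiguousarray(data.mask), forced,
            np.ascontiguousarray(X), evals, evecs, U,
            spec.iterations, spec.burn_in, spec.thinning,
            spec.hypermean_scale, spec.sd_scale, spec.detection_scale,
            spec.spike_mass, spec.prior_only,
            outs["alpha"], outs["beta"], outs["gam"], outs["sig"],
            outs["hyp"], outs["lam"], outs["eta"], outs["mup"],
            outs["sigp"], outs["Z"], outs["tree"], acc)
        for nm in names:
            chains[nm].append(outs[nm])
        acceptance.append({"species_blocks": acc[0], "detection": acc[1]})

    arrays = {nm: np.stack(chains[nm]) for nm in names}
    samples = PosteriorSamples(
        spec, data.species, data.sites, spec.covariates,
        spec.trait_names if spec.include_traits else (),
        arrays, acceptance)
    if not samples.converged:
        warnings.warn(
            f"model not converged: max R-hat {samples.max_rhat:.3f} > 1.1",
            RuntimeWarning,
        )
    return samples
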