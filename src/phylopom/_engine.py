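"""Numba kernels for the Metropolis-within-Gibbs community occupancy sampler.

Every update kernel operates in place on plain float64/int64 arrays so the
same code backs both the public single-step operations and the compiled
full-chain driver. Randomness comes from numba's np.random state, seeded
once per chain via :func:`seed_rng`.

State layout (K species, I sites, J covariates, M methods, P mean-model
columns, nT trees):

- ``alpha`` (K,), ``beta`` (J, K): species intercepts and slopes
- ``gam`` (J, P): per-covariate mean-model coefficients (P = 1 without traits)
- ``mean`` (J, K): current prior means ``U @ gam[j]``
- ``sig`` (J,): community SDs; ``hyp`` = [mu_alpha, sig_alpha]
- ``lam`` (J,): Pagel's lambda per covariate, exactly 0.0 in the spike
- ``etaD`` (M, K): detection logits; ``mup``/``sigp`` (M,): their hypers
- ``Z`` (I, K) int64 latent occupancy; ``tree_state`` int64[1]
- ``Vinv`` (J, K, K), ``logdetV`` (J,): cached inverse / log-determinant of
  ``lam_j * C + (1 - lam_j) * I`` for the current tree
"""
from __future__ import annotations

import numpy as np
from numba import njit

LOG2PI = float(np.log(2.0 * np.pi))
LS_MIN = -7.0   # clamp for adapted log proposal scales
LS_MAX = 2.0


@njit(cache=True, inline="always")
def _clamp_ls(x):
    if x < LS_MIN:
        return LS_MIN
    if x > LS_MAX:
        return LS_MAX
    return x


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _log1pexp(x):
    if x > 35.0:
        return x
    if x < -35.0:
        return np.exp(x)
    return np.log1p(np.exp(x))


@njit(cache=True, inline="always")
def _sigmoid(x):
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


SIG_MIN = 1e-3
SIG_MAX = 1e3


@njit(cache=True)
def _lam_cov(C, lam):
    K = C.shape[0]
    V = lam * C + (1.0 - lam + 1e-10) * np.eye(K)
    return V


@njit(cache=True)
def _refresh_V_cache(j, evals, evecs, lam_j, Vinv, logdetV):
    """Refresh inverse and log-det of lam*C + (1-lam)*I from C's eigensystem."""
    K = evals.shape[0]
    if lam_j == 0.0:
        Vinv[j] = np.eye(K)
        logdetV[j] = 0.0
    else:
        s = 0.0
        scaled = np.empty((K, K))
        for a in range(K):
            d = lam_j * evals[a] + (1.0 - lam_j) + 1e-10
            s += np.log(d)
            inv = 1.0 / d
            for b in range(K):
                scaled[b, a] = evecs[b, a] * inv
        Vinv[j] = scaled @ evecs.T
        logdetV[j] = s


@njit(cache=True)
def _beta_mvn_ll_w(w, evals, lam, sig):
    """MVN log-density in the eigenbasis: w = Q.T @ resid."""
    K = w.shape[0]
    q = 0.0
    logdet = 0.0
    if lam == 0.0:
        for a in range(K):
            q += w[a] * w[a]
    else:
        for a in range(K):
            d = lam * evals[a] + (1.0 - lam) + 1e-10
            q += w[a] * w[a] / d
            logdet += np.log(d)
    return -0.5 * (K * LOG2PI + 2.0 * K * np.log(sig) + logdet + q / (sig * sig))


@njit(cache=True)
def _beta_mvn_ll(resid, C, lam, sig):
    """MVN log-density of slope residuals under lambda, sigma (direct form)."""
    K = resid.shape[0]
    if lam == 0.0:
        q = 0.0
        for a in range(K):
            q += resid[a] * resid[a]
        logdet = 0.0
    else:
        V = _lam_cov(C, lam)
        L = np.linalg.cholesky(V)
        x = np.linalg.solve(L, resid)
        q = 0.0
        logdet = 0.0
        for a in range(K):
            q += x[a] * x[a]
            logdet += 2.0 * np.log(L[a, a])
    return -0.5 * (K * LOG2PI + 2.0 * K * np.log(sig) + logdet + q / (sig * sig))


@njit(cache=True)
def update_Z(Z, LP, etaD, N, Y, mask, forced, prior_only):
    """Gibbs update of the latent occupancy states.

    ``LP`` is the cached occupancy linear predictor (sites x species).
    """
    I, K = Z.shape
    M = etaD.shape[0]
    # qtab[m, k, n] = (1 - p[m, k]) ** n: probability of n non-detections
    maxn = 0
    for m in range(M):
        for i in range(I):
            if N[m, i] > maxn:
                maxn = N[m, i]
    qtab = np.ones((M, K, maxn + 1))
    if not prior_only:
        for m in range(M):
            for k in range(K):
                if mask[m, k]:
                    p = _sigmoid(etaD[m, k])
                    for n in range(1, maxn + 1):
                        qtab[m, k, n] = qtab[m, k, n - 1] * (1.0 - p)
    for i in range(I):
        for k in range(K):
            if forced[i, k] and not prior_only:
                Z[i, k] = 1
                continue
            psi = _sigmoid(LP[i, k])
            if prior_only:
                Z[i, k] = 1 if np.random.random() < psi else 0
            else:
                q = 1.0
                for m in range(M):
                    if mask[m, k]:
                        q *= qtab[m, k, N[m, i]]
                pz = psi * q / (psi * q + 1.0 - psi)
                Z[i, k] = 1 if np.random.random() < pz else 0


@njit(cache=True)
def update_species_blocks(alpha, beta, Z, X, LP, L1, mean, Vinv, sig, hyp,
                          ls_block, prior_only, adapt, adapt_rate):
    """Adaptive random-walk Metropolis on each species' (alpha, beta) block.

    The slope prior enters through its exact full conditional: for covariate
    j and species k, beta[j, k] | rest is Normal with precision
    Vinv[j][k, k] / sig_j^2.
    """
    K = alpha.shape[0]
    I, J = X.shape
    acc = 0.0
    # g[j] = Vinv[j] @ (beta[j] - mean[j]), kept current incrementally
    g = np.empty((J, K))
    for j in range(J):
        for k in range(K):
            s = 0.0
            for l in range(K):
                s += Vinv[j, k, l] * (beta[j, l] - mean[j, l])
            g[j, k] = s
    if prior_only:
        # likelihood disabled: the species-block full conditional is the
        # prior itself, so draw it exactly (Gibbs) instead of random-walking
        for k in range(K):
            alpha[k] = hyp[0] + hyp[1] * np.random.normal()
            for j in range(J):
                vkk = Vinv[j, k, k]
                s = g[j, k] - vkk * (beta[j, k] - mean[j, k])
                cmean = mean[j, k] - s / vkk
                csd = sig[j] / np.sqrt(vkk)
                new_b = cmean + csd * np.random.normal()
                db = new_b - beta[j, k]
                beta[j, k] = new_b
                for l in range(K):
                    g[j, l] += Vinv[j, l, k] * db
            for i in range(I):
                lin = alpha[k]
                for j in range(J):
                    lin += X[i, j] * beta[j, k]
                LP[i, k] = lin
        return 1.0
    for k in range(K):
        step = np.exp(ls_block[k])
        da = step * np.random.normal()
        db = np.empty(J)
        for j in range(J):
            db[j] = step * np.random.normal()
        dll = 0.0
        lin_new = np.empty(I)
        l1_new = np.empty(I)
        if not prior_only:
            for i in range(I):
                d = da
                for j in range(J):
                    d += X[i, j] * db[j]
                lin_new[i] = LP[i, k] + d
                l1_new[i] = _log1pexp(lin_new[i])
                dll += Z[i, k] * d - l1_new[i] + L1[i, k]
        dlp = -((alpha[k] + da - hyp[0]) ** 2
                - (alpha[k] - hyp[0]) ** 2) / (2.0 * hyp[1] ** 2)
        for j in range(J):
            vkk = Vinv[j, k, k]
            s = g[j, k] - vkk * (beta[j, k] - mean[j, k])
            cmean = mean[j, k] - s / vkk
            cvar = sig[j] ** 2 / vkk
            bn = beta[j, k] + db[j]
            dlp += -((bn - cmean) ** 2 - (beta[j, k] - cmean) ** 2) / (2.0 * cvar)
        a_prob = np.exp(min(0.0, dll + dlp))
        if np.random.random() < a_prob:
            alpha[k] += da
            for j in range(J):
                beta[j, k] += db[j]
                for l in range(K):
                    g[j, l] += Vinv[j, l, k] * db[j]
            for i in range(I):
                LP[i, k] = lin_new[i]
                L1[i, k] = l1_new[i]
        if adapt:
            ls_block[k] = _clamp_ls(ls_block[k] + adapt_rate * (a_prob - 0.3))
        acc += a_prob
    return acc / K


@njit(cache=True)
def update_hypers(alpha, beta, gam, mean, sig, hyp, U, Vinv,
                  hs, ss, ls_sig, ls_siga, adapt, adapt_rate):
    """Community-level updates: conjugate means, MH log-walks for SDs."""
    K = alpha.shape[0]
    J, P = gam.shape

    # mu_alpha: conjugate normal given alpha and sig_alpha
    post_var = 1.0 / (K / hyp[1] ** 2 + 1.0 / hs ** 2)
    post_mean = post_var * np.sum(alpha) / hyp[1] ** 2
    hyp[0] = post_mean + np.sqrt(post_var) * np.random.normal()

    # sig_alpha: random walk on log sigma, half-normal(ss) prior
    cur = hyp[1]
    prop = cur * np.exp(np.exp(ls_siga[0]) * np.random.normal())
    if SIG_MIN < prop < SIG_MAX:
        q_cur = 0.0
        for k in range(K):
            q_cur += (alpha[k] - hyp[0]) ** 2
        dl = (-K * (np.log(prop) - np.log(cur))
              - 0.5 * q_cur * (1.0 / prop ** 2 - 1.0 / cur ** 2)
              - (prop ** 2 - cur ** 2) / (2.0 * ss ** 2)
              + (np.log(prop) - np.log(cur)))
        a_prob = np.exp(min(0.0, dl))
        if np.random.random() < a_prob:
            hyp[1] = prop
        if adapt:
            ls_siga[0] = _clamp_ls(ls_siga[0] + adapt_rate * (a_prob - 0.35))

    for j in range(J):
        # gam[j]: conjugate MVN given beta[j], sig[j], Vinv[j]
        s2 = sig[j] ** 2
        A = (U.T @ Vinv[j] @ U) / s2 + np.eye(P) / hs ** 2
        b = (U.T @ Vinv[j] @ beta[j]) / s2
        gmean = np.linalg.solve(A, b)
        La = np.linalg.cholesky(A)
        z = np.empty(P)
        for t in range(P):
            z[t] = np.random.normal()
        dev = np.linalg.solve(La.T, z)
        for t in range(P):
            gam[j, t] = gmean[t] + dev[t]
        newmean = U @ gam[j]
        for k in range(K):
            mean[j, k] = newmean[k]

        # sig[j]: log random walk
        r = beta[j] - mean[j]
        q = r @ (Vinv[j] @ r)
        cur = sig[j]
        prop = cur * np.exp(np.exp(ls_sig[j]) * np.random.normal())
        if SIG_MIN < prop < SIG_MAX:
            dl = (-K * (np.log(prop) - np.log(cur))
                  - 0.5 * q * (1.0 / prop ** 2 - 1.0 / cur ** 2)
                  - (prop ** 2 - cur ** 2) / (2.0 * ss ** 2)
                  + (np.log(prop) - np.log(cur)))
            a_prob = np.exp(min(0.0, dl))
            if np.random.random() < a_prob:
                sig[j] = prop
            if adapt:
                ls_sig[j] = _clamp_ls(ls_sig[j] + adapt_rate * (a_prob - 0.35))


@njit(cache=True)
def update_detection(etaD, Y, N, Z, mask, mup, sigp, ls_eta, ls_sigp,
                     ds, ss, prior_only, adapt, adapt_rate):
    """Detection logits (random walk) and their method-level hypers."""
    M, K = etaD.shape
    I = Z.shape[0]
    acc = 0.0
    n_in = 0
    for m in range(M):
        for k in range(K):
            if not mask[m, k] or prior_only:
                # prior draw: exact full conditional without a likelihood
                etaD[m, k] = mup[m] + sigp[m] * np.random.normal()
                continue
            n_in += 1
            cur = etaD[m, k]
            prop = cur + np.exp(ls_eta[m, k]) * np.random.normal()
            dll = 0.0
            if not prior_only:
                # binomial likelihood depends on (sum Y, sum N) over occupied sites
                sumy = 0
                sumn = 0
                for i in range(I):
                    if Z[i, k] == 1:
                        sumy += Y[m, i, k]
                        sumn += N[m, i]
                dll = sumy * (prop - cur) - sumn * (_log1pexp(prop) - _log1pexp(cur))
            dlp = -((prop - mup[m]) ** 2 - (cur - mup[m]) ** 2) / (2.0 * sigp[m] ** 2)
            a_prob = np.exp(min(0.0, dll + dlp))
            if np.random.random() < a_prob:
                etaD[m, k] = prop
            if adapt:
                ls_eta[m, k] = _clamp_ls(ls_eta[m, k] + adapt_rate * (a_prob - 0.4))
            acc += a_prob

        # method-level hypers over masked-in species
        Km = 0
        ssum = 0.0
        for k in range(K):
            if mask[m, k]:
                Km += 1
                ssum += etaD[m, k]
        if Km == 0:
            continue
        post_var = 1.0 / (Km / sigp[m] ** 2 + 1.0 / ds ** 2)
        post_mean = post_var * ssum / sigp[m] ** 2
        mup[m] = post_mean + np.sqrt(post_var) * np.random.normal()

        q = 0.0
        for k in range(K):
            if mask[m, k]:
                q += (etaD[m, k] - mup[m]) ** 2
        cur = sigp[m]
        prop = cur * np.exp(np.exp(ls_sigp[m]) * np.random.normal())
        if SIG_MIN < prop < SIG_MAX:
            dl = (-Km * (np.log(prop) - np.log(cur))
                  - 0.5 * q * (1.0 / prop ** 2 - 1.0 / cur ** 2)
                  - (prop ** 2 - cur ** 2) / (2.0 * ss ** 2)
                  + (np.log(prop) - np.log(cur)))
            a_prob = np.exp(min(0.0, dl))
            if np.random.random() < a_prob:
                sigp[m] = prop
            if adapt:
                ls_sigp[m] = _clamp_ls(ls_sigp[m] + adapt_rate * (a_prob - 0.35))
    return acc / max(n_in, 1)


@njit(cache=True)
def update_lambda(lam, beta, mean, sig, evals, evecs, Vinv, logdetV,
                  spike_mass, ls_lam, adapt, adapt_rate):
    """Spike-and-slab Metropolis-Hastings move for each covariate's lambda.

    The target over lambda is the mixture prior (point mass ``spike_mass``
    at 0, uniform slab on (0, 1]) times the MVN density of the current
    slopes. From the spike the only move proposes a fresh slab value; from
    the slab the chain proposes a jump to 0 with probability 1/2 and a
    reflected random walk otherwise, making the chain irreducible across
    both components.
    """
    J, K = beta.shape
    w = spike_mass
    acc = 0.0
    for j in range(J):
        r = beta[j] - mean[j]
        wv = evecs.T @ r
        cur = lam[j]
        if cur == 0.0:
            prop = np.random.random()
            if prop == 0.0:
                prop = 1e-12
            loga = (np.log((1.0 - w) * 0.5 / w)
                    + _beta_mvn_ll_w(wv, evals, prop, sig[j])
                    - _beta_mvn_ll_w(wv, evals, 0.0, sig[j]))
            a_prob = np.exp(min(0.0, loga))
            if np.random.random() < a_prob:
                lam[j] = prop
                _refresh_V_cache(j, evals, evecs, prop, Vinv, logdetV)
        else:
            if np.random.random() < 0.5:
                loga = (np.log(w / ((1.0 - w) * 0.5))
                        + _beta_mvn_ll_w(wv, evals, 0.0, sig[j])
                        - _beta_mvn_ll_w(wv, evals, cur, sig[j]))
                a_prob = np.exp(min(0.0, loga))
                if np.random.random() < a_prob:
                    lam[j] = 0.0
                    _refresh_V_cache(j, evals, evecs, 0.0, Vinv, logdetV)
            else:
                prop = cur + np.exp(ls_lam[j]) * np.random.normal()
                # exact reflection into [0, 1]: fold by period 2
                prop = np.abs(prop) % 2.0
                if prop > 1.0:
                    prop = 2.0 - prop
                if prop <= 0.0:
                    prop = 1e-12
                loga = (_beta_mvn_ll_w(wv, evals, prop, sig[j])
                        - _beta_mvn_ll_w(wv, evals, cur, sig[j]))
                a_prob = np.exp(min(0.0, loga))
                if np.random.random() < a_prob:
                    lam[j] = prop
                    _refresh_V_cache(j, evals, evecs, prop, Vinv, logdetV)
                if adapt:
                    ls_lam[j] = _clamp_ls(ls_lam[j] + adapt_rate * (a_prob - 0.4))
        acc += 1.0
    return acc


@njit(cache=True)
def update_tree(tree_state, lam, beta, mean, sig, evals_all, evecs_all,
                Vinv, logdetV):
    """Uniform tree proposal accepted by the slope-prior Metropolis ratio."""
    nT = evals_all.shape[0]
    if nT == 1:
        tree_state[0] = 0
        return
    cur = tree_state[0]
    prop = np.random.randint(0, nT)
    if prop == cur:
        return
    J = beta.shape[0]
    dl = 0.0
    for j in range(J):
        if lam[j] == 0.0:
            continue  # identity covariance: tree does not enter
        r = beta[j] - mean[j]
        w_cur = evecs_all[cur].T @ r
        w_prop = evecs_all[prop].T @ r
        dl += (_beta_mvn_ll_w(w_prop, evals_all[prop], lam[j], sig[j])
               - _beta_mvn_ll_w(w_cur, evals_all[cur], lam[j], sig[j]))
    if np.log(np.random.random() + 1e-300) < dl:
        tree_state[0] = prop
        for j in range(J):
            _refresh_V_cache(j, evals_all[prop], evecs_all[prop], lam[j],
                             Vinv, logdetV)


@njit(cache=True)
def run_chain(seed, Y, N, mask, forced, X, evals_all, evecs_all, U,
              n_iter, burn_in, thin,
              hs, ss, ds, spike_mass, prior_only,
              out_alpha, out_beta, out_gam, out_sig, out_hyp,
              out_lam, out_eta, out_mup, out_sigp, out_Z, out_tree,
              acc_out):
    """Run one MCMC chain; fills the ``out_*`` arrays with retained draws.

    Sweep order per iteration: Z -> species blocks -> community hypers ->
    detection -> lambda -> tree. Adaptation of proposal scales stops at the
    end of burn-in.
    """
    seed_rng(seed)
    I, J = X.shape
    K = U.shape[0]
    P = U.shape[1]
    M = mask.shape[0]
    nT = evals_all.shape[0]

    alpha = np.empty(K)
    beta = np.empty((J, K))
    for k in range(K):
        alpha[k] = 0.3 * np.random.normal()
        for j in range(J):
            beta[j, k] = 0.3 * np.random.normal()
    gam = np.zeros((J, P))
    mean = np.zeros((J, K))
    sig = np.ones(J)
    hyp = np.array([0.0, 1.0])
    lam = np.full(J, 0.5)
    etaD = np.zeros((M, K))
    mup = np.zeros(M)
    sigp = np.ones(M)
    Z = np.zeros((I, K), dtype=np.int64)
    for i in range(I):
        for k in range(K):
            if forced[i, k] and not prior_only:
                Z[i, k] = 1
            elif np.random.random() < 0.5:
                Z[i, k] = 1
    tree_state = np.zeros(1, dtype=np.int64)
    tree_state[0] = np.random.randint(0, nT)

    LP = np.empty((I, K))
    L1 = np.empty((I, K))
    for i in range(I):
        for k in range(K):
            lin = alpha[k]
            for j in range(J):
                lin += X[i, j] * beta[j, k]
            LP[i, k] = lin
            L1[i, k] = _log1pexp(lin)

    Vinv = np.zeros((J, K, K))
    logdetV = np.zeros(J)
    for j in range(J):
        _refresh_V_cache(j, evals_all[tree_state[0]], evecs_all[tree_state[0]],
                         lam[j], Vinv, logdetV)

    ls_block = np.full(K, np.log(0.3))
    ls_eta = np.full((M, K), np.log(0.5))
    ls_sig = np.full(J, np.log(0.4))
    ls_siga = np.full(1, np.log(0.4))
    ls_sigp = np.full(M, np.log(0.4))
    ls_lam = np.full(J, np.log(0.15))

    s = 0
    acc_block = 0.0
    acc_det = 0.0
    for it in range(n_iter):
        adapt = it < burn_in
        adapt_rate = 1.0 / (1.0 + it * 0.01) ** 0.6

        update_Z(Z, LP, etaD, N, Y, mask, forced, prior_only)
        acc_block += update_species_blocks(
            alpha, beta, Z, X, LP, L1, mean, Vinv, sig, hyp,
            ls_block, prior_only, adapt, adapt_rate)
        update_hypers(alpha, beta, gam, mean, sig, hyp, U, Vinv,
                      hs, ss, ls_sig, ls_siga, adapt, adapt_rate)
        acc_det += update_detection(etaD, Y, N, Z, mask, mup, sigp,
                                    ls_eta, ls_sigp, ds, ss, prior_only,
                                    adapt, adapt_rate)
        update_lambda(lam, beta, mean, sig, evals_all[tree_state[0]],
                      evecs_all[tree_state[0]], Vinv, logdetV, spike_mass,
                      ls_lam, adapt, adapt_rate)
        update_tree(tree_state, lam, beta, mean, sig, evals_all, evecs_all,
                    Vinv, logdetV)

        if it >= burn_in and (it - burn_in) % thin == 0:
            out_alpha[s] = alpha
            out_beta[s] = beta
            out_gam[s] = gam
            out_sig[s] = sig
            out_hyp[s] = hyp
            out_lam[s] = lam
            out_eta[s] = etaD
            out_mup[s] = mup
            out_sigp[s] = sigp
            for i in range(I):
                for k in range(K):
                    out_Z[s, i, k] = Z[i, k]
            out_tree[s] = tree_state[0]
            s += 1

    acc_out[0] = acc_block / n_iter
    acc_out[1] = acc_det / n_iter
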