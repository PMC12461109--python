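import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, kstest, ks_2samp, norm

import phylopom as pp
from phylopom.model import CommunityModelSpec, summarize_draws


def make_covariates(n_sites, seed=0):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {
            "elevation": np.linspace(400, 1700, max(n_sites, 2))[:n_sites],
            "temperature": rng.normal(size=n_sites),
            "precipitation": rng.normal(size=n_sites),
            "forest_cover": rng.normal(size=n_sites),
        },
        index=pd.Index([f"s{i}" for i in range(n_sites)], name="site"),
    )
    cov = pp.SiteCovariates(frame)
    if n_sites == 1:  # degenerate helper for single-site unit tests
        return pp.SiteCovariates(frame, standardized=tuple(frame.columns))
    return cov.standardize()


def single_species_dataset(Y, N, site_names):
    M, I = N.shape
    mask = np.array([[True], [False]])
    return pp.DetectionDataset(["sp1"], site_names, Y, N, mask)


class TestSpec:
    def test_invariants(self):
        with pytest.raises(ValueError):
            CommunityModelSpec(spike_mass=0.0)
        with pytest.raises(ValueError):
            CommunityModelSpec(burn_in=100, iterations=100)
        with pytest.raises(ValueError):
            CommunityModelSpec(thinning=0)

    def test_draw_count(self, study14):
        spec = CommunityModelSpec(chains=2, iterations=400, burn_in=200,
                                  thinning=10, seed=0)
        cov = study14.covariates.standardize()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = pp.fit_pom(study14.detections, cov, study14.trees[:1], spec=spec)
        assert s.arrays["alpha"].shape[:2] == (2, 20)
        assert s.n_draws == 2 * (400 - 200) // 10


class TestOccupancyDetectionLoglik:
    def _state(self, data, cov, psi_logit, eta, Z):
        spec = CommunityModelSpec()
        C = pp.PhyloCorrelation(data.species, np.eye(data.n_species))
        state = pp.init_state(data, cov, [C], spec=spec, seed=0)
        state.alpha[:] = psi_logit
        state.beta[:] = 0.0
        state.etaD[:] = eta
        state.Z[:] = Z
        return state

    def test_single_site_binomial_term(self):
        # Z=1, p=0.5, N=2, Y=1: detection term log(2 * 0.5 * 0.5)
        data = single_species_dataset(
            np.array([[[1]], [[0]]]), np.array([[2], [0]]), ["s0"])
        cov = make_covariates(1)
        state = self._state(data, cov, psi_logit=0.0, eta=0.0, Z=1)
        ll = pp.occupancy_detection_loglik(state, data)
        assert ll == pytest.approx(np.log(0.5) + np.log(0.5))  # binom + Bern(Z)

    def test_unoccupied_zero_detection_term(self):
        data = single_species_dataset(
            np.array([[[0]], [[0]]]), np.array([[2], [0]]), ["s0"])
        cov = make_covariates(1)
        state = self._state(data, cov, psi_logit=0.0, eta=0.0, Z=0)
        ll = pp.occupancy_detection_loglik(state, data)
        assert ll == pytest.approx(np.log(0.5))  # only the Bernoulli(Z) mass

    def test_matches_direct_enumeration_of_joint(self):
        """Summing exp(loglik) over all Z configurations recovers the
        marginal likelihood from brute-force enumeration."""
        rng = np.random.default_rng(0)
        K, I = 2, 3
        Y = np.zeros((2, I, K), dtype=int)
        Y[0] = rng.integers(0, 2, size=(I, K))
        N = np.array([[2, 1, 2], [0, 0, 0]])
        Y[0, 1, :] = np.minimum(Y[0, 1, :], 1)
        mask = np.array([[True, True], [False, False]])
        data = pp.DetectionDataset(["a", "b"], ["s0", "s1", "s2"], Y, N, mask)
        cov = make_covariates(I)
        C = pp.PhyloCorrelation(["a", "b"], np.eye(2))
        state = pp.init_state(data, cov, [C], seed=1)
        state.alpha[:] = rng.normal(size=K)
        state.beta[:] = rng.normal(size=(3, K)) * 0.5
        state.etaD[:] = rng.normal(size=(2, K))

        psi = state.psi
        p = state.detection_prob()

        def joint(zconf):
            Zm = np.array(zconf).reshape(I, K)
            state.Z[:] = Zm
            return np.exp(pp.occupancy_detection_loglik(state, data))

        # brute-force marginal: sum over 2^(I*K) configurations
        total = sum(joint(z) for z in itertools.product([0, 1], repeat=I * K))
        direct = 1.0
        for i in range(I):
            for k in range(K):
                like1 = psi[i, k] * binom.pmf(Y[0, i, k], N[0, i], p[0, k])
                like0 = (1 - psi[i, k]) * (1.0 if Y[0, i, k] == 0 else 0.0)
                direct *= like1 + like0
        assert total == pytest.approx(direct, rel=1e-10)

    def test_bad_probability_raises(self):
        data = single_species_dataset(
            np.array([[[1]], [[0]]]), np.array([[2], [0]]), ["s0"])
        cov = make_covariates(1)
        state = self._state(data, cov, 0.0, 0.0, 1)
        state.etaD = state.etaD + np.nan
        with pytest.raises(ValueError):
            pp.occupancy_detection_loglik(state, data)


class TestGibbsUpdateZ:
    def _setup(self, Y, N, psi_logit=0.0, eta=0.0, prior_only=False):
        data = single_species_dataset(Y, N, [f"s{i}" for i in range(N.shape[1])])
        cov = make_covariates(N.shape[1])
        spec = CommunityModelSpec(prior_only=prior_only)
        C = pp.PhyloCorrelation(["sp1"], np.eye(1))
        state = pp.init_state(data, cov, [C], spec=spec, seed=3)
        state.alpha[:] = psi_logit
        state.beta[:] = 0.0
        state.etaD[:] = eta
        return state, data

    def test_detection_forces_occupancy(self):
        state, data = self._setup(np.array([[[2]], [[0]]]), np.array([[2], [0]]))
        for _ in range(50):
            pp.gibbs_update_Z(state, data)
            assert state.Z[0, 0] == 1

    def test_no_surveys_gives_psi(self):
        state, data = self._setup(np.array([[[0]], [[0]]]), np.array([[1], [0]]))
        # make the single surveyed site unsurveyed-like via N=0 elsewhere is
        # impossible (validation), so use p=0 instead: q=1 and P(Z=1)=psi
        state.etaD[:] = -40.0
        hits = sum(pp.gibbs_update_Z(state, data).Z[0, 0] for _ in range(4000))
        assert hits / 4000 == pytest.approx(0.5, abs=0.03)

    def test_hand_computed_conditional(self):
        # psi=0.5, p=0.5, N=2, Y=0: P(Z=1|.) = 0.5*0.25/(0.5*0.25+0.5) = 0.2
        state, data = self._setup(np.array([[[0]], [[0]]]), np.array([[2], [0]]))
        hits = sum(pp.gibbs_update_Z(state, data).Z[0, 0] for _ in range(20000))
        se = np.sqrt(0.2 * 0.8 / 20000)
        assert hits / 20000 == pytest.approx(0.2, abs=4 * se)


class TestEnumerationOracle:
    def test_z_posterior_matches_enumeration(self):
        """2 species x 3 sites: cell-wise P(Z=1 | Y) from repeated Gibbs
        draws matches exact enumeration over all 64 Z configurations."""
        rng = np.random.default_rng(7)
        K, I = 2, 3
        Y = np.array([[[1, 0], [0, 0], [2, 1]], [[0, 0], [0, 0], [0, 0]]])
        N = np.array([[2, 2, 2], [0, 0, 0]])
        mask = np.array([[True, True], [False, False]])
        data = pp.DetectionDataset(["a", "b"], ["s0", "s1", "s2"], Y, N, mask)
        cov = make_covariates(I, seed=5)
        C = pp.PhyloCorrelation(["a", "b"], np.eye(2))
        state = pp.init_state(data, cov, [C], seed=11)
        state.alpha[:] = [0.3, -0.4]
        state.beta[:] = rng.normal(size=(3, K)) * 0.4
        state.etaD[0] = [0.2, -0.3]

        psi = state.psi
        p = state.detection_prob()

        # exact enumeration over all Z configurations
        weights = {}
        for zconf in itertools.product([0, 1], repeat=I * K):
            Zm = np.array(zconf).reshape(I, K)
            w = 1.0
            for i in range(I):
                for k in range(K):
                    pe = p[0, k] * Zm[i, k]
                    w *= binom.pmf(Y[0, i, k], N[0, i], pe)
                    w *= psi[i, k] if Zm[i, k] else 1 - psi[i, k]
            weights[zconf] = w
        total = sum(weights.values())
        exact = np.zeros((I, K))
        for zconf, w in weights.items():
            exact += np.array(zconf).reshape(I, K) * w / total

        n_draws = 40000
        freq = np.zeros((I, K))
        for _ in range(n_draws):
            pp.gibbs_update_Z(state, data)
            freq += state.Z
        freq /= n_draws
        se = np.sqrt(exact * (1 - exact) / n_draws) + 1e-12
        assert (np.abs(freq - exact) <= 3 * se + 1e-9).all()


class TestUpdateTreeIndex:
    def _state(self, trees, seed=0):
        study = pp.study_mimic(3, n_sites=14, n_trees=1)
        cov = study.covariates.standardize()
        return pp.init_state(study.detections, cov, trees, seed=seed), study

    def test_single_tree_identity(self):
        study = pp.study_mimic(3, n_sites=14, n_trees=1)
        cov = study.covariates.standardize()
        state = pp.init_state(study.detections, cov, study.trees, seed=0)
        for _ in range(100):
            pp.update_tree_index(state)
            assert state.tree_state[0] == 0

    def test_two_identical_trees_symmetric(self):
        study = pp.study_mimic(3, n_sites=14, n_trees=1)
        cov = study.covariates.standardize()
        tree = study.trees[0]
        state = pp.init_state(study.detections, cov, [tree, tree], seed=1)
        state.lam[:] = 0.7
        counts = np.zeros(2)
        for _ in range(10000):
            pp.update_tree_index(state)
            counts[state.tree_state[0]] += 1
        assert counts[0] / counts.sum() == pytest.approx(0.5, abs=0.05)

    def test_discriminates_generating_tree(self):
        """beta simulated under tree A's correlation: index favors A."""
        study = pp.study_mimic(3, n_sites=14, n_trees=1)
        cov = study.covariates.standardize()
        species = study.detections.species
        tree_a = study.trees[0]
        tree_b = pp.simulate_tree(27, seed=77, labels=species)
        Ca = pp.correlation_from_tree(tree_a, species)
        state = pp.init_state(study.detections, cov, [tree_a, tree_b], seed=2)
        rng = np.random.default_rng(0)
        L = np.linalg.cholesky(Ca.matrix + 1e-10 * np.eye(27))
        for j in range(3):
            state.beta[j] = L @ rng.standard_normal(27)
        state.lam[:] = 1.0
        state.sig[:] = 1.0
        counts = np.zeros(2)
        for _ in range(10000):
            pp.update_tree_index(state)
            counts[state.tree_state[0]] += 1
        assert counts[0] > counts[1]


class TestBayesFactor:
    def test_even_split(self):
        draws = np.array([0.0] * 5000 + [0.5] * 5000)
        assert pp.bayes_factor(draws).value == pytest.approx(1.0)

    def test_headline_arithmetic(self):
        draws = np.array([0.0] * 862 + [0.5] * 9138)
        assert pp.bayes_factor(draws).value == pytest.approx(10.6, abs=0.01)

    def test_all_positive_capped(self):
        bf = pp.bayes_factor(np.full(10000, 0.3))
        assert bf.capped
        assert "10000" in str(bf)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            pp.bayes_factor([])

    def test_prior_odds_scaling(self):
        draws = np.array([0.0] * 5000 + [0.5] * 5000)
        assert pp.bayes_factor(draws, prior_mass=0.75).value == pytest.approx(3.0)


class TestGelmanRubin:
    def test_same_distribution(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(2, 5000))
        assert pp.gelman_rubin(chains) < 1.05

    def test_shifted_chain(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(2, 5000))
        chains[1] += 5.0
        assert pp.gelman_rubin(chains) > 1.1

    def test_constant_chains(self):
        assert pp.gelman_rubin(np.ones((3, 100))) == 1.0

    def test_agrees_with_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(4, 500)) + rng.normal(size=(4, 1)) * 0.2
        ours = pp.gelman_rubin(chains)
        theirs = float(np.asarray(az.rhat(chains, method="split")))
        assert ours == pytest.approx(theirs, abs=0.01)


class TestSummaries:
    def test_mean(self):
        s = summarize_draws(np.array([1.0, 2, 3, 4, 5]))
        assert s["mean"] == 3.0

    def test_symmetric_no_support(self):
        rng = np.random.default_rng(0)
        s = summarize_draws(rng.normal(0, 1, 4000))
        assert not s["support"]

    def test_tight_positive_support(self):
        rng = np.random.default_rng(1)
        s = summarize_draws(rng.normal(2, 0.1, 4000))
        assert s["support"]


class TestFitPom:
    def test_deterministic(self, study14):
        cov = study14.covariates.standardize()
        spec = CommunityModelSpec(chains=2, iterations=600, burn_in=300,
                                  thinning=5, seed=42)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s1 = pp.fit_pom(study14.detections, cov, study14.trees, spec=spec)
            s2 = pp.fit_pom(study14.detections, cov, study14.trees, spec=spec)
        for name in s1.arrays:
            np.testing.assert_array_equal(s1.arrays[name], s2.arrays[name])

    def test_all_zero_detections_no_crash(self):
        study = pp.study_mimic(3, n_sites=14, n_trees=1)
        data = study.detections
        zero = pp.DetectionDataset(data.species, data.sites,
                                   np.zeros_like(data.Y), data.N, data.mask)
        cov = study.covariates.standardize()
        spec = CommunityModelSpec(chains=2, iterations=2000, burn_in=1000,
                                  thinning=5, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = pp.fit_pom(zero, cov, study.trees, spec=spec)
        # occupancy posterior concentrates low
        assert s.z_draws.mean() < 0.45

    def test_detections_force_occupancy_in_draws(self, study14):
        cov = study14.covariates.standardize()
        spec = CommunityModelSpec(chains=2, iterations=1000, burn_in=500,
                                  thinning=5, seed=7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = pp.fit_pom(study14.detections, cov, study14.trees, spec=spec)
        forced = study14.detections.detected_any
        assert (s.z_draws[:, :, forced] == 1).all()

    def test_lambda_draws_spike_or_slab(self, study14):
        cov = study14.covariates.standardize()
        spec = CommunityModelSpec(chains=2, iterations=1000, burn_in=500,
                                  thinning=5, seed=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = pp.fit_pom(study14.detections, cov, study14.trees, spec=spec)
        lam = s.arrays["lam"]
        assert ((lam == 0) | ((lam > 0) & (lam <= 1))).all()

    def test_single_species_recovery(self):
        """K=1, 500 sites, known alpha=0, beta_temp=1, p=0.7."""
        rng = np.random.default_rng(2)
        I = 500
        frame = pd.DataFrame(
            {
                "elevation": np.linspace(400, 1700, I),
                "temperature": rng.normal(size=I),
                "precipitation": rng.normal(size=I),
                "forest_cover": rng.normal(size=I),
            },
            index=pd.Index([f"s{i}" for i in range(I)], name="site"),
        )
        cov = pp.SiteCovariates(frame).standardize()
        X = cov.matrix(("temperature", "precipitation", "forest_cover"))
        psi = 1 / (1 + np.exp(-(0.0 + X[:, 0] * 1.0)))
        Z = (rng.random(I) < psi).astype(int)
        N = np.array([np.full(I, 3), np.zeros(I, dtype=int)])
        Y = np.zeros((2, I, 1), dtype=int)
        Y[0, :, 0] = rng.binomial(3, 0.7 * Z)
        mask = np.array([[True], [False]])
        data = pp.DetectionDataset(["sp1"], cov.sites, Y, N, mask)
        C = pp.PhyloCorrelation(["sp1"], np.eye(1))
        spec = CommunityModelSpec(chains=2, iterations=8000, burn_in=4000,
                                  thinning=5, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = pp.fit_pom(data, cov, [C], spec=spec)
        alpha_hat = s.draws("alpha[sp1]").mean()
        beta_hat = s.draws("beta[temperature,sp1]").mean()
        p_hat = 1 / (1 + np.exp(-s.draws("p_logit[mist_net,sp1]"))).mean()
        assert abs(alpha_hat - 0.0) < 0.2
        assert abs(beta_hat - 1.0) < 0.2
        assert abs(p_hat - 0.7) < 0.1
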