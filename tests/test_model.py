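import math

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist
from scipy.stats import multivariate_normal

from coxdeform.geometry import (PointPattern, Region, SpatialGrid, build_grid,
                                discretize)
from coxdeform.model import (AnisotropyMode, DeformationPrior,
                             DeformationState, GPHyper, ModelState,
                             PosteriorDensity, build_beta_covariance,
                             conditional_row_corr, corr_exponential,
                             default_config, deformation_log_prior,
                             geometric_transform, get_link, link_eval,
                             log_likelihood, log_posterior)

UNIT = Region(0, 1, 0, 1)


class TestCorrAndLinks:
    def test_exponential_correlation_values(self):
        assert corr_exponential(0.0, 2.0) == 1.0
        assert corr_exponential(1.0, 1.0) == pytest.approx(math.exp(-1))
        assert corr_exponential(2.0, 1.0) == pytest.approx(math.exp(-2))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            corr_exponential(-0.1, 1.0)
        with pytest.raises(ValueError):
            corr_exponential(1.0, 0.0)

    def test_link_values(self):
        assert link_eval(get_link("probit"), 0.0) == pytest.approx(0.5)
        assert link_eval(get_link("log"), 0.0) == pytest.approx(1.0)
        # left tail: Phi(-3) ~ 1.35e-3, effectively zero intensity
        assert link_eval(get_link("probit"), -3.0) == pytest.approx(
            0.0013499, abs=1e-6)

    def test_unknown_link_rejected(self):
        with pytest.raises(ValueError):
            get_link("logit")


class TestBetaCovariance:
    def test_two_cell_closed_form(self):
        # delta=0.5, theta=1, deformed distance 1: 2*[[1, e^-1], [e^-1, 1]]
        coords = np.array([[0.0, 0.0], [1.0, 0.0]])
        deformation = DeformationState(d=coords, anchor_ids=(0, 1))
        Sigma = build_beta_covariance(coords, theta=1.0, delta=0.5,
                                      deformation=deformation, jitter=0.0)
        expect = 2.0 * np.array([[1.0, math.exp(-1)], [math.exp(-1), 1.0]])
        assert np.allclose(Sigma, expect, atol=1e-12)

    def test_identity_deformation_equals_isotropic(self):
        grid = build_grid(UNIT, 3, 3)
        Sigma_d = build_beta_covariance(
            grid, 0.5, 0.5, AnisotropyMode("deformation"),
            DeformationState.identity(grid))
        Sigma_iso = build_beta_covariance(grid, 0.5, 0.5,
                                          AnisotropyMode("isotropic"))
        assert np.array_equal(Sigma_d, Sigma_iso)

    def test_geometric_identity_transform_equals_isotropic(self):
        grid = build_grid(UNIT, 4, 3)
        Sigma_g = build_beta_covariance(
            grid, 0.7, 2.0, AnisotropyMode("geometric", psi_deg=0.0,
                                           ratio=1.0))
        Sigma_iso = build_beta_covariance(grid, 0.7, 2.0,
                                          AnisotropyMode("isotropic"))
        assert np.allclose(Sigma_g, Sigma_iso, atol=1e-14)

    def test_geometric_ratio_shrinks_second_axis(self):
        pts = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        out = geometric_transform(pts, psi_deg=0.0, ratio=2.0)
        # ratio=2 halves separation along y, leaves x intact
        assert np.allclose(out[1] - out[0], [0.0, 0.5])
        assert np.allclose(out[2] - out[0], [1.0, 0.0])

    def test_positive_definite_for_random_deformations(self):
        rng = np.random.default_rng(2)
        grid = build_grid(UNIT, 4, 4)
        for _ in range(20):
            d = grid.centroids + rng.normal(0, 0.2, size=(grid.Z, 2))
            d[0] = grid.centroids[0]
            d[-1] = grid.centroids[-1]
            deformation = DeformationState(d=d, anchor_ids=(0, grid.Z - 1))
            Sigma = build_beta_covariance(
                grid, theta=float(rng.uniform(0.05, 2.0)),
                delta=float(rng.uniform(0.1, 5.0)),
                mode=AnisotropyMode("deformation"), deformation=deformation)
            np.linalg.cholesky(Sigma)  # raises if not PD
            assert np.allclose(Sigma, Sigma.T)

    def test_distance_preserving_transform_leaves_covariance(self):
        # global rotation+translation of D-space preserves all distances,
        # hence the covariance: the non-identifiability anchoring resolves
        grid = build_grid(UNIT, 3, 3)
        rng = np.random.default_rng(4)
        d = grid.centroids + rng.normal(0, 0.1, size=(grid.Z, 2))
        ang = 0.7
        rot = np.array([[math.cos(ang), -math.sin(ang)],
                        [math.sin(ang), math.cos(ang)]])
        d2 = d @ rot.T + np.array([3.0, -1.0])
        s1 = build_beta_covariance(grid, 0.5, 1.0,
                                   AnisotropyMode("deformation"),
                                   DeformationState(d, (0, grid.Z - 1)))
        s2 = build_beta_covariance(grid, 0.5, 1.0,
                                   AnisotropyMode("deformation"),
                                   DeformationState(d2, (0, grid.Z - 1)))
        assert np.allclose(s1, s2, atol=1e-12)


class TestDeformationPrior:
    def test_at_conditional_mean_only_constant_remains(self):
        grid = build_grid(UNIT, 3, 3)
        prior = DeformationPrior()
        lp = deformation_log_prior(DeformationState.identity(grid), prior,
                                   grid)
        Rcond, free = conditional_row_corr(grid, prior, (0, grid.Z - 1))
        F = len(free)
        sig2 = np.array(prior.sigma_d) ** 2
        logdet = 2 * np.linalg.slogdet(Rcond)[1] + F * np.sum(np.log(sig2))
        assert lp == pytest.approx(-0.5 * logdet - F * math.log(2 * math.pi),
                                   rel=1e-12)

    def test_quadratic_scales_inversely_with_variance(self):
        grid = build_grid(UNIT, 3, 3)
        pert = np.zeros((grid.Z, 2))
        pert[4] = [0.01, -0.02]  # interior, non-anchored cell
        drops = []
        for sig in (0.05, 0.1):
            prior = DeformationPrior(sigma_d=(sig, sig))
            lp0 = deformation_log_prior(DeformationState.identity(grid),
                                        prior, grid)
            lp1 = deformation_log_prior(
                DeformationState(grid.centroids + pert, (0, grid.Z - 1)),
                prior, grid)
            drops.append(lp0 - lp1)
        # Mahalanobis quadratic halves in log scale as sigma doubles (1/sig^2)
        assert drops[0] / drops[1] == pytest.approx(4.0, rel=1e-10)

    def test_agrees_with_dense_kronecker_oracle(self):
        # brute force: condition the full 2Z-dimensional MVN on the anchors
        grid = build_grid(UNIT, 3, 3)
        prior = DeformationPrior(sigma_d=(0.07, 0.04), phi=0.25)
        rng = np.random.default_rng(8)
        d = grid.centroids + rng.normal(0, 0.05, size=(grid.Z, 2))
        d[0] = grid.centroids[0]
        d[-1] = grid.centroids[-1]
        state = DeformationState(d, (0, grid.Z - 1))
        lp = deformation_log_prior(state, prior, grid)

        R = prior.row_corr(grid.centroids)  # jittered, as the model defines
        free = np.arange(1, grid.Z - 1)
        anchors = np.array([0, grid.Z - 1])
        Rff = R[np.ix_(free, free)]
        Rfa = R[np.ix_(free, anchors)]
        Raa = R[np.ix_(anchors, anchors)]
        Rcond = Rff - Rfa @ np.linalg.inv(Raa) @ Rfa.T
        Rcond[np.diag_indices_from(Rcond)] += (prior.jitter
                                               * np.mean(np.diag(Rcond)))
        # vec over (site, axis) blocks: covariance kron(Rcond, diag(sigma^2))
        cov = np.kron(Rcond, np.diag(np.array(prior.sigma_d) ** 2))
        mean = grid.centroids[free].ravel()
        lp_oracle = multivariate_normal.logpdf(d[free].ravel(), mean, cov)
        assert lp == pytest.approx(lp_oracle, abs=1e-8)

    def test_anchor_violation_rejected(self):
        grid = build_grid(UNIT, 3, 3)
        d = grid.centroids.copy()
        d[0] += 0.1
        with pytest.raises(ValueError, match="anchor"):
            deformation_log_prior(DeformationState(d, (0, grid.Z - 1)),
                                  DeformationPrior(), grid)


def _state(grid, beta, link="log", lam=1.0, mu=0.0, delta=0.5, theta=0.4,
           mode="isotropic"):
    return ModelState(beta=np.asarray(beta, float),
                      deformation=DeformationState.identity(grid),
                      hyper=GPHyper(theta=theta, delta=delta, mu=mu,
                                    lambda_star=lam),
                      link=get_link(link),
                      mode=AnisotropyMode(mode))


def _counts(grid, y):
    from coxdeform.geometry import ObservedCounts
    return ObservedCounts(y=np.asarray(y, dtype=np.int64), grid=grid)


class TestLikelihood:
    def test_single_cell_log_link(self):
        grid = build_grid(UNIT, 1, 1)
        ll = log_likelihood(_state(grid, [0.0]), _counts(grid, [0]))
        assert ll == pytest.approx(-1.0)

    def test_single_cell_probit(self):
        # y=2, lambda*=100, Phi(0)=0.5, nu=0.5: 2 log 50 - 25
        grid = build_grid(UNIT, 1, 1)
        grid = SpatialGrid(region=Region(0, 1, 0, 0.5), nx=1, ny=1,
                           centroids=np.array([[0.5, 0.25]]),
                           cell_measures=np.array([0.5]))
        ll = log_likelihood(_state(grid, [0.0], link="probit", lam=100.0),
                            _counts(grid, [2]))
        assert ll == pytest.approx(2 * math.log(50.0) - 25.0)

    def test_zero_intensity_with_events_is_minus_inf(self):
        grid = build_grid(UNIT, 1, 1)
        state = _state(grid, [-400.0], link="probit", lam=10.0)
        assert log_likelihood(state, _counts(grid, [3])) == -math.inf

    def test_integral_term_converges_to_quadrature(self):
        # beta(s) = sin(2 pi x) cos(2 pi y): the discretized intensity
        # integral approaches the continuous integral as the grid refines
        def beta_fun(c):
            return np.sin(2 * np.pi * c[:, 0]) * np.cos(2 * np.pi * c[:, 1])

        g = (np.arange(256) + 0.5) / 256
        gx, gy = np.meshgrid(g, g)
        target = float(np.exp(np.sin(2 * np.pi * gx)
                              * np.cos(2 * np.pi * gy)).mean())
        errs = []
        for n in (4, 8, 16, 64):
            grid = build_grid(UNIT, n, n)
            state = _state(grid, beta_fun(grid.centroids))
            # with y = 0 the log likelihood is minus the intensity integral
            integral = -log_likelihood(state, _counts(grid, [0] * grid.Z))
            errs.append(abs(integral - target))
        assert errs[-1] < errs[0]
        assert errs[-1] < 5e-4

    def test_constant_option_adds_y_factorials(self):
        from scipy.stats import poisson
        grid = build_grid(UNIT, 2, 2)
        state = _state(grid, [0.1, -0.2, 0.3, 0.0])
        counts = _counts(grid, [3, 0, 5, 1])
        full = log_likelihood(state, counts, include_constant=True)
        lam_nu = state.cell_intensity() * grid.cell_measures
        oracle = float(poisson.logpmf(counts.y, lam_nu).sum())
        assert full == pytest.approx(oracle, rel=1e-12)


class TestLogPosterior:
    def _random_setup(self, seed, link, mode):
        rng = np.random.default_rng(seed)
        grid = build_grid(UNIT, 3, 3)
        pattern = PointPattern(rng.uniform(0, 1, (50, 2)), UNIT)
        counts = discretize(pattern, grid)
        cfg = default_config(grid, 50, link=link, mode=mode)
        d = grid.centroids.copy()
        if mode == "deformation":
            d[1:-1] += rng.normal(0, 0.03, size=(grid.Z - 2, 2))
        state = ModelState(
            beta=rng.normal(0, 1, grid.Z),
            deformation=DeformationState(d, (0, grid.Z - 1)),
            hyper=GPHyper(theta=float(rng.uniform(0.2, 1.0)),
                          delta=0.5 if link == "probit"
                          else float(rng.uniform(0.3, 2.0)),
                          mu=0.0 if link == "probit"
                          else float(rng.normal()),
                          lambda_star=float(rng.uniform(30, 90))
                          if link == "probit" else 1.0),
            link=get_link(link),
            mode=AnisotropyMode(mode) if mode != "geometric"
            else AnisotropyMode("geometric", psi_deg=20.0, ratio=1.5))
        return grid, counts, cfg, state

    @pytest.mark.parametrize("link,mode", [
        ("probit", "deformation"), ("log", "deformation"),
        ("probit", "isotropic"), ("log", "geometric")])
    def test_equals_sum_of_independent_components(self, link, mode):
        grid, counts, cfg, state = self._random_setup(17, link, mode)
        lp = log_posterior(state, counts, cfg)

        expected = log_likelihood(state, counts)
        Sigma = build_beta_covariance(grid, state.hyper.theta,
                                      state.hyper.delta, state.mode,
                                      state.deformation, cfg.jitter)
        expected += multivariate_normal.logpdf(state.beta,
                                               np.zeros(grid.Z), Sigma)
        a, b = cfg.theta_prior
        expected += gamma_dist.logpdf(state.hyper.theta, a, scale=1 / b)
        if link == "probit":
            a, b = cfg.lambda_star_prior
            expected += gamma_dist.logpdf(state.hyper.lambda_star, a,
                                          scale=1 / b)
        else:
            a, b = cfg.delta_prior
            expected += gamma_dist.logpdf(state.hyper.delta, a, scale=1 / b)
        if mode == "deformation":
            expected += deformation_log_prior(state.deformation,
                                              cfg.deformation_prior, grid)
        if mode == "geometric":
            a, b = cfg.ratio_excess_prior
            expected += gamma_dist.logpdf(state.mode.ratio - 1.0, a,
                                          scale=1 / b)
        assert lp == pytest.approx(expected, rel=1e-10)

    def test_cell_relabeling_invariance(self):
        grid, counts, cfg, state = self._random_setup(23, "probit",
                                                      "isotropic")
        lp = log_posterior(state, counts, cfg)
        rng = np.random.default_rng(1)
        perm = rng.permutation(grid.Z)
        pgrid = SpatialGrid(region=grid.region, nx=grid.nx, ny=grid.ny,
                            centroids=grid.centroids[perm],
                            cell_measures=grid.cell_measures[perm])
        pcounts = _counts(pgrid, counts.y[perm])
        anchor_new = (int(np.nonzero(perm == 0)[0][0]),
                      int(np.nonzero(perm == grid.Z - 1)[0][0]))
        pstate = ModelState(beta=state.beta[perm],
                            deformation=DeformationState(
                                state.deformation.d[perm], anchor_new),
                            hyper=state.hyper, link=state.link,
                            mode=state.mode)
        assert log_posterior(pstate, pcounts, cfg) == pytest.approx(
            lp, rel=1e-12)

    def test_single_cell_flat_data_hand_computation(self):
        grid = build_grid(UNIT, 1, 1)
        cfg = default_config(grid, 0, link="log", mode="isotropic")
        state = _state(grid, [0.3], mu=0.1, delta=0.8)
        lp = log_posterior(state, _counts(grid, [0]), cfg)
        Sigma = 1 / 0.8 + cfg.jitter / 0.8
        hand = (-math.exp(0.1 + 0.3)
                - 0.5 * (0.3 ** 2 / Sigma + math.log(2 * math.pi * Sigma))
                + gamma_dist.logpdf(0.4, cfg.theta_prior[0],
                                    scale=1 / cfg.theta_prior[1])
                + gamma_dist.logpdf(0.8, 0.1, scale=10.0))
        assert lp == pytest.approx(hand, rel=1e-10)


class TestNonCenteredTransforms:
    def _post(self, link="probit", mode="deformation", **kw):
        rng = np.random.default_rng(31)
        grid = build_grid(UNIT, 3, 3)
        counts = discretize(PointPattern(rng.uniform(0, 1, (40, 2)), UNIT),
                            grid)
        cfg = default_config(grid, 40, link=link, mode=mode)
        return PosteriorDensity(counts, cfg, **kw), rng

    def test_zero_raw_maps_to_prior_centre(self):
        post, _ = self._post()
        raw = np.zeros(post.layout.size)
        state = post.unpack(raw)
        assert np.allclose(state.beta, 0.0)
        assert np.allclose(state.deformation.d, post.grid.centroids)

    @pytest.mark.parametrize("link,mode", [
        ("probit", "deformation"), ("log", "isotropic"),
        ("probit", "geometric")])
    def test_round_trip_identity(self, link, mode):
        post, rng = self._post(link, mode)
        raw = post.initial_raw(rng, scale=0.5)
        back = post.pack(post.unpack(raw))
        assert np.max(np.abs(back - raw)) < 1e-10

    def test_pushforward_matches_target_mvn(self):
        # fixed deformation/theta/delta: beta = L z over 10^4 standard
        # normals reproduces the prior covariance within MC error
        post, rng = self._post(mode="isotropic")
        raw = np.zeros(post.layout.size)
        theta = math.exp(raw[post.layout.i_logtheta])
        Sigma = build_beta_covariance(post.grid, theta,
                                      post.config.delta_fixed,
                                      AnisotropyMode("isotropic"))
        n = 10_000
        betas = np.empty((n, post.grid.Z))
        for i in range(n):
            r = raw.copy()
            r[post.layout.sl_zbeta] = rng.standard_normal(post.grid.Z)
            betas[i] = post.unpack(r).beta
        emp = np.cov(betas.T)
        assert np.max(np.abs(betas.mean(axis=0))) < 4 / math.sqrt(n) * 2
        assert np.max(np.abs(emp - Sigma)) < 0.15

    def test_deformation_pushforward_covariance(self):
        post, rng = self._post()
        lay = post.layout
        n = 8000
        free = post._free
        devs = np.empty((n, len(free), 2))
        raw = np.zeros(lay.size)
        for i in range(n):
            r = raw.copy()
            r[lay.sl_zd] = rng.standard_normal(2 * len(free))
            devs[i] = post.unpack(r).deformation.d[free] \
                - post.grid.centroids[free]
        Rcond, _ = conditional_row_corr(post.grid,
                                        post.config.deformation_prior,
                                        post.anchor_ids)
        sig2 = np.array(post.config.deformation_prior.sigma_d) ** 2
        emp_x = np.cov(devs[:, :, 0].T)
        assert np.max(np.abs(emp_x - Rcond * sig2[0])) < 5e-4

    @pytest.mark.parametrize("link,mode,centered", [
        ("probit", "deformation", False),
        ("log", "geometric", False),
        ("probit", "isotropic", True),
    ])
    def test_gradient_matches_finite_differences(self, link, mode, centered):
        post, rng = self._post(link, mode, centered_beta=centered)
        raw = post.initial_raw(rng, scale=0.3)
        _, grad = post.logp_and_grad(raw)
        eps = 1e-6
        for i in range(raw.size):
            r1, r2 = raw.copy(), raw.copy()
            r1[i] += eps
            r2[i] -= eps
            num = (post.logp(r1) - post.logp(r2)) / (2 * eps)
            assert grad[i] == pytest.approx(num, rel=2e-4, abs=1e-6)
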