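"""Hierarchical Cox process with latent spatial deformation.

The observed point pattern is a Poisson process whose intensity is
``lambda(s) = lambda_star * g(mu + beta(s))`` for a latent zero-mean Gaussian
process ``beta`` with precision ``delta`` and exponential correlation
``rho_theta``.  Nonstationarity/anisotropy enters through a latent bivariate
Gaussian deformation ``d : G -> D``: correlation between two sites is a
function of the distance between their *deformed* images,
``Corr(beta(s_i), beta(s_j)) = exp(-||d(s_i) - d(s_j)|| / theta)``.

The deformation has a matrix-variate normal prior centred on the identity
map with per-axis variances ``sigma_d^2`` and exponential cross-site
correlation with range ``phi``.  Two cells (the first and last centroid in
row-major order) are anchored at their geographic positions to remove the
translation/rotation non-identifiability of distances; anchoring is done by
conditioning the matrix-normal prior on the anchor columns, which keeps a
proper prior and a smooth posterior geometry.

Everything is discretized on a grid: ``beta`` is piecewise constant with the
cell centroid as representative point, so the likelihood integral becomes
``sum_z lambda_star g(mu + beta(s_z)) nu(G_z)``.

Three covariance modes are supported:

- ``deformation`` — distances measured between deformed centroids (the model
  above);
- ``isotropic``  — geographic distances (the stationary special case);
- ``geometric``  — geographic coordinates rotated by an angle ``psi`` and the
  second principal axis shrunk by the anisotropy ratio ``r >= 1`` before
  measuring distances (classical geometric anisotropy; two parameters).

The module also provides the joint unnormalized log-posterior on a
*non-centered* parameterization (latent Gaussians expressed as transforms of
standard normals) together with its exact gradient, which is what the HMC
sampler in :mod:`coxdeform.inference` consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.special import log_ndtr, ndtr

from .geometry import ObservedCounts, SpatialGrid

__all__ = [
    "LinkSpec",
    "PROBIT",
    "LOG",
    "get_link",
    "DeformationState",
    "DeformationPrior",
    "GPHyper",
    "AnisotropyMode",
    "ModelState",
    "ModelConfig",
    "default_config",
    "corr_exponential",
    "link_eval",
    "geometric_transform",
    "build_beta_covariance",
    "deformation_log_prior",
    "log_likelihood",
    "log_posterior",
    "PosteriorDensity",
]

_LOG_2PI = math.log(2.0 * math.pi)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Link functions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinkSpec:
    """Monotone map g from the latent Gaussian to a non-negative multiplier.

    Bounded links (probit) require the maximal intensity ``lambda_star`` to
    be estimated; for the exponential (log link) the supremum is infinite and
    ``lambda_star`` is fixed at 1.
    """

    name: str
    needs_lambda_star: bool

    def g(self, eta: np.ndarray) -> np.ndarray:
        if self.name == "probit":
            return ndtr(eta)
        return np.exp(eta)

    def log_g(self, eta: np.ndarray) -> np.ndarray:
        if self.name == "probit":
            return log_ndtr(eta)
        return np.asarray(eta, dtype=float)

    def dg(self, eta: np.ndarray) -> np.ndarray:
        if self.name == "probit":
            return _INV_SQRT_2PI * np.exp(-0.5 * np.square(eta))
        return np.exp(eta)


PROBIT = LinkSpec("probit", needs_lambda_star=True)
LOG = LinkSpec("log", needs_lambda_star=False)


def get_link(name: str) -> LinkSpec:
    try:
        return {"probit": PROBIT, "log": LOG}[name]
    except KeyError:
        raise ValueError(f"unknown link {name!r}; expected 'probit' or 'log'")


def link_eval(link: LinkSpec, eta):
    """Evaluate g(eta): the normal CDF for probit, exp for the log link."""
    return link.g(np.asarray(eta, dtype=float))


# ---------------------------------------------------------------------------
# Correlation / covariance building blocks
# ---------------------------------------------------------------------------

def corr_exponential(dist, range_: float):
    """Exponential correlation exp(-dist/range); 1 at zero distance."""
    dist = np.asarray(dist, dtype=float)
    if np.any(dist < 0):
        raise ValueError("distances must be non-negative")
    if range_ <= 0:
        raise ValueError("correlation range must be positive")
    return np.exp(-dist / range_)


def _pairwise_dist(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=-1))


def geometric_transform(coords: np.ndarray, psi_deg: float,
                        ratio: float) -> np.ndarray:
    """Rotate axes by psi and shrink the second principal axis by 1/ratio.

    Distances between the transformed coordinates define the geometric
    anisotropy correlation: correlation decays ``ratio`` times faster along
    the second principal axis than along the first.
    """
    if ratio < 1:
        raise ValueError("anisotropy ratio must be >= 1")
    p = math.radians(psi_deg)
    c, s = math.cos(p), math.sin(p)
    rot = np.array([[c, s], [-s, c]])
    T = np.diag([1.0, 1.0 / ratio]) @ rot
    return coords @ T.T


@dataclass(frozen=True)
class AnisotropyMode:
    """Covariance mode: deformation | isotropic | geometric."""

    kind: str = "deformation"
    psi_deg: float = 0.0  # geometric only: rotation angle in (-90, 90]
    ratio: float = 1.0    # geometric only: anisotropy ratio >= 1

    def __post_init__(self) -> None:
        if self.kind not in ("deformation", "isotropic", "geometric"):
            raise ValueError(f"unknown anisotropy mode {self.kind!r}")
        if self.ratio < 1:
            raise ValueError("anisotropy ratio must be >= 1")
        if not (-90.0 < self.psi_deg <= 90.0):
            raise ValueError("rotation angle must lie in (-90, 90]")


# ---------------------------------------------------------------------------
# Deformation state and prior
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeformationState:
    """Deformed centroid coordinates d(s_z), one row per cell (Z, 2).

    The two anchored rows are fixed exactly at their geographic centroids.
    """

    d: np.ndarray                 # (Z, 2)
    anchor_ids: tuple[int, int]   # indices of the anchored cells

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        if d.ndim != 2 or d.shape[1] != 2:
            raise ValueError("deformation must be (Z, 2)")
        if not np.all(np.isfinite(d)):
            raise ValueError("deformation contains non-finite entries")

    @staticmethod
    def identity(grid: SpatialGrid) -> "DeformationState":
        return DeformationState(d=grid.centroids.copy(),
                                anchor_ids=(0, grid.Z - 1))

    def check_anchors(self, grid: SpatialGrid, atol: float = 0.0) -> None:
        a = list(self.anchor_ids)
        if not np.allclose(self.d[a], grid.centroids[a], atol=atol, rtol=0):
            raise ValueError("anchored rows must equal their geographic "
                             "centroids")


@dataclass(frozen=True)
class DeformationPrior:
    """Matrix-normal prior for the deformation.

    Mean is the identity map (prior indifference about how D differs from
    G); ``sigma_d`` are per-axis standard deviations controlling how much
    warping is allowed; ``phi`` is the exponential correlation range across
    sites, controlling smoothness of the warp.
    """

    sigma_d: tuple[float, float] = (0.1, 0.1)
    phi: float = 0.3
    jitter: float = 1e-8

    def __post_init__(self) -> None:
        if min(self.sigma_d) <= 0 or self.phi <= 0:
            raise ValueError("sigma_d and phi must be positive")

    def row_corr(self, coords: np.ndarray) -> np.ndarray:
        R = corr_exponential(_pairwise_dist(coords), self.phi)
        return _add_jitter(R, self.jitter)


def _add_jitter(mat: np.ndarray, jitter: float) -> np.ndarray:
    out = mat.copy()
    out[np.diag_indices_from(out)] += jitter * np.mean(np.diag(mat))
    return out


def _chol_lower(mat: np.ndarray, what: str) -> np.ndarray:
    try:
        return cholesky(mat, lower=True, check_finite=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise np.linalg.LinAlgError(
            f"Cholesky of {what} failed even after jitter; increase the "
            "jitter setting in the model config") from exc


@dataclass(frozen=True)
class GPHyper:
    """Scalar hyperparameters of the latent field and intensity."""

    theta: float          # correlation range of beta (in D-space units)
    delta: float          # precision of beta
    mu: float             # intercept of the linear predictor
    lambda_star: float    # maximal intensity (1 under the log link)

    def __post_init__(self) -> None:
        if self.theta <= 0 or self.delta <= 0 or self.lambda_star <= 0:
            raise ValueError("theta, delta and lambda_star must be positive")


@dataclass(frozen=True)
class ModelState:
    """Everything the joint density needs: (beta_Z, d_Z, hyper, link, mode)."""

    beta: np.ndarray              # (Z,)
    deformation: DeformationState
    hyper: GPHyper
    link: LinkSpec
    mode: AnisotropyMode = AnisotropyMode("deformation")

    def cell_intensity(self) -> np.ndarray:
        """Per-cell intensity lambda_star * g(mu + beta_z)."""
        h = self.hyper
        return h.lambda_star * self.link.g(h.mu + self.beta)


# ---------------------------------------------------------------------------
# Model configuration (priors, fixed hyperparameters, mode/link choice)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Link/mode choice plus priors and fixed hyperparameters.

    Gamma priors are (shape, rate).  Under the probit link ``mu`` and
    ``delta`` are fixed (0 and 0.5) to aid identification, and
    ``lambda_star`` gets a Gamma prior; under the log link ``lambda_star``
    is fixed at 1, ``mu`` has a flat improper prior and ``delta`` a vague
    Gamma(0.1, 0.1) prior.
    """

    link: str = "probit"
    mode: str = "deformation"
    theta_prior: tuple[float, float] = (2.0, 2.0 / 0.47)
    lambda_star_prior: tuple[float, float] = (2.0, 2.0 / 1000.0)
    delta_prior: tuple[float, float] = (0.1, 0.1)
    mu_fixed: float = 0.0
    delta_fixed: float = 0.5
    deformation_prior: DeformationPrior = field(default_factory=DeformationPrior)
    ratio_excess_prior: tuple[float, float] = (2.0, 4.0)  # r = 1 + Gamma
    jitter: float = 1e-8
    include_likelihood_constant: bool = False

    @property
    def link_spec(self) -> LinkSpec:
        return get_link(self.link)


def default_config(grid: SpatialGrid, n_events: int, link: str = "probit",
                   mode: str = "deformation", **overrides) -> ModelConfig:
    """Data-scaled default priors.

    The range prior is centred so correlation has decayed to 0.05 at the
    region diameter; the maximal-intensity prior is centred on the empirical
    mean intensity n/area.
    """
    theta0 = grid.region.diameter / math.log(20.0)
    lam_hat = max(n_events, 1) / grid.region.area
    cfg = ModelConfig(link=link, mode=mode,
                      theta_prior=(2.0, 2.0 / theta0),
                      lambda_star_prior=(2.0, 2.0 / lam_hat))
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# Covariance of the latent field beta
# ---------------------------------------------------------------------------

def _mode_coords(grid_or_coords, deformation: DeformationState | None,
                 mode: AnisotropyMode) -> np.ndarray:
    coords = (grid_or_coords.centroids
              if isinstance(grid_or_coords, SpatialGrid) else
              np.asarray(grid_or_coords, dtype=float))
    if mode.kind == "deformation":
        if deformation is None:
            raise ValueError("deformation mode requires a DeformationState")
        return deformation.d
    if mode.kind == "geometric":
        return geometric_transform(coords, mode.psi_deg, mode.ratio)
    return coords


def build_beta_covariance(grid_or_coords, theta: float, delta: float,
                          mode: AnisotropyMode = AnisotropyMode("deformation"),
                          deformation: DeformationState | None = None,
                          jitter: float = 1e-8) -> np.ndarray:
    """Z x Z covariance of beta: (1/delta) exp(-dist/theta) plus jitter.

    Distances depend on the mode: deformed coordinates, plain geographic
    coordinates, or geometrically transformed coordinates.
    """
    coords = _mode_coords(grid_or_coords, deformation, mode)
    R = corr_exponential(_pairwise_dist(coords), theta)
    return _add_jitter(R / delta, jitter)


# ---------------------------------------------------------------------------
# Deformation prior density (conditioned on the anchors)
# ---------------------------------------------------------------------------

def _anchor_split(Z: int, anchor_ids: tuple[int, int]):
    a = np.asarray(anchor_ids, dtype=int)
    free = np.setdiff1d(np.arange(Z), a)
    return a, free


def conditional_row_corr(grid: SpatialGrid, prior: DeformationPrior,
                         anchor_ids: tuple[int, int]):
    """Schur complement of the cross-site correlation given the anchors.

    Because the anchors sit exactly at the prior mean, conditioning leaves
    the free-cell mean at the identity map and only shrinks the row
    correlation.
    """
    R = prior.row_corr(grid.centroids)
    a, free = _anchor_split(grid.Z, anchor_ids)
    Raa = R[np.ix_(a, a)]
    Rfa = R[np.ix_(free, a)]
    Rff = R[np.ix_(free, free)]
    La = _chol_lower(Raa, "anchor correlation block")
    W = solve_triangular(La, Rfa.T, lower=True)  # (2, F)
    Rcond = Rff - W.T @ W
    return _add_jitter(Rcond, prior.jitter), free


def deformation_log_prior(deformation: DeformationState,
                          prior: DeformationPrior,
                          grid: SpatialGrid) -> float:
    """Log density of the free deformation columns given the anchors.

    The joint prior is matrix-normal with row correlation ``rho_phi`` over
    sites and column covariance ``diag(sigma_d^2)`` over axes; conditioning
    on the two anchored sites (fixed at the prior mean) yields a proper
    matrix-normal on the remaining F = Z - 2 sites whose density this
    returns, normalizing constant included.
    """
    deformation.check_anchors(grid, atol=1e-12)
    Rcond, free = conditional_row_corr(grid, prior, deformation.anchor_ids)
    F = len(free)
    delta_mat = deformation.d[free] - grid.centroids[free]  # (F, 2)
    L = _chol_lower(Rcond, "conditional deformation correlation")
    half = solve_triangular(L, delta_mat, lower=True)       # (F, 2)
    sig2 = np.square(np.asarray(prior.sigma_d, dtype=float))
    quad = float(np.sum(np.square(half) / sig2[None, :]))
    logdet_R = 2.0 * float(np.sum(np.log(np.diag(L))))
    logdet = 2.0 * logdet_R + F * float(np.sum(np.log(sig2)))
    return -0.5 * (quad + logdet) - F * _LOG_2PI


# ---------------------------------------------------------------------------
# Likelihood and joint posterior on the natural scale
# ---------------------------------------------------------------------------

def log_likelihood(state: ModelState, counts: ObservedCounts,
                   include_constant: bool = False) -> float:
    """Discretized Poisson-process log likelihood.

    ``sum_z y_z log(lambda_star g(mu+beta_z)) -
    sum_z lambda_star g(mu+beta_z) nu(G_z)``; the y! terms are a constant in
    the parameters and are included only on request (they must be treated
    the same way for every model being compared).
    """
    h, link = state.hyper, state.link
    eta = h.mu + state.beta
    log_g = link.log_g(eta)
    y = counts.y
    nu = counts.grid.cell_measures
    if np.any((y > 0) & (link.g(eta) == 0.0)):
        # events observed where the intensity multiplier underflowed to 0
        return -np.inf
    out = float(np.sum(y * (math.log(h.lambda_star) + log_g))
                - h.lambda_star * np.sum(link.g(eta) * nu))
    if include_constant:
        from scipy.special import gammaln
        out += float(np.sum(y * np.log(nu)) - np.sum(gammaln(y + 1.0)))
    return out


def _gamma_logpdf(x: float, shape: float, rate: float) -> float:
    from scipy.special import gammaln
    return (shape * math.log(rate) - gammaln(shape)
            + (shape - 1.0) * math.log(x) - rate * x)


def log_posterior(state: ModelState, counts: ObservedCounts,
                  config: ModelConfig) -> float:
    """Unnormalized joint log posterior on the natural parameter scale.

    Sum of the (anchored) deformation prior, the MVN prior of beta given the
    deformation, the hyperparameter priors, and the likelihood.  This is the
    reference density; HMC targets the same density through the non-centered
    reparameterization in :class:`PosteriorDensity`.
    """
    grid = counts.grid
    h = state.hyper
    lp = 0.0
    if state.mode.kind == "deformation":
        lp += deformation_log_prior(state.deformation,
                                    config.deformation_prior, grid)
    # beta | d, theta, delta
    Sigma = build_beta_covariance(grid, h.theta, h.delta, state.mode,
                                  state.deformation, config.jitter)
    L = _chol_lower(Sigma, "beta covariance")
    half = solve_triangular(L, state.beta, lower=True)
    lp += (-0.5 * float(half @ half)
           - float(np.sum(np.log(np.diag(L)))) - 0.5 * grid.Z * _LOG_2PI)
    # hyper priors
    lp += _gamma_logpdf(h.theta, *config.theta_prior)
    if config.link_spec.needs_lambda_star:
        lp += _gamma_logpdf(h.lambda_star, *config.lambda_star_prior)
    else:
        lp += _gamma_logpdf(h.delta, *config.delta_prior)
        # flat improper prior on mu contributes 0
    if state.mode.kind == "geometric":
        a, b = config.ratio_excess_prior
        lp += _gamma_logpdf(state.mode.ratio - 1.0, a, b)
        # psi uniform on (-90, 90] contributes a constant
    lp += log_likelihood(state, counts, config.include_likelihood_constant)
    return lp


# ---------------------------------------------------------------------------
# Cholesky pullback (reverse-mode differentiation through chol)
# ---------------------------------------------------------------------------

def _chol_backward(L: np.ndarray, Lbar: np.ndarray) -> np.ndarray:
    """Gradient w.r.t. Sigma given the gradient w.r.t. L = chol(Sigma).

    Returns the full (symmetrized) matrix S such that
    df = sum(S * dSigma) for symmetric perturbations dSigma.
    """
    P = np.tril(L.T @ Lbar)
    P[np.diag_indices_from(P)] *= 0.5
    # B = L^{-T} P L^{-1}
    tmp = solve_triangular(L, P.T, lower=True, trans="T",
                           check_finite=False)
    B = solve_triangular(L, tmp.T, lower=True, trans="T",
                         check_finite=False).T
    return 0.5 * (B + B.T)


# ---------------------------------------------------------------------------
# Non-centered joint posterior density with exact gradient
# ---------------------------------------------------------------------------

def _sigmoid(x: float) -> float:
    return 0.5 * (1.0 + math.tanh(0.5 * x))


@dataclass
class _ParamLayout:
    """Index layout of the raw (unconstrained) parameter vector."""

    Z: int
    mode: str
    link: str
    n_free: int  # free deformation sites

    def __post_init__(self) -> None:
        i = 0
        self.sl_zbeta = slice(i, i + self.Z)
        i += self.Z
        if self.mode == "deformation":
            self.sl_zd = slice(i, i + 2 * self.n_free)
            i += 2 * self.n_free
        elif self.mode == "geometric":
            self.i_psi, self.i_ratio = i, i + 1
            i += 2
        if self.link == "probit":
            self.i_loglam = i
            i += 1
        else:
            self.i_mu, self.i_logdelta = i, i + 1
            i += 2
        self.i_logtheta = i
        self.size = i + 1


class PosteriorDensity:
    """Joint unnormalized log posterior in non-centered raw coordinates.

    Raw vector layout: ``[z_beta (Z) | mode block | link block | log theta]``
    where the mode block is the standard-normal deformation matrix
    (2 x (Z-2), flattened) in deformation mode or ``(w_psi, log(r-1))`` in
    geometric mode, and the link block is ``log lambda_star`` (probit) or
    ``(mu, log delta)`` (log link).

    The transforms are:

    - ``beta = L z_beta`` with ``L = chol(Sigma_beta(d, theta, delta))``;
    - free deformation rows
      ``d_free = s_free + sigma_d * (L_cond W)`` with ``W`` standard normal
      and ``L_cond`` the Cholesky factor of the anchor-conditioned row
      correlation (precomputed: it depends only on ``phi`` and geometry);
    - positive scalars on the log scale, the rotation angle through a scaled
      logistic onto (-90, 90).

    ``logp`` equals the natural-scale :func:`log_posterior` up to the
    (constant) Jacobians of the fixed bijections, and ``logp_and_grad``
    returns its exact gradient via a hand-derived adjoint pass (including
    the Cholesky pullback).
    """

    def __init__(self, counts: ObservedCounts, config: ModelConfig,
                 prior_only: bool = False,
                 centered_beta: bool = False) -> None:
        self.counts = counts
        self.config = config
        self.prior_only = prior_only
        # centered_beta=True targets the same posterior with beta itself as
        # the raw coordinate (reference for non-centered geometry checks)
        self.centered_beta = centered_beta
        self.grid = counts.grid
        self.link = config.link_spec
        self.mode_kind = config.mode
        Z = self.grid.Z
        self.anchor_ids = (0, Z - 1)
        if self.mode_kind == "deformation":
            Rcond, free = conditional_row_corr(
                self.grid, config.deformation_prior, self.anchor_ids)
            self._L_cond = _chol_lower(Rcond, "conditional deformation "
                                               "correlation")
            self._free = free
        else:
            self._free = np.array([], dtype=int)
        self.layout = _ParamLayout(Z=Z, mode=self.mode_kind,
                                   link=config.link, n_free=len(self._free))
        self._sigma_d = np.asarray(config.deformation_prior.sigma_d, float)

    # -- transforms ---------------------------------------------------------

    def _deformation_from_raw(self, zd: np.ndarray) -> np.ndarray:
        d = self.grid.centroids.copy()
        W = zd.reshape(self.layout.n_free, 2)
        d[self._free] += (self._L_cond @ W) * self._sigma_d[None, :]
        return d

    def unpack(self, raw: np.ndarray) -> ModelState:
        lay, cfg = self.layout, self.config
        theta = math.exp(raw[lay.i_logtheta])
        if cfg.link == "probit":
            lam = math.exp(raw[lay.i_loglam])
            mu, delta = cfg.mu_fixed, cfg.delta_fixed
        else:
            lam = 1.0
            mu = raw[lay.i_mu]
            delta = math.exp(raw[lay.i_logdelta])
        if self.mode_kind == "deformation":
            d = self._deformation_from_raw(raw[lay.sl_zd])
            mode = AnisotropyMode("deformation")
        elif self.mode_kind == "geometric":
            psi = -90.0 + 180.0 * _sigmoid(raw[lay.i_psi])
            ratio = 1.0 + math.exp(raw[lay.i_ratio])
            d = self.grid.centroids
            mode = AnisotropyMode("geometric", psi_deg=psi, ratio=ratio)
        else:
            d = self.grid.centroids
            mode = AnisotropyMode("isotropic")
        deformation = DeformationState(d=d, anchor_ids=self.anchor_ids)
        if self.centered_beta:
            beta = np.asarray(raw[lay.sl_zbeta], dtype=float)
        else:
            Sigma = build_beta_covariance(self.grid, theta, delta, mode,
                                          deformation, cfg.jitter)
            L = _chol_lower(Sigma, "beta covariance")
            beta = L @ raw[lay.sl_zbeta]
        return ModelState(beta=beta, deformation=deformation,
                          hyper=GPHyper(theta=theta, delta=delta, mu=mu,
                                        lambda_star=lam),
                          link=self.link, mode=mode)

    def pack(self, state: ModelState) -> np.ndarray:
        """Inverse of :meth:`unpack` (used for round-trip checks)."""
        lay, cfg = self.layout, self.config
        raw = np.zeros(lay.size)
        raw[lay.i_logtheta] = math.log(state.hyper.theta)
        if cfg.link == "probit":
            raw[lay.i_loglam] = math.log(state.hyper.lambda_star)
        else:
            raw[lay.i_mu] = state.hyper.mu
            raw[lay.i_logdelta] = math.log(state.hyper.delta)
        if self.mode_kind == "deformation":
            delta_mat = (state.deformation.d[self._free]
                         - self.grid.centroids[self._free])
            W = solve_triangular(self._L_cond,
                                 delta_mat / self._sigma_d[None, :],
                                 lower=True)
            raw[lay.sl_zd] = W.ravel()
        elif self.mode_kind == "geometric":
            p = (state.mode.psi_deg + 90.0) / 180.0
            raw[lay.i_psi] = math.log(p / (1.0 - p))
            raw[lay.i_ratio] = math.log(state.mode.ratio - 1.0)
        if self.centered_beta:
            raw[lay.sl_zbeta] = state.beta
        else:
            Sigma = build_beta_covariance(self.grid, state.hyper.theta,
                                          state.hyper.delta, state.mode,
                                          state.deformation, cfg.jitter)
            L = _chol_lower(Sigma, "beta covariance")
            raw[lay.sl_zbeta] = solve_triangular(L, state.beta, lower=True)
        return raw

    # -- density ------------------------------------------------------------

    def logp(self, raw: np.ndarray) -> float:
        return self._eval(raw, want_grad=False)[0]

    def logp_and_grad(self, raw: np.ndarray) -> tuple[float, np.ndarray]:
        return self._eval(raw, want_grad=True)

    def _eval(self, raw: np.ndarray, want_grad: bool):
        lay, cfg, link = self.layout, self.config, self.link
        grid, y, nu = self.grid, self.counts.y, self.grid.cell_measures
        Z = lay.Z
        grad = np.zeros(lay.size) if want_grad else None

        z_beta = raw[lay.sl_zbeta]
        lt = raw[lay.i_logtheta]
        theta = math.exp(lt)

        if cfg.link == "probit":
            ll_ = raw[lay.i_loglam]
            lam = math.exp(ll_)
            mu, delta = cfg.mu_fixed, cfg.delta_fixed
        else:
            lam = 1.0
            mu = raw[lay.i_mu]
            ld = raw[lay.i_logdelta]
            delta = math.exp(ld)

        # coordinates entering the correlation
        if self.mode_kind == "deformation":
            zd = raw[lay.sl_zd]
            coords = self._deformation_from_raw(zd)
        elif self.mode_kind == "geometric":
            w_psi = raw[lay.i_psi]
            v_r = raw[lay.i_ratio]
            sig = _sigmoid(w_psi)
            psi_deg = -90.0 + 180.0 * sig
            ratio = 1.0 + math.exp(v_r)
            p = math.radians(psi_deg)
            c, s = math.cos(p), math.sin(p)
            rot = np.array([[c, s], [-s, c]])
            T = np.diag([1.0, 1.0 / ratio]) @ rot
            coords = grid.centroids @ T.T
        else:
            coords = grid.centroids

        D = _pairwise_dist(coords)
        R = np.exp(-D / theta)
        Sigma = _add_jitter(R / delta, cfg.jitter)
        L = _chol_lower(Sigma, "beta covariance")
        if self.centered_beta:
            beta = z_beta
            a_vec = cho_solve((L, True), beta, check_finite=False)
        else:
            beta = L @ z_beta
        eta = mu + beta

        # likelihood
        log_g = link.log_g(eta)
        g = link.g(eta)
        dg = link.dg(eta)
        if np.any((y > 0) & ~np.isfinite(log_g)):
            lp = -np.inf
            return (lp, grad) if want_grad else (lp, None)
        loglik = (float(np.sum(y * (math.log(lam) + log_g)))
                  - lam * float(np.sum(g * nu)))
        if cfg.include_likelihood_constant:
            from scipy.special import gammaln
            loglik += float(np.sum(y * np.log(nu))
                            - np.sum(gammaln(y + 1.0)))
        if self.prior_only:
            loglik = 0.0

        # priors in raw space (Jacobians of log transforms folded in)
        a_t, b_t = cfg.theta_prior
        lp = loglik + a_t * lt - b_t * theta
        if self.centered_beta:
            lp += (-0.5 * float(beta @ a_vec)
                   - float(np.sum(np.log(np.diag(L)))))
        else:
            lp += -0.5 * float(z_beta @ z_beta)
        if self.mode_kind == "deformation":
            lp += -0.5 * float(zd @ zd)
        elif self.mode_kind == "geometric":
            a_r, b_r = cfg.ratio_excess_prior
            ex = ratio - 1.0
            lp += a_r * v_r - b_r * ex
            lp += math.log(sig) + math.log(1.0 - sig)  # uniform angle
        if cfg.link == "probit":
            a_l, b_l = cfg.lambda_star_prior
            lp += a_l * ll_ - b_l * lam
        else:
            a_d, b_d = cfg.delta_prior
            lp += a_d * ld - b_d * delta

        if not want_grad:
            return lp, None

        # ----- adjoint pass ------------------------------------------------
        # likelihood gradients
        if link.name == "probit":
            # phi/Phi computed in log space (stable deep in the left tail)
            log_ratio = -0.5 * np.square(eta) - 0.5 * _LOG_2PI - log_g
            mills = np.where(y > 0, np.exp(log_ratio), 0.0)
            u = y * mills - lam * dg * nu             # dloglik/dbeta_z
        else:
            u = y - lam * g * nu
        if self.prior_only:
            u = np.zeros_like(u, dtype=float)
        if self.centered_beta:
            grad[lay.sl_zbeta] = u - a_vec
            Sigma_inv = cho_solve((L, True), np.eye(lay.Z),
                                  check_finite=False)
            Sbar = 0.5 * (np.outer(a_vec, a_vec) - Sigma_inv)
        else:
            grad[lay.sl_zbeta] = L.T @ u - z_beta
            Lbar = np.tril(np.outer(u, z_beta))
            Sbar = _chol_backward(L, Lbar)            # dlp/dSigma (full sym)

        # theta (Sigma = R/delta + jitter; dR/dtheta = R*D/theta^2)
        theta_bar = float(np.sum(Sbar * R * D)) / (delta * theta * theta)
        grad[lay.i_logtheta] = a_t - b_t * theta + theta * theta_bar

        if cfg.link == "probit":
            grad[lay.i_loglam] = a_l - b_l * lam
            if not self.prior_only:
                grad[lay.i_loglam] += (float(np.sum(y))
                                       - lam * float(np.sum(g * nu)))
        else:
            grad[lay.i_mu] = float(np.sum(u))
            delta_bar = -float(np.sum(Sbar * R)) / (delta * delta)
            grad[lay.i_logdelta] = a_d - b_d * delta + delta * delta_bar

        if self.mode_kind in ("deformation", "geometric"):
            # distance pullback: Dbar = -(Sbar*R)/(delta*theta); then
            # coord_bar_i = sum_j A_ij (d_i - d_j) with A = (Dbar+Dbar^T)/D
            with np.errstate(divide="ignore", invalid="ignore"):
                A = np.where(D > 0, -2.0 * (Sbar * R) / (delta * theta * D),
                             0.0)
            coord_bar = A.sum(axis=1)[:, None] * coords - A @ coords
            if self.mode_kind == "deformation":
                free_bar = coord_bar[self._free] * self._sigma_d[None, :]
                Wbar = self._L_cond.T @ free_bar
                grad[lay.sl_zd] = Wbar.ravel() - zd
            else:
                Tbar = coord_bar.T @ grid.centroids  # (2,2): dlp/dT
                dT_dpsi = np.diag([1.0, 1.0 / ratio]) @ np.array(
                    [[-s, c], [-c, -s]])
                dpsi_rad_dw = math.radians(180.0) * sig * (1.0 - sig)
                grad[lay.i_psi] = (float(np.sum(Tbar * dT_dpsi)) * dpsi_rad_dw
                                   + 1.0 - 2.0 * sig)
                dT_dr = np.diag([0.0, -1.0 / (ratio * ratio)]) @ rot
                r_bar = float(np.sum(Tbar * dT_dr))
                grad[lay.i_ratio] = a_r - b_r * ex + r_bar * ex

        return lp, grad

    def initial_raw(self, rng: np.random.Generator,
                    scale: float = 0.1) -> np.ndarray:
        """Random initial point near the prior centre with finite density."""
        raw = scale * rng.standard_normal(self.layout.size)
        lay, cfg = self.layout, self.config
        a_t, b_t = cfg.theta_prior
        raw[lay.i_logtheta] += math.log(a_t / b_t)
        if cfg.link == "probit":
            a_l, b_l = cfg.lambda_star_prior
            raw[lay.i_loglam] += math.log(a_l / b_l)
        else:
            n = max(self.counts.total, 1)
            raw[lay.i_mu] += math.log(n / self.grid.region.area)
            raw[lay.i_logdelta] += math.log(cfg.delta_prior[0]
                                            / cfg.delta_prior[1])
        return raw
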