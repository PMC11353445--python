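"""Interpolation of the deformation process at arbitrary coordinates.

The deformation prior is jointly Gaussian over any finite set of sites, so
given a posterior draw of the deformed centroids ``d_Z`` the deformation at
new target sites ``s_W`` follows the conditional multivariate normal

    vec(d_W) | vec(d_Z) ~ N(mu_{W|Z}, Sigma_{W|Z}),
    mu_{W|Z}    = vec(s_W) + (R12 R22^{-1} (x) I_2)(vec(d_Z) - vec(s_Z)),
    Sigma_{W|Z} = (R11 - R12 R22^{-1} R12^T) (x) sigma_d^2,

with R11, R12, R22 the cross-site prior correlations (exponential with
range phi) evaluated on *geographic* distances.  The default point estimate
is the conditional mean per draw; full conditional sampling is optional.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve

from .geometry import SpatialGrid
from .inference import PosteriorDraws
from .model import DeformationPrior, corr_exponential

__all__ = ["interpolate_deformation", "conditional_kernel"]


def _cross_dist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.sqrt(np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1))


def conditional_kernel(targets: np.ndarray, grid: SpatialGrid,
                       prior: DeformationPrior):
    """Kriging weights K = R12 R22^{-1} and conditional row covariance.

    Returns ``(K, Sigma_row)`` where ``Sigma_row = R11 - K R12^T``; the full
    conditional covariance is ``Sigma_row (x) diag(sigma_d^2)``.
    """
    cz = grid.centroids
    R22 = prior.row_corr(cz)  # jittered
    R12 = corr_exponential(_cross_dist(targets, cz), prior.phi)
    R11 = corr_exponential(_cross_dist(targets, targets), prior.phi)
    K = solve(R22, R12.T, assume_a="pos").T  # (W, Z)
    Sigma_row = R11 - K @ R12.T
    return K, Sigma_row


def interpolate_deformation(draws: PosteriorDraws, targets: np.ndarray,
                            prior: DeformationPrior | None = None,
                            sample: bool = False,
                            rng: np.random.Generator | int | None = None,
                            ) -> np.ndarray:
    """Deformed images of ``targets`` for every posterior draw.

    Parameters
    ----------
    draws
        Posterior draws from a deformation-mode fit.
    targets
        (W, 2) coordinates inside the study region.
    prior
        Deformation prior; defaults to the one the model was fitted with.
    sample
        If False (default) return the conditional mean per draw — the
        summary used for deformation maps.  If True add conditional noise,
        giving exact draws from the joint posterior of ``d_W``.

    Returns
    -------
    (n_draws, W, 2) array of deformed target coordinates.  A target that
    coincides with a centroid reproduces that draw's deformed centroid
    exactly (zero conditional variance).
    """
    if draws.d is None:
        raise ValueError("draws contain no deformation (mode was not "
                         "'deformation')")
    grid = draws.counts.grid
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if not np.all(grid.region.contains(targets)):
        raise ValueError("all interpolation targets must lie inside the "
                         "study region")
    if prior is None:
        prior = draws.config.deformation_prior
    K, Sigma_row = conditional_kernel(targets, grid, prior)
    dZ = draws.flat("d")                       # (n, Z, 2)
    resid = dZ - grid.centroids[None]          # (n, Z, 2)
    out = targets[None] + np.einsum("wz,nzk->nwk", K, resid)
    if sample:
        rng = (rng if isinstance(rng, np.random.Generator)
               else np.random.default_rng(rng))
        # PSD square root via eigendecomposition (conditional covariance
        # may be singular when targets coincide with centroids)
        w, V = np.linalg.eigh(0.5 * (Sigma_row + Sigma_row.T))
        w = np.clip(w, 0.0, None)
        Lr = V * np.sqrt(w)[None, :]
        sigma_d = np.asarray(prior.sigma_d, dtype=float)
        noise = rng.standard_normal((out.shape[0], targets.shape[0], 2))
        out = out + np.einsum("wv,nvk->nwk", Lr, noise) * sigma_d[None, None]
    return out
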