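"""Posterior sampling by dynamic Hamiltonian Monte Carlo.

The joint posterior is sampled in the non-centered raw space provided by
:class:`coxdeform.model.PosteriorDensity` using a dynamic HMC sampler
(no-U-turn tree doubling with slice sampling across the trajectory),
dual-averaging step-size adaptation towards a target acceptance statistic,
and a diagonal mass matrix estimated during warmup.  Convergence is
summarized with effective sample sizes and split R-hat (via arviz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .geometry import ObservedCounts
from .model import ModelConfig, PosteriorDensity

__all__ = ["PosteriorDraws", "fit", "diagnostics", "nuts"]

_MAX_ENERGY_ERROR = 1000.0  # divergence threshold on the joint log density


# ---------------------------------------------------------------------------
# Core NUTS kernel
# ---------------------------------------------------------------------------

def _leapfrog(density, q, p, grad, eps, inv_mass):
    p_half = p + 0.5 * eps * grad
    q_new = q + eps * inv_mass * p_half
    lp_new, grad_new = density.logp_and_grad(q_new)
    p_new = p_half + 0.5 * eps * grad_new
    return q_new, p_new, lp_new, grad_new


def _joint(lp, p, inv_mass):
    with np.errstate(over="ignore"):
        return lp - 0.5 * float(np.sum(p * p * inv_mass))


class _Tree:
    """One NUTS trajectory tree (recursive doubling)."""

    __slots__ = ("density", "inv_mass", "eps", "logu", "H0", "rng",
                 "n_alpha", "alpha_sum", "diverged", "n_grad")

    def __init__(self, density, inv_mass, eps, logu, H0, rng):
        self.density = density
        self.inv_mass = inv_mass
        self.eps = eps
        self.logu = logu
        self.H0 = H0
        self.rng = rng
        self.n_alpha = 0
        self.alpha_sum = 0.0
        self.diverged = False
        self.n_grad = 0

    def build(self, q, p, grad, lp, v, j):
        """Returns (q-, p-, g-, lp-, q+, p+, g+, lp+, (q', g', lp'), n', s')."""
        if j == 0:
            qn, pn, lpn, gn = _leapfrog(self.density, q, p, grad,
                                        v * self.eps, self.inv_mass)
            self.n_grad += 1
            H = _joint(lpn, pn, self.inv_mass)
            n_new = 1 if self.logu <= H else 0
            s_new = 1 if self.logu < H + _MAX_ENERGY_ERROR else 0
            if s_new == 0 or not np.isfinite(H):
                self.diverged = True
                s_new = 0
            self.alpha_sum += min(1.0, math.exp(min(0.0, H - self.H0)))
            self.n_alpha += 1
            return qn, pn, gn, lpn, qn, pn, gn, lpn, (qn, gn, lpn), n_new, s_new
        (qm, pm, gm, lpm, qp, pp, gp, lpp, prop, n1, s1) = \
            self.build(q, p, grad, lp, v, j - 1)
        if s1 == 1:
            if v == -1:
                (qm, pm, gm, lpm, _, _, _, _, prop2, n2, s2) = \
                    self.build(qm, pm, gm, lpm, v, j - 1)
            else:
                (_, _, _, _, qp, pp, gp, lpp, prop2, n2, s2) = \
                    self.build(qp, pp, gp, lpp, v, j - 1)
            if n1 + n2 > 0 and self.rng.uniform() < n2 / (n1 + n2):
                prop = prop2
            dq = qp - qm
            s1 = (s2
                  & (np.dot(dq, pm * self.inv_mass) >= 0)
                  & (np.dot(dq, pp * self.inv_mass) >= 0))
            n1 = n1 + n2
        return qm, pm, gm, lpm, qp, pp, gp, lpp, prop, n1, s1


def _nuts_step(density, q, lp, grad, eps, inv_mass, rng, max_treedepth):
    p0 = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    H0 = _joint(lp, p0, inv_mass)
    logu = H0 + math.log(rng.uniform())
    tree = _Tree(density, inv_mass, eps, logu, H0, rng)
    qm = qp = q
    pm = pp = p0
    gm = gp = grad
    lpm = lpp = lp
    q_cur, lp_cur, g_cur = q, lp, grad
    n, s, depth = 1, 1, 0
    while s == 1 and depth < max_treedepth:
        v = 1 if rng.uniform() < 0.5 else -1
        if v == -1:
            (qm, pm, gm, lpm, _, _, _, _, prop, n2, s2) = \
                tree.build(qm, pm, gm, lpm, v, depth)
        else:
            (_, _, _, _, qp, pp, gp, lpp, prop, n2, s2) = \
                tree.build(qp, pp, gp, lpp, v, depth)
        if s2 == 1 and n2 > 0 and rng.uniform() < min(1.0, n2 / n):
            q_cur, g_cur, lp_cur = prop
        n += n2
        dq = qp - qm
        s = (s2
             & (np.dot(dq, pm * inv_mass) >= 0)
             & (np.dot(dq, pp * inv_mass) >= 0))
        depth += 1
    accept_stat = tree.alpha_sum / max(tree.n_alpha, 1)
    return q_cur, lp_cur, g_cur, accept_stat, depth, tree.diverged


@dataclass
class _DualAveraging:
    """Nesterov dual averaging of log step size (Stan's schedule)."""

    mu: float
    gamma: float = 0.05
    t0: float = 10.0
    kappa: float = 0.75
    count: int = 0
    h_bar: float = 0.0
    log_eps_bar: float = 0.0

    def update(self, accept_stat: float, target: float) -> float:
        self.count += 1
        w = 1.0 / (self.count + self.t0)
        self.h_bar = (1 - w) * self.h_bar + w * (target - accept_stat)
        log_eps = self.mu - math.sqrt(self.count) / self.gamma * self.h_bar
        w2 = self.count ** (-self.kappa)
        self.log_eps_bar = w2 * log_eps + (1 - w2) * self.log_eps_bar
        return math.exp(log_eps)


def _find_initial_eps(density, q, lp, grad, inv_mass, rng) -> float:
    eps = 1.0
    p = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    H0 = _joint(lp, p, inv_mass)
    _, p1, lp1, _ = _leapfrog(density, q, p, grad, eps, inv_mass)
    H1 = _joint(lp1, p1, inv_mass)
    dH = H1 - H0 if np.isfinite(H1) else -np.inf
    direction = 1 if dH > math.log(0.5) else -1
    for _ in range(60):
        eps *= 2.0 ** direction
        _, p1, lp1, _ = _leapfrog(density, q, p, grad, eps, inv_mass)
        H1 = _joint(lp1, p1, inv_mass)
        dH = H1 - H0 if np.isfinite(H1) else -np.inf
        if (direction == 1 and dH <= math.log(0.5)) or \
           (direction == -1 and dH > math.log(0.5)):
            break
    return eps


def nuts(density: PosteriorDensity, raw0: np.ndarray, n_iter: int,
         n_warmup: int, rng: np.random.Generator, max_treedepth: int = 8,
         target_accept: float = 0.8) -> dict[str, Any]:
    """Run one NUTS chain; returns post-warmup raw draws and statistics."""
    q = np.asarray(raw0, dtype=float).copy()
    lp, grad = density.logp_and_grad(q)
    if not np.isfinite(lp):
        raise ValueError("non-finite initial log-posterior")
    dim = q.size
    inv_mass = np.ones(dim)
    eps = _find_initial_eps(density, q, lp, grad, inv_mass, rng)
    da = _DualAveraging(mu=math.log(10.0 * eps))
    # warmup windows: 15% step-size only, 70% variance window, 15% final
    w_var_lo = int(0.15 * n_warmup)
    w_var_hi = int(0.85 * n_warmup)
    var_buf: list[np.ndarray] = []
    keep = np.empty((n_iter - n_warmup, dim))
    divergences = 0
    accept_sum = 0.0
    depth_sum = 0
    for it in range(n_iter):
        q, lp, grad, astat, depth, div = _nuts_step(
            density, q, lp, grad, eps, inv_mass, rng, max_treedepth)
        if it < n_warmup:
            eps = da.update(astat, target_accept)
            if w_var_lo <= it < w_var_hi and n_warmup >= 100:
                var_buf.append(q.copy())
            if it == w_var_hi - 1 and len(var_buf) >= 20:
                samples = np.asarray(var_buf)
                n = samples.shape[0]
                var = samples.var(axis=0, ddof=1)
                var = n / (n + 5.0) * var + (5.0 / (n + 5.0)) * 1e-3
                inv_mass = var  # inverse mass = posterior variance estimate
                lp, grad = density.logp_and_grad(q)
                eps = _find_initial_eps(density, q, lp, grad, inv_mass, rng)
                da = _DualAveraging(mu=math.log(10.0 * eps))
            if it == n_warmup - 1:
                eps = math.exp(da.log_eps_bar)
        else:
            keep[it - n_warmup] = q
            divergences += int(div)
            accept_sum += astat
            depth_sum += depth
    n_keep = n_iter - n_warmup
    return {
        "raws": keep,
        "divergences": divergences,
        "step_size": eps,
        "mean_accept": accept_sum / max(n_keep, 1),
        "mean_treedepth": depth_sum / max(n_keep, 1),
    }


# ---------------------------------------------------------------------------
# Draw container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Stored posterior draws with per-cell intensity and run metadata.

    Array shapes are ``(chains, draws)`` for scalars, ``(chains, draws, Z)``
    for the latent field and intensity, and ``(chains, draws, Z, 2)`` for
    the deformation.  Scalar entries not sampled under the given link/mode
    (e.g. ``lambda_star`` under the log link) are stored at their fixed
    values so every draw reconstructs a complete model state.
    """

    config: ModelConfig
    counts: ObservedCounts
    beta: np.ndarray
    theta: np.ndarray
    lambda_star: np.ndarray
    mu: np.ndarray
    delta: np.ndarray
    d: np.ndarray | None = None
    psi_deg: np.ndarray | None = None
    ratio: np.ndarray | None = None
    report: dict[str, Any] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.theta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.theta.shape[1]

    @property
    def Z(self) -> int:
        return self.beta.shape[2]

    def intensity(self) -> np.ndarray:
        """Per-draw per-cell intensity lambda_star g(mu + beta), flattened
        over chains: shape (chains*draws, Z)."""
        link = self.config.link_spec
        eta = self.mu[..., None] + self.beta
        lam = self.lambda_star[..., None] * link.g(eta)
        return lam.reshape(-1, self.Z)

    def flat(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        if arr is None:
            raise ValueError(f"{name} was not sampled in this fit")
        return arr.reshape(-1, *arr.shape[2:])

    def posterior_mean_intensity(self) -> np.ndarray:
        return self.intensity().mean(axis=0)

    def deformation_distance_summary(self) -> pd.DataFrame:
        """Posterior mean and SD of ||s_z - d(s_z)|| per cell."""
        if self.d is None:
            raise ValueError("no deformation draws in this fit")
        s = self.counts.grid.centroids
        dist = np.linalg.norm(self.flat("d") - s[None], axis=-1)
        return pd.DataFrame({
            "cell_id": np.arange(self.Z),
            "mean_displacement": dist.mean(axis=0),
            "sd_displacement": dist.std(axis=0, ddof=1),
        })

    # -- long-format persistence -------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        C, N, Z = self.n_chains, self.n_draws, self.Z
        chain = np.repeat(np.arange(C), N)
        draw = np.tile(np.arange(N), C)

        def add(name, values, index):
            rows.append(pd.DataFrame({
                "chain": np.repeat(chain, 1 if values.ndim == 1 else values.shape[1]),
                "draw": np.repeat(draw, 1 if values.ndim == 1 else values.shape[1]),
                "param": name,
                "index": (np.zeros(len(chain), dtype=int) if values.ndim == 1
                          else np.tile(index, C * N)),
                "value": values.ravel(),
            }))

        add("theta", self.theta.reshape(-1), None)
        add("lambda_star", self.lambda_star.reshape(-1), None)
        add("mu", self.mu.reshape(-1), None)
        add("delta", self.delta.reshape(-1), None)
        add("beta", self.beta.reshape(-1, Z), np.arange(Z))
        if self.d is not None:
            add("d_x", self.d[..., 0].reshape(-1, Z), np.arange(Z))
            add("d_y", self.d[..., 1].reshape(-1, Z), np.arange(Z))
        if self.psi_deg is not None:
            add("psi_deg", self.psi_deg.reshape(-1), None)
            add("ratio", self.ratio.reshape(-1), None)
        return pd.concat(rows, ignore_index=True)

    @staticmethod
    def from_dataframe(df: pd.DataFrame, counts: ObservedCounts,
                       config: ModelConfig,
                       report: dict | None = None) -> "PosteriorDraws":
        C = int(df["chain"].max()) + 1
        N = int(df["draw"].max()) + 1
        Z = counts.grid.Z

        def get_scalar(name):
            sub = df[df["param"] == name].sort_values(["chain", "draw"])
            return sub["value"].to_numpy().reshape(C, N)

        def get_vec(name):
            sub = df[df["param"] == name].sort_values(["chain", "draw", "index"])
            return sub["value"].to_numpy().reshape(C, N, Z)

        kw: dict[str, Any] = dict(
            theta=get_scalar("theta"), lambda_star=get_scalar("lambda_star"),
            mu=get_scalar("mu"), delta=get_scalar("delta"),
            beta=get_vec("beta"))
        if (df["param"] == "d_x").any():
            kw["d"] = np.stack([get_vec("d_x"), get_vec("d_y")], axis=-1)
        if (df["param"] == "psi_deg").any():
            kw["psi_deg"] = get_scalar("psi_deg")
            kw["ratio"] = get_scalar("ratio")
        return PosteriorDraws(config=config, counts=counts,
                              report=report or {}, **kw)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit(counts: ObservedCounts, config: ModelConfig, seed: int,
        chains: int = 4, iters: int = 1500, warmup: int | None = None,
        max_treedepth: int = 8, target_accept: float = 0.8,
        prior_only: bool = False, centered_beta: bool = False,
        divergence_warn_frac: float = 0.05) -> PosteriorDraws:
    """Sample the joint posterior with NUTS.

    ``iters`` is the total iteration count per chain; ``warmup`` (default
    half) iterations are used for adaptation and discarded.  Runs are
    deterministic given ``(seed, chains, iters)``.
    """
    if warmup is None:
        warmup = iters // 2
    if not 0 < warmup < iters:
        raise ValueError("need 0 < warmup < iters")
    density = PosteriorDensity(counts, config, prior_only=prior_only,
                               centered_beta=centered_beta)
    seeds = np.random.SeedSequence(seed).spawn(chains)
    chain_results = []
    for c in range(chains):
        rng = np.random.default_rng(seeds[c])
        raw0 = None
        for _ in range(20):
            cand = density.initial_raw(rng, scale=0.1)
            if np.isfinite(density.logp(cand)):
                raw0 = cand
                break
        if raw0 is None:
            raise ValueError("non-finite initial log-posterior; check data "
                             "and priors")
        chain_results.append(nuts(density, raw0, iters, warmup, rng,
                                  max_treedepth, target_accept))

    n_keep = iters - warmup
    Z = counts.grid.Z
    beta = np.empty((chains, n_keep, Z))
    theta = np.empty((chains, n_keep))
    lam = np.empty((chains, n_keep))
    mu = np.empty((chains, n_keep))
    delta = np.empty((chains, n_keep))
    d = (np.empty((chains, n_keep, Z, 2))
         if config.mode == "deformation" else None)
    psi = np.empty((chains, n_keep)) if config.mode == "geometric" else None
    ratio = np.empty((chains, n_keep)) if config.mode == "geometric" else None
    for c, res in enumerate(chain_results):
        for i, raw in enumerate(res["raws"]):
            st = density.unpack(raw)
            beta[c, i] = st.beta
            theta[c, i] = st.hyper.theta
            lam[c, i] = st.hyper.lambda_star
            mu[c, i] = st.hyper.mu
            delta[c, i] = st.hyper.delta
            if d is not None:
                d[c, i] = st.deformation.d
            if psi is not None:
                psi[c, i] = st.mode.psi_deg
                ratio[c, i] = st.mode.ratio

    total_div = sum(r["divergences"] for r in chain_results)
    report = {
        "link": config.link,
        "mode": config.mode,
        "chains": chains,
        "iters": iters,
        "warmup": warmup,
        "seed": seed,
        "divergences": total_div,
        "divergence_fraction": total_div / (chains * n_keep),
        "step_sizes": [r["step_size"] for r in chain_results],
        "mean_accept": float(np.mean([r["mean_accept"]
                                      for r in chain_results])),
        "mean_treedepth": float(np.mean([r["mean_treedepth"]
                                         for r in chain_results])),
        "warnings": [],
    }
    if report["divergence_fraction"] > divergence_warn_frac:
        report["warnings"].append(
            f"divergent transitions in {report['divergence_fraction']:.1%} "
            "of post-warmup iterations; estimates may be biased")
    draws = PosteriorDraws(config=config, counts=counts, beta=beta,
                           theta=theta, lambda_star=lam, mu=mu, delta=delta,
                           d=d, psi_deg=psi, ratio=ratio, report=report)
    diag = diagnostics(draws)
    report["max_rhat"] = (float(diag["rhat"].max())
                          if "rhat" in diag else None)
    report["min_ess"] = float(diag["ess"].min())
    if report["max_rhat"] is not None and report["max_rhat"] > 1.05:
        report["warnings"].append(
            f"max split R-hat {report['max_rhat']:.3f} > 1.05; chains may "
            "not have mixed")
    return draws


def diagnostics(draws: PosteriorDraws) -> pd.DataFrame:
    """ESS and split R-hat per parameter (R-hat omitted for single chains)."""
    import warnings

    import arviz as az

    post: dict[str, np.ndarray] = {"theta": draws.theta, "beta": draws.beta}
    if draws.config.link_spec.needs_lambda_star:
        post["lambda_star"] = draws.lambda_star
    else:
        post["mu"] = draws.mu
        post["delta"] = draws.delta
    if draws.psi_deg is not None:
        post["psi_deg"] = draws.psi_deg
        post["ratio"] = draws.ratio
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=post)
        ess = az.ess(idata)
        rhat = az.rhat(idata) if draws.n_chains >= 2 else None

    rows = []
    for name, arr in post.items():
        if arr.ndim == 2:
            row = {"param": name, "ess": float(ess[name].values)}
            if rhat is not None:
                row["rhat"] = float(rhat[name].values)
            rows.append(row)
        else:
            for z in range(arr.shape[2]):
                row = {"param": f"{name}[{z}]",
                       "ess": float(ess[name].values[z])}
                if rhat is not None:
                    row["rhat"] = float(rhat[name].values[z])
                rows.append(row)
    return pd.DataFrame(rows)
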