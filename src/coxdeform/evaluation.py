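"""Model comparison and accuracy criteria.

All criteria act on the per-cell intensity ``lambda_z = lambda_star
g(mu + beta_z)`` (not the expected count ``lambda_z nu_z``) except the
predictive ones, which use the per-cell Poisson likelihood of the observed
counts:

- MAE: mean absolute error of the posterior mean intensity against a known
  truth (simulation studies only);
- IS / AIS: Winkler interval score of the central 95% posterior interval,
  averaged over cells;
- CPO / slCPO: per-cell conditional predictive ordinate estimated by the
  harmonic-mean identity over posterior draws, summed on the log scale;
- DIC: posterior mean deviance plus the effective number of parameters
  ``pD``, with the plug-in deviance evaluated at the posterior mean of the
  per-cell linear predictor and of the scalar intensity parameters.

The Poisson ``y!`` constants are included in lCPO (so values are proper log
predictive ordinates) and kept consistently in both deviance terms of the
DIC, so comparisons across link functions are on a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .geometry import ObservedCounts
from .inference import PosteriorDraws

__all__ = [
    "mae",
    "interval_score",
    "averaged_interval_score",
    "slcpo",
    "dic",
    "ComparisonReport",
    "evaluate",
    "compare",
]


def mae(posterior_mean_intensity: np.ndarray,
        true_intensity: np.ndarray) -> float:
    """Mean absolute error between estimated and true per-cell intensity."""
    est = np.asarray(posterior_mean_intensity, dtype=float)
    tru = np.asarray(true_intensity, dtype=float)
    if est.shape != tru.shape:
        raise ValueError(f"length mismatch: {est.shape} vs {tru.shape}")
    return float(np.mean(np.abs(est - tru)))


def interval_score(lower, upper, truth, alpha: float = 0.05):
    """Winkler interval score of a central (1-alpha) interval.

    ``(u - l) + (2/alpha)(l - x) 1{x < l} + (2/alpha)(x - u) 1{x > u}``;
    negatively oriented (smaller is better).
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if np.any(lower > upper):
        raise ValueError("interval has lower > upper")
    return ((upper - lower)
            + (2.0 / alpha) * (lower - truth) * (truth < lower)
            + (2.0 / alpha) * (truth - upper) * (truth > upper))


def averaged_interval_score(intensity_draws: np.ndarray,
                            true_intensity: np.ndarray,
                            alpha: float = 0.05):
    """Per-cell IS of the central posterior interval, and its mean (AIS)."""
    lo = np.percentile(intensity_draws, 100 * alpha / 2, axis=0)
    hi = np.percentile(intensity_draws, 100 * (1 - alpha / 2), axis=0)
    per_cell = interval_score(lo, hi, true_intensity, alpha)
    return float(per_cell.mean()), per_cell


def _percell_loglik(intensity_draws: np.ndarray,
                    counts: ObservedCounts) -> np.ndarray:
    """(n_draws, Z) Poisson log likelihood of each cell count per draw."""
    m = intensity_draws * counts.grid.cell_measures[None, :]
    y = counts.y[None, :]
    with np.errstate(divide="ignore"):
        out = y * np.log(m) - m - gammaln(counts.y + 1.0)[None, :]
    return np.where((y == 0) & (m == 0), -m, out)


def slcpo(draws: PosteriorDraws | np.ndarray,
          counts: ObservedCounts) -> tuple[float, np.ndarray]:
    """Sum of log conditional predictive ordinates, and per-cell lCPO.

    CPO_z is the harmonic mean over posterior draws of the per-cell
    likelihood, computed stably on the log scale.
    """
    lam = draws.intensity() if isinstance(draws, PosteriorDraws) else draws
    n = lam.shape[0]
    if n < 2:
        raise ValueError("need at least 2 draws for CPO")
    ll = _percell_loglik(lam, counts)            # (n, Z)
    lcpo = np.log(n) - logsumexp(-ll, axis=0)    # log harmonic mean
    return float(lcpo.sum()), lcpo


def dic(draws: PosteriorDraws, counts: ObservedCounts) -> float:
    """Deviance information criterion ``DIC = Dbar + pD = 2 Dbar - Dhat``.

    The plug-in point is the posterior mean of the per-cell linear
    predictor ``mu + beta_z`` together with the posterior means of
    ``lambda_star`` and ``mu``.
    """
    lam = draws.intensity()
    if lam.shape[0] < 2:
        raise ValueError("need at least 2 draws for DIC")
    d_bar = float(np.mean(-2.0 * _percell_loglik(lam, counts).sum(axis=1)))
    link = draws.config.link_spec
    eta_hat = (draws.mu[..., None] + draws.beta).reshape(-1, draws.Z) \
        .mean(axis=0)
    lam_hat = draws.lambda_star.mean() * link.g(eta_hat)
    d_hat = float(-2.0 * _percell_loglik(lam_hat[None, :], counts).sum())
    return 2.0 * d_bar - d_hat


@dataclass
class ComparisonReport:
    """Criteria for one fitted model on one dataset."""

    link: str
    mode: str
    slcpo: float
    dic: float
    data_hash: str
    mae: float | None = None
    ais: float | None = None
    per_cell_is: np.ndarray | None = field(default=None, repr=False)
    per_cell_lcpo: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        out = {"link": self.link, "mode": self.mode, "slcpo": self.slcpo,
               "dic": self.dic, "data_hash": self.data_hash}
        if self.mae is not None:
            out["mae"] = self.mae
        if self.ais is not None:
            out["ais"] = self.ais
        return out


def evaluate(draws: PosteriorDraws, counts: ObservedCounts,
             true_intensity: np.ndarray | None = None,
             alpha: float = 0.05) -> ComparisonReport:
    """Compute every applicable criterion for one fit.

    MAE and AIS require a known true intensity (simulation studies); slCPO
    and DIC are always available.
    """
    lam = draws.intensity()
    s, lcpo_cells = slcpo(draws, counts)
    report = ComparisonReport(
        link=draws.config.link, mode=draws.config.mode, slcpo=s,
        dic=dic(draws, counts), data_hash=counts.data_hash(),
        per_cell_lcpo=lcpo_cells)
    if true_intensity is not None:
        report.mae = mae(lam.mean(axis=0), true_intensity)
        report.ais, report.per_cell_is = averaged_interval_score(
            lam, true_intensity, alpha)
    return report


def compare(reports: list[ComparisonReport]) -> pd.DataFrame:
    """Rank fitted models by DIC; flag the best value of each criterion.

    All reports must refer to the same observed counts.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    hashes = {r.data_hash for r in reports}
    if len(hashes) != 1:
        raise ValueError("reports were computed on different datasets")
    df = pd.DataFrame([r.to_dict() for r in reports]).drop(
        columns="data_hash")
    df = df.sort_values("dic").reset_index(drop=True)
    for col in ("mae", "ais", "dic"):
        if col in df:
            df[f"best_{col}"] = df[col] == df[col].min()
    df["best_slcpo"] = df["slcpo"] == df["slcpo"].max()
    return df
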