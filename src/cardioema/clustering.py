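"""Within-person Dirichlet-process Gaussian-mixture clustering.

Each participant's standardized 6-D change scores are fit with a
stick-breaking (truncated) DP mixture of full-covariance Gaussians by
variational inference; the truncation equals the number of events, so the
prior — not a preset K — decides how many components carry mass.  Events
receive posterior membership probabilities over *every* component; clusters
holding at least 5% of the soft event mass are retained, and events whose
most probable component is unretained are labelled unclustered ("UC").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from sklearn.cluster import KMeans
from sklearn.mixture import BayesianGaussianMixture

#: a cluster must hold at least this fraction of soft event mass
MIN_CLUSTER_FRACTION = 0.05

UNCLUSTERED = "UC"


@dataclass
class DPGMMConfig:
    truncation: Optional[int] = None      # None -> number of events
    concentration_prior: Optional[float] = None  # None -> 1 / truncation
    covariance_type: str = "full"
    max_iter: int = 2000
    tol: float = 1e-3
    n_restarts: int = 5
    #: k-means granularities used to initialize successive restarts; restarts
    #: beyond the grid fall back to sklearn's default initialization
    init_k_grid: tuple = (1, 2, 3, 5, 8, 4, 6, 10, 12, 15)
    seed: int = 0


class _KMeansInitBGM(BayesianGaussianMixture):
    """DP-GMM whose variational optimization starts from a k-means partition.

    With the truncation at the number of events, the stock initialization
    assigns every point its own component and variational inference tends to
    stall in fragmented local optima.  Seeding the responsibilities from a
    k-means solution at a plausible granularity (the stick-breaking prior
    still decides the final number of populated components) gives restarts
    at different granularities; the best evidence lower bound wins.
    """

    def __init__(self, init_k=None, **kwargs):
        self.init_k = init_k
        super().__init__(**kwargs)

    def _initialize_parameters(self, X, random_state, **kwargs):
        if self.init_k is None or self.init_k > X.shape[0]:
            return super()._initialize_parameters(X, random_state, **kwargs)
        km = KMeans(n_clusters=self.init_k, n_init=5,
                    random_state=random_state).fit(X)
        resp = np.zeros((X.shape[0], self.n_components))
        resp[np.arange(X.shape[0]), km.labels_] = 1.0
        self._initialize(X, resp)


@dataclass
class ClusterSolution:
    """Per-participant mixture fit with soft memberships."""

    component_means: np.ndarray        # (K_eff, 6), z-space
    component_covariances: np.ndarray  # (K_eff, 6, 6)
    mixture_weights: np.ndarray        # (K_eff,)
    membership: np.ndarray             # (n, K_eff), rows sum to 1
    retained_ids: list = field(default_factory=list)
    elbo: float = np.nan

    @property
    def n_events(self) -> int:
        return self.membership.shape[0]

    @property
    def size_fractions(self) -> np.ndarray:
        """Soft cluster sizes: column sums of membership / n."""
        return self.membership.sum(axis=0) / self.n_events

    @property
    def unclustered_mass(self) -> float:
        """Fraction of soft event mass outside the retained clusters."""
        return float(1.0 - self.size_fractions[self.retained_ids].sum())

    def hard_labels(self) -> list:
        """Max-probability labels; unretained components map to 'UC'."""
        arg = self.membership.argmax(axis=1)
        retained = set(self.retained_ids)
        return [int(k) if k in retained else UNCLUSTERED for k in arg]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "component_means": self.component_means.tolist(),
            "component_covariances": self.component_covariances.tolist(),
            "mixture_weights": self.mixture_weights.tolist(),
            "retained_ids": self.retained_ids,
            "elbo": self.elbo,
        }))


def fit_dpgmm(z_matrix: np.ndarray, cfg: Optional[DPGMMConfig] = None,
              ) -> ClusterSolution:
    """Variational fit of the DP Gaussian mixture to an n x 6 z-matrix.

    Runs ``n_restarts`` restarts with seeds split from ``cfg.seed`` and keeps
    the solution with the best evidence lower bound.  Components carrying no
    posterior mass are dropped and rows renormalized (the discarded mass is
    below 1e-8 per row).  Raises when no restart converges.
    """
    cfg = cfg or DPGMMConfig()
    X = np.asarray(z_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 10:
        raise ValueError("need an n x d matrix with n >= 10")
    if not np.all(np.isfinite(X)):
        raise ValueError("z matrix contains missing values")
    n = X.shape[0]
    trunc = cfg.truncation or n
    if trunc > n:
        raise ValueError("truncation cannot exceed the number of events")
    conc = cfg.concentration_prior or 1.0 / trunc

    seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_restarts)
    best, diagnostics = None, []
    for r, s in enumerate(seeds):
        init_k = cfg.init_k_grid[r] if r < len(cfg.init_k_grid) else None
        model = _KMeansInitBGM(
            init_k=init_k,
            n_components=trunc, covariance_type=cfg.covariance_type,
            weight_concentration_prior_type="dirichlet_process",
            weight_concentration_prior=conc, max_iter=cfg.max_iter,
            tol=cfg.tol, random_state=int(s % (2 ** 31)), reg_covar=1e-6,
        ).fit(X)
        diagnostics.append((int(s), model.converged_, model.lower_bound_))
        if model.converged_ and (best is None
                                 or model.lower_bound_ > best.lower_bound_):
            best = model
    if best is None:
        raise RuntimeError(f"DP-GMM did not converge in any restart: "
                           f"{diagnostics}")

    resp = best.predict_proba(X)
    mass = resp.sum(axis=0)
    keep = np.flatnonzero(mass > 1e-8)
    resp = resp[:, keep]
    resp = resp / resp.sum(axis=1, keepdims=True)
    sol = ClusterSolution(
        component_means=best.means_[keep],
        component_covariances=best.covariances_[keep],
        mixture_weights=best.weights_[keep] / best.weights_[keep].sum(),
        membership=resp, elbo=float(best.lower_bound_),
    )
    return retain_clusters(sol)


def retain_clusters(sol: ClusterSolution,
                    min_frac: float = MIN_CLUSTER_FRACTION) -> ClusterSolution:
    """Set ``retained_ids`` to clusters holding >= ``min_frac`` of events."""
    sol.retained_ids = [int(k) for k in
                        np.flatnonzero(sol.size_fractions >= min_frac)]
    return sol


def weighted_cluster_means(sol: ClusterSolution,
                           raw_changes: np.ndarray) -> dict:
    """Probability-weighted mean raw change per retained cluster.

    mean_k = sum_i p_ik c_i / sum_i p_ik — every event contributes to every
    retained cluster in proportion to its membership.
    """
    C = np.asarray(raw_changes, dtype=float)
    if C.shape[0] != sol.n_events:
        raise ValueError("raw changes not aligned with membership rows")
    out = {}
    for k in sol.retained_ids:
        w = sol.membership[:, k]
        total = w.sum()
        assert total > 0, "retained cluster with zero mass"
        out[k] = (w[:, None] * C).sum(axis=0) / total
    return out


def membership_quality(sol: ClusterSolution) -> float:
    """Mean over events of the maximum membership probability."""
    return float(sol.membership.max(axis=1).mean())


def select_k_bic(X: np.ndarray, k_max: int = 10, seed: int = 0) -> int:
    """Cross-check utility: BIC-optimal component count of a standard GMM."""
    from sklearn.mixture import GaussianMixture
    X = np.asarray(X, dtype=float)
    bics = [GaussianMixture(n_components=k, covariance_type="full",
                            random_state=seed, n_init=3).fit(X).bic(X)
            for k in range(1, k_max + 1)]
    return int(np.argmin(bics)) + 1
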