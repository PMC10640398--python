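"""The integrated SPAN model: NB mixture + HMRF, trained by EM and ICM.

Training follows a pretrain-then-refine scheme. The NB mixture is first
fitted by EM alone (no spatial term); its hard responsibilities seed the
label field. The main loop then alternates three updates until the
fraction of labels changing in a sweep drops to ``label_change_tol``
(default 0.1%) or ``max_icm_iters`` is reached:

1. mixture parameters: gradient ascent on the hard-label conditional
   likelihood L2 (plus the delta prior), warm-started;
2. field parameters: pseudolikelihood ascent (``fit_hmrf``);
3. one ICM sweep: spots visited in ascending index order, each set to the
   type maximizing NB log-likelihood + field logit given the *current*
   neighbor labels (updated within the sweep); ties go to the smallest
   type index.

The mixing weights pi act only during pretraining; the final per-spot
posterior is the softmax of likelihood + field scores and carries no pi
term.

``SPANModel``/``SPANResults`` expose this in the usual Model/Results
idiom; the module-level functions (``fit_span``, ``icm_sweep``, ...) are
the underlying operations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import log_softmax

from . import nb_mixture as nbm
from .graph import NeighborGraph, SpotCoordinates, build_grid_graph, build_knn_graph, neighbor_type_counts
from .hmrf import HMRFParams, fit_hmrf, pseudolikelihood
from .nb_mixture import (
    CountMatrix,
    HyperParams,
    MarkerMatrix,
    MixtureParams,
    compute_size_factors,
    fit_mixture,
    loglik_matrix,
)

__all__ = ["SPANConfig", "SPANResults", "SPANModel", "conditional_log_likelihood",
           "icm_sweep", "fit_span"]

logger = logging.getLogger(__name__)


@dataclass
class SPANConfig:
    """Tuning knobs of the fit.

    Defaults: Adam learning rate 0.01 everywhere, B = 10 RBF centers, at
    most 20 ICM iterations, stopping when fewer than 0.1% of labels change
    in a sweep; 30 gradient steps per mixture update and 50 per field
    update; pretraining runs EM to a loose tolerance (1e-4, <= 50
    iterations). Spots are swept in ascending index order.
    """

    learning_rate: float = 0.01
    B: int = 10
    max_icm_iters: int = 20
    label_change_tol: float = 0.001
    n_grad_steps_gamma: int = 30
    n_grad_steps_phi: int = 50
    pretrain_tol: float = 1e-4
    pretrain_max_iters: int = 50
    pretrain_grad_steps: int = 30
    delta_bar: float = 0.0
    sigma2: float = 1.0
    alpha: float = 0.01
    seed: int = 0
    spatial: bool = True  # False freezes the field at zero (mixture-only ablation)

    def __post_init__(self):
        if not (0.0 < self.label_change_tol < 1.0):
            raise ValueError("label_change_tol must lie in (0, 1)")
        for name in ("B", "max_icm_iters", "n_grad_steps_gamma", "n_grad_steps_phi"):
            if getattr(self, name) < 0 or (name == "B" and self.B < 1):
                raise ValueError(f"{name} must be a nonnegative count (B >= 1)")

    def hyper(self) -> HyperParams:
        return HyperParams(self.delta_bar, self.sigma2, self.alpha, self.B)


def conditional_log_likelihood(Y, z, mixture_params: MixtureParams, s, X, rho) -> float:
    """L2: total NB log-likelihood of the counts under the hard labels."""
    z = np.asarray(z)
    L = loglik_matrix(Y, mixture_params, s, X, rho)
    return float(L[np.arange(len(z)), z].sum())


def icm_sweep(Y, z, graph: NeighborGraph, mixture_params: MixtureParams,
              hmrf_params: HMRFParams, s, X, rho):
    """One sequential ICM sweep over all spots in ascending index order.

    Each spot is set to ``argmax_k [loglik_ik + eta_k - sum_l zeta_kl u_i(l)]``
    where the neighbor counts ``u_i`` reflect labels already updated earlier
    in the sweep. Returns the new labels, the softmax posterior of the score
    vectors at visit time, and the fraction of spots whose label changed.
    """
    z = np.array(z, copy=True)
    K = mixture_params.delta_raw.shape[1]
    L = loglik_matrix(Y, mixture_params, s, X, rho)  # (N, K)
    zeta = hmrf_params.effective_zeta()
    eta = hmrf_params.eta
    u = neighbor_type_counts(graph, z, K).astype(float)
    posterior = np.empty_like(L)
    changed = 0
    for i in range(graph.n_spots):
        scores = L[i] + eta - zeta @ u[i]
        k_new = int(np.argmax(scores))  # argmax ties -> smallest index
        posterior[i] = np.exp(log_softmax(scores))
        if k_new != z[i]:
            k_old = z[i]
            z[i] = k_new
            changed += 1
            for j in graph.adjacency[i]:
                u[j, k_old] -= 1.0
                u[j, k_new] += 1.0
    return z, posterior, changed / max(graph.n_spots, 1)


@dataclass
class SPANResults:
    """Fit results: hard labels, per-spot assignment posterior, fitted
    parameters and per-iteration training history."""

    model: "SPANModel | None"
    z: np.ndarray
    posterior: np.ndarray
    mixture_params: MixtureParams
    hmrf_params: HMRFParams
    history: list[dict]
    converged: bool
    config: SPANConfig

    @property
    def type_names(self) -> list[str]:
        if self.model is not None:
            return self.model.markers.type_names
        return [f"type_{k}" for k in range(self.posterior.shape[1])]

    @property
    def labels(self) -> np.ndarray:
        names = np.asarray(self.type_names, dtype=object)
        return names[self.z]

    @property
    def confidence(self) -> np.ndarray:
        """Posterior probability of the assigned type, per spot."""
        return self.posterior[np.arange(len(self.z)), self.z]

    def summary(self) -> str:
        K = self.posterior.shape[1]
        lines = ["SPAN spatial cell-type assignment", "=" * 46]
        lines.append(f"spots: {len(self.z)}    types: {K}")
        lines.append(f"ICM iterations: {len(self.history)}    converged: {self.converged}")
        if self.history:
            lines.append(
                f"final label-change fraction: {self.history[-1]['changed_fraction']:.4f}"
            )
        lines.append("")
        lines.append(f"{'type':<16}{'n_spots':>9}{'frac':>8}{'mean conf':>11}{'eta':>9}")
        counts = np.bincount(self.z, minlength=K)
        for k, name in enumerate(self.type_names):
            mask = self.z == k
            conf = self.confidence[mask].mean() if mask.any() else float("nan")
            lines.append(
                f"{name:<16}{counts[k]:>9d}{counts[k] / len(self.z):>8.3f}"
                f"{conf:>11.3f}{self.hmrf_params.eta[k]:>9.3f}"
            )
        zeta = self.hmrf_params.effective_zeta()
        off = zeta[np.triu_indices(K, 1)]
        lines.append("")
        lines.append(
            f"pairwise smoothing zeta: mean {off.mean():.3f}  min {off.min():.3f}  "
            f"max {off.max():.3f}"
        )
        return "\n".join(lines)

    def params_dict(self) -> dict:
        mp = self.mixture_params
        return {
            "mixture": {
                "delta": mp.delta.tolist(),
                "beta0": mp.beta0.tolist(),
                "beta": mp.beta.tolist(),
                "a": mp.a.tolist(),
                "b": mp.b.tolist(),
                "pi": mp.pi.tolist(),
                "rbf_centers": mp.centers.tolist(),
            },
            "hmrf": self.hmrf_params.to_dict(),
            "config": asdict(self.config),
            "history": self.history,
            "converged": self.converged,
        }

    def save(self, outdir) -> None:
        """Write labels.csv, posterior.csv and params.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        spot_ids = (
            self.model.counts.spot_ids
            if self.model is not None
            else [f"spot_{i}" for i in range(len(self.z))]
        )
        pd.DataFrame({"spot_id": spot_ids, "assigned_type": self.labels}).to_csv(
            outdir / "labels.csv", index=False
        )
        post = pd.DataFrame(self.posterior, columns=self.type_names)
        post.insert(0, "spot_id", spot_ids)
        post.to_csv(outdir / "posterior.csv", index=False)
        with open(outdir / "params.json", "w") as fh:
            json.dump(self.params_dict(), fh, indent=1)

    def plot(self, ax=None, **scatter_kwargs):
        """Label map: spots at their coordinates colored by assigned type."""
        import matplotlib.pyplot as plt

        if self.model is None or self.model.coords is None:
            raise ValueError("no coordinates attached to this fit")
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        pos = self.model.coords.positions
        for k, name in enumerate(self.type_names):
            m = self.z == k
            ax.scatter(pos[m, 1], -pos[m, 0], s=scatter_kwargs.pop("s", 8),
                       label=name, **scatter_kwargs)
        ax.set_aspect("equal")
        ax.legend(markerscale=2, fontsize=8)
        return ax


def fit_span(Y, rho, graph: NeighborGraph, X=None, config: SPANConfig | None = None,
             model: "SPANModel | None" = None) -> SPANResults:
    """Full training run (pretrain + ICM loop); see the module docstring."""
    config = config or SPANConfig()
    hyper = config.hyper()
    rho_arr = np.asarray(getattr(rho, "rho", rho), dtype=float)
    K = rho_arr.shape[1]
    if K < 2:
        raise ValueError("at least two types are required")
    s = compute_size_factors(Y)

    # pretrain the mixture alone and seed the label field
    mix, gamma, _ = fit_mixture(
        Y, rho, X, hyper,
        tol=config.pretrain_tol, max_em_iters=config.pretrain_max_iters,
        n_grad_steps=config.pretrain_grad_steps, learning_rate=config.learning_rate,
        seed=config.seed, s=s,
    )
    z = np.argmax(gamma, axis=1)
    posterior = gamma
    phi = HMRFParams.zeros(K) if not config.spatial else HMRFParams.init(K)

    history: list[dict] = []
    converged = False
    for _ in range(config.max_icm_iters):
        mix, l2 = nbm.maximize_conditional(
            Y, z, mix, s, X, rho, hyper,
            n_grad_steps=config.n_grad_steps_gamma, learning_rate=config.learning_rate,
        )
        if config.spatial:
            phi = fit_hmrf(
                z, graph, phi, n_grad_steps=config.n_grad_steps_phi,
                learning_rate=config.learning_rate, K=K,
            )
        z_new, posterior, changed = icm_sweep(Y, z, graph, mix, phi, s, X, rho)
        empty = np.setdiff1d(np.arange(K), z_new)
        if empty.size:
            logger.warning("clusters emptied during ICM (kept): %s", empty.tolist())
        z = z_new
        history.append({
            "changed_fraction": changed,
            "l2": l2,
            "pseudolikelihood": pseudolikelihood(z, graph, phi) if config.spatial else 0.0,
        })
        if changed <= config.label_change_tol:
            converged = True
            break

    return SPANResults(
        model=model, z=z, posterior=posterior, mixture_params=mix,
        hmrf_params=phi, history=history, converged=converged, config=config,
    )


class SPANModel:
    """Marker-gene-informed spatial assignment model.

    Parameters
    ----------
    counts
        ``CountMatrix`` (or plain array) of raw counts over the marker
        genes, spots x genes.
    markers
        ``MarkerMatrix`` with the binary gene-by-type indicator. Gene order
        must match the columns of ``counts``.
    coords, graph
        Spatial input: either ``SpotCoordinates`` (a neighbor graph is
        built according to the platform — lattice adjacency for grids,
        symmetrized kNN with ``k`` neighbors for Euclidean coordinates) or
        a prebuilt ``NeighborGraph``.
    covariates
        Optional spot-level design matrix (e.g. one-hot batch indicators,
        reference level dropped).

    Examples
    --------
    >>> model = SPANModel(counts, markers, coords=coords)
    >>> res = model.fit(seed=0)
    >>> print(res.summary())
    """

    def __init__(self, counts, markers, coords: SpotCoordinates | None = None,
                 graph: NeighborGraph | None = None, covariates=None, k: int = 15):
        self.counts = counts if isinstance(counts, CountMatrix) else CountMatrix(np.asarray(counts))
        self.markers = markers if isinstance(markers, MarkerMatrix) else MarkerMatrix(np.asarray(markers))
        if self.markers.rho.shape[0] != self.counts.n_genes:
            raise ValueError("marker matrix rows must match count matrix genes")
        self.coords = coords
        if graph is None:
            if coords is None:
                raise ValueError("either coords or graph is required")
            graph = (build_knn_graph(coords, k=k) if coords.mode == "euclidean"
                     else build_grid_graph(coords))
        if graph.n_spots != self.counts.n_spots:
            raise ValueError("graph size must match count matrix spots")
        self.graph = graph
        self.covariates = None if covariates is None else np.asarray(covariates, dtype=float)
        if self.covariates is not None and self.covariates.shape[0] != self.counts.n_spots:
            raise ValueError("covariate rows must match count matrix spots")
        self.size_factors = compute_size_factors(self.counts)

    @classmethod
    def from_dataframes(cls, counts: pd.DataFrame, markers: pd.DataFrame,
                        coords: pd.DataFrame, covariates: pd.DataFrame | None = None,
                        platform: str = "st", k: int = 15) -> "SPANModel":
        """Build from tidy frames: counts indexed by spot with gene columns;
        markers with ``gene``/``cell_type`` columns; coords with
        ``row``/``col`` or ``x``/``y`` columns indexed like the counts."""
        from .io import marker_table_to_matrix, coords_from_dataframe

        rho, gene_order = marker_table_to_matrix(markers, list(counts.columns))
        Y = CountMatrix(
            counts[gene_order].to_numpy(), spot_ids=[str(i) for i in counts.index],
            gene_ids=gene_order,
        )
        sc = coords_from_dataframe(coords, platform)
        cov = None if covariates is None else covariates.to_numpy(dtype=float)
        return cls(Y, rho, coords=sc, covariates=cov, k=k)

    @property
    def n_spots(self) -> int:
        return self.counts.n_spots

    @property
    def n_types(self) -> int:
        return self.markers.n_types

    def fit(self, config: SPANConfig | None = None, seed: int | None = None,
            spatial: bool | None = None, **config_overrides) -> SPANResults:
        """Run the full pretrain + ICM training loop; see ``fit_span``."""
        config = config or SPANConfig(**config_overrides)
        if seed is not None:
            config = SPANConfig(**{**asdict(config), "seed": seed})
        if spatial is not None:
            config = SPANConfig(**{**asdict(config), "spatial": spatial})
        return fit_span(self.counts, self.markers, self.graph, self.covariates,
                        config, model=self)
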