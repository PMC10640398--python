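"""Splatter-style synthetic spatially resolved transcriptomics data.

The generative story mirrors the group-structured part of the Splatter
single-cell simulator, laid out on a spatial grid:

* gene base means ``lambda_g ~ Gamma(base_shape, rate=base_rate)``;
* per group k, a ``de_prob`` fraction of genes receives a log-normal
  differential-expression factor ``f_gk = exp(N(0, sigma^2))`` (others 1),
  giving group means ``lambda_gk = lambda_g * f_gk``;
* spot library sizes ``L_i ~ logNormal(lib_loc, lib_scale)``;
* expected counts ``mu_ig = L_i * lambda_{g,z_i} / sum_g lambda_{g,z_i}``;
* observed counts ``y_ig ~ NB(mean mu_ig, inverse-dispersion nb_size_sim)``.

Markers are the genes with ``f_gk`` above a threshold (default 1.5,
strict). Ground-truth labels are laid out as contiguous horizontal bands
on a square grid (cortical-layer-like). Perturbations reproduce common
benchmarking scenarios: swapping spots between groups (spatial noise),
replacing markers with random non-DE genes or moving them to wrong types
(marker corruption), and multiplicative per-batch gene factors (batch
effects).

Dropout, BCV trends and trajectory paths of the full Splatter model are
deliberately omitted; only the group/DE machinery exercised here is
emulated. Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .graph import SpotCoordinates
from .nb_mixture import CountMatrix, MarkerMatrix

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "select_markers",
    "make_layout",
    "inject_spatial_noise",
    "corrupt_markers",
    "add_batch_effects",
    "marker_view",
]

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Generator settings.

    sigma is the log-scale of the DE factors and acts as the signal
    strength: larger sigma separates the groups more. de_prob is the
    fraction of genes that are differentially expressed per group;
    marker_threshold the (strict) DE-factor cutoff for calling a marker.
    """

    n_spots: int = 900
    n_genes: int = 1000
    K: int = 4
    sigma: float = 0.5
    de_prob: float = 0.1
    marker_threshold: float = 1.5
    lib_loc: float = math.log(2000.0)
    lib_scale: float = 0.35
    base_shape: float = 0.6
    base_rate: float = 0.3
    nb_size_sim: float = 2.0
    group_sizes: tuple[int, ...] | None = None
    spatial_noise_ratio: float = 0.0
    fake_marker_ratio: float = 0.0
    misassign_ratio: float = 0.0
    n_batches: int = 1
    batch_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("spatial_noise_ratio", "fake_marker_ratio", "misassign_ratio"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.sigma < 0 or self.marker_threshold <= 1.0:
            raise ValueError("require sigma >= 0 and marker_threshold > 1")
        if self.group_sizes is not None and sum(self.group_sizes) != self.n_spots:
            raise ValueError("group_sizes must sum to n_spots")

    def resolved_group_sizes(self) -> tuple[int, ...]:
        if self.group_sizes is not None:
            return tuple(self.group_sizes)
        base = self.n_spots // self.K
        sizes = [base] * self.K
        for k in range(self.n_spots - base * self.K):
            sizes[k] += 1
        return tuple(sizes)


@dataclass
class SimulatedDataset:
    """Simulator output: counts over all genes, truth labels, coordinates,
    the derived marker panel and the underlying generative quantities."""

    Y: CountMatrix
    z_true: np.ndarray
    coords: SpotCoordinates
    rho: MarkerMatrix
    de_factors: np.ndarray  # (G, K)
    true_log_means: np.ndarray  # (N, G) log mu*_ig
    batch_ids: np.ndarray | None = None
    config: SimConfig | None = None


def make_layout(config: SimConfig) -> tuple[SpotCoordinates, np.ndarray]:
    """Square grid with contiguous horizontal bands of types 0..K-1.

    Spots are placed row-major on the smallest square grid holding
    ``n_spots``; the first ``group_sizes[0]`` spots get type 0 and so on,
    which yields layered bands like a cortical section.
    """
    n = config.n_spots
    side = math.ceil(math.sqrt(n))
    if side * side < n:
        raise ValueError("grid too small for requested spot count")
    rows, cols = np.divmod(np.arange(n), side)
    coords = SpotCoordinates(
        positions=np.column_stack([rows, cols]).astype(float), mode="array_grid_square"
    )
    z = np.repeat(np.arange(config.K), config.resolved_group_sizes())
    return coords, z


def select_markers(de_factors: np.ndarray, threshold: float = 1.5,
                   type_names: list[str] | None = None,
                   gene_ids: list[str] | None = None) -> MarkerMatrix:
    """Marker panel: rho_gk = 1 iff f_gk > threshold (strict); genes that
    mark no type are dropped from the panel."""
    f = np.asarray(de_factors, dtype=float)
    if np.any(f < 0):
        raise ValueError("DE factors must be nonnegative")
    rho = (f > threshold).astype(float)
    missing = np.flatnonzero(rho.sum(axis=0) == 0)
    if missing.size:
        logger.warning("no marker gene exceeds the threshold for groups %s",
                       missing.tolist())
    keep = rho.sum(axis=1) > 0
    if gene_ids is None:
        gene_ids = [f"gene_{g}" for g in range(f.shape[0])]
    return MarkerMatrix(
        rho=rho[keep],
        type_names=type_names,
        gene_ids=[gene_ids[g] for g in np.flatnonzero(keep)],
    )


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, size: float) -> np.ndarray:
    # numpy's NB is (n, p) with mean n(1-p)/p; here n = size, p = size/(size+mu)
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate one dataset (counts, truth, coordinates, marker panel)."""
    if config.de_prob * config.n_genes < config.K:
        raise ValueError("too few DE genes to cover all groups; raise de_prob or n_genes")
    root = np.random.SeedSequence(config.seed)
    keys = {name: np.random.default_rng(s) for name, s in zip(
        ("genes", "library", "counts", "noise", "markers", "batch"), root.spawn(6))}

    G, K = config.n_genes, config.K
    rng = keys["genes"]
    lam = rng.gamma(config.base_shape, 1.0 / config.base_rate, size=G)
    de_factors = np.ones((G, K))
    n_de = int(round(config.de_prob * G))
    for k in range(K):
        idx = rng.choice(G, size=n_de, replace=False)
        de_factors[idx, k] = np.exp(rng.normal(0.0, config.sigma, size=n_de))
    lam_gk = lam[:, None] * de_factors  # (G, K)

    coords, z = make_layout(config)
    L = keys["library"].lognormal(config.lib_loc, config.lib_scale, size=config.n_spots)

    batch_ids = None
    log_batch = 0.0
    if config.n_batches > 1:
        batch_ids = (np.arange(config.n_spots) * config.n_batches) // config.n_spots
        factors = np.exp(keys["batch"].normal(
            0.0, config.batch_sigma, size=(config.n_batches, G)))
        log_batch = np.log(factors)[batch_ids]  # (N, G)

    group_sum = lam_gk.sum(axis=0)  # (K,)
    log_mu = (np.log(L)[:, None] + np.log(lam_gk[:, z].T) - np.log(group_sum[z])[:, None]
              + log_batch)
    Y = _draw_counts(keys["counts"], np.exp(log_mu), config.nb_size_sim)

    rho = select_markers(de_factors, config.marker_threshold,
                         type_names=[f"type_{k}" for k in range(K)])
    dataset = SimulatedDataset(
        Y=CountMatrix(Y), z_true=z, coords=coords, rho=rho,
        de_factors=de_factors, true_log_means=log_mu, batch_ids=batch_ids,
        config=config,
    )
    if config.spatial_noise_ratio > 0:
        dataset = inject_spatial_noise(dataset, config.spatial_noise_ratio,
                                       rng=keys["noise"])
    if config.fake_marker_ratio > 0:
        dataset = replace(dataset, rho=corrupt_markers(
            dataset.rho, dataset.de_factors, "fake", config.fake_marker_ratio,
            rng=keys["markers"]))
    if config.misassign_ratio > 0:
        dataset = replace(dataset, rho=corrupt_markers(
            dataset.rho, dataset.de_factors, "misassign", config.misassign_ratio,
            rng=keys["markers"]))
    return dataset


def inject_spatial_noise(dataset: SimulatedDataset, ratio: float,
                         seed: int | None = None,
                         rng: np.random.Generator | None = None) -> SimulatedDataset:
    """Swap expression rows and labels of random cross-group spot pairs.

    ``floor(ratio * N / 2)`` disjoint pairs of spots with different labels
    are drawn uniformly; each pair exchanges its count row and label while
    coordinates stay put, roughening the spatial arrangement without
    changing the label histogram or the total counts.
    """
    if not (0.0 <= ratio <= 1.0):
        raise ValueError("ratio must lie in [0, 1]")
    if ratio == 0:
        return dataset
    K = dataset.rho.n_types
    if len(np.unique(dataset.z_true)) < 2:
        logger.warning("spatial noise requested with a single group; no-op")
        return dataset
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = len(dataset.z_true)
    n_pairs = int(ratio * n) // 2
    order = rng.permutation(n)
    z = dataset.z_true.copy()
    Y = dataset.Y.Y.copy()
    log_mu = dataset.true_log_means.copy()
    used = np.zeros(n, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for i in order:
        if len(pairs) >= n_pairs:
            break
        if used[i]:
            continue
        partners = [j for j in order if not used[j] and z[j] != z[i]]
        if not partners:
            break
        j = partners[0]
        used[i] = used[j] = True
        pairs.append((int(i), int(j)))
    if len(pairs) < n_pairs:
        logger.warning("only %d of %d requested swap pairs were possible",
                       len(pairs), n_pairs)
    for i, j in pairs:
        z[i], z[j] = z[j], z[i]
        Y[[i, j]] = Y[[j, i]]
        log_mu[[i, j]] = log_mu[[j, i]]
    return replace(dataset, Y=CountMatrix(Y, dataset.Y.spot_ids, dataset.Y.gene_ids),
                   z_true=z, true_log_means=log_mu)


def corrupt_markers(rho: MarkerMatrix, de_factors: np.ndarray, mode: str,
                    ratio: float, seed: int | None = None,
                    rng: np.random.Generator | None = None) -> MarkerMatrix:
    """Degrade the marker panel.

    ``fake``: a fraction of marker genes is swapped out for uniformly
    chosen non-DE genes, each assigned one uniformly random type (panel
    size preserved). ``misassign``: the same count of marker genes keep
    their place but have their indicator row moved to a single wrong type.
    """
    if mode not in ("fake", "misassign"):
        raise ValueError(f"unknown corruption mode {mode!r}")
    if not (0.0 <= ratio <= 1.0):
        raise ValueError("ratio must lie in [0, 1]")
    if ratio == 0:
        return rho
    rng = rng if rng is not None else np.random.default_rng(seed)
    f = np.asarray(de_factors, dtype=float)
    K = rho.n_types
    all_gene_ids = [f"gene_{g}" for g in range(f.shape[0])]
    panel = list(rho.gene_ids)
    n_corrupt = int(ratio * len(panel))
    if n_corrupt == 0:
        return rho
    victims = rng.choice(len(panel), size=n_corrupt, replace=False)
    new_rho = rho.rho.copy()
    new_ids = list(panel)
    if mode == "fake":
        non_de = [g for g in range(f.shape[0])
                  if np.all(f[g] == 1.0) and all_gene_ids[g] not in panel]
        if len(non_de) < n_corrupt:
            raise ValueError("not enough non-DE genes to draw fake markers from")
        replacements = rng.choice(len(non_de), size=n_corrupt, replace=False)
        for v, r in zip(victims, replacements):
            row = np.zeros(K)
            row[rng.integers(K)] = 1.0
            new_rho[v] = row
            new_ids[v] = all_gene_ids[non_de[r]]
    else:
        for v in victims:
            current = np.flatnonzero(rho.rho[v])
            wrong = np.setdiff1d(np.arange(K), current)
            row = np.zeros(K)
            row[rng.choice(wrong)] = 1.0
            new_rho[v] = row
    return MarkerMatrix(rho=new_rho, type_names=rho.type_names, gene_ids=new_ids)


def add_batch_effects(dataset: SimulatedDataset, n_batches: int,
                      batch_sigma: float, seed: int = 0) -> SimulatedDataset:
    """Partition spots into contiguous batches and redraw counts with
    per-batch per-gene multiplicative factors ``exp(N(0, batch_sigma^2))``
    applied to the expected counts."""
    if n_batches < 2:
        raise ValueError("n_batches must be at least 2")
    rng = np.random.default_rng(seed)
    n, G = dataset.true_log_means.shape
    batch_ids = (np.arange(n) * n_batches) // n
    factors = np.exp(rng.normal(0.0, batch_sigma, size=(n_batches, G)))
    log_mu = dataset.true_log_means + np.log(factors)[batch_ids]
    size = dataset.config.nb_size_sim if dataset.config is not None else 2.0
    Y = _draw_counts(rng, np.exp(log_mu), size)
    return replace(dataset, Y=CountMatrix(Y, dataset.Y.spot_ids, dataset.Y.gene_ids),
                   true_log_means=log_mu, batch_ids=batch_ids)


def marker_view(dataset: SimulatedDataset) -> tuple[CountMatrix, MarkerMatrix]:
    """Subset the count matrix to the (possibly corrupted) marker panel, in
    panel order — the model input."""
    gene_index = {g: i for i, g in enumerate(dataset.Y.gene_ids)}
    cols = [gene_index[g] for g in dataset.rho.gene_ids]
    Y = CountMatrix(dataset.Y.Y[:, cols], spot_ids=dataset.Y.spot_ids,
                    gene_ids=list(dataset.rho.gene_ids))
    return Y, dataset.rho
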