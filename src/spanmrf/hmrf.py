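"""Potts-like hidden Markov random field over spot labels.

The joint over labels z on the neighbor graph is

    p(z) ∝ exp( sum_k eta_k n_k  -  sum_{k<l} zeta_kl n_kl )

with n_k the spots of type k and n_kl the discordant neighbor pairs with
types {k, l}; zeta_kl > 0 penalizes discordant neighbors. The per-spot
conditional follows exactly:

    p(z_i = k | z_neighbors) ∝ exp( eta_k - sum_{l != k} zeta_kl u_i(l) )

where u_i(l) counts neighbors of i with label l. Since the partition
function is intractable, (eta, zeta) are estimated by maximizing the
pseudolikelihood (product of per-spot conditionals) with Adam on a
reparameterized form: eta_0 is pinned at 0 (the conditionals are invariant
to eta shifts), zeta = softplus of symmetric raw off-diagonal entries,
capped at ZETA_MAX, plus a small ridge on the raw entries — a perfectly
smooth labeling otherwise drives zeta to infinity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, log_softmax, logsumexp, softmax

from ._optim import adam_maximize
from .graph import NeighborGraph, neighbor_type_counts

__all__ = [
    "HMRFParams",
    "ZETA_MAX",
    "label_statistics",
    "joint_log_potential",
    "conditional_logits",
    "pseudolikelihood",
    "fit_hmrf",
]

ZETA_MAX = 20.0
RIDGE = 1e-3


def _softplus(x):
    return np.logaddexp(0.0, x)


@dataclass
class HMRFParams:
    """Field parameters: per-type external field eta (eta_0 fixed at 0 for
    identifiability) and symmetric positive pairwise penalties zeta."""

    eta: np.ndarray  # (K,)
    zeta_raw: np.ndarray  # (K, K) symmetric raw; only upper triangle is free

    def __post_init__(self):
        self.eta = np.asarray(self.eta, dtype=float)
        self.zeta_raw = np.asarray(self.zeta_raw, dtype=float)
        K = len(self.eta)
        if self.zeta_raw.shape != (K, K):
            raise ValueError("zeta_raw must be K x K")
        self.zeta_raw = np.triu(self.zeta_raw, 1) + np.triu(self.zeta_raw, 1).T

    @property
    def K(self) -> int:
        return len(self.eta)

    @property
    def zeta(self) -> np.ndarray:
        z = np.minimum(_softplus(self.zeta_raw), ZETA_MAX)
        np.fill_diagonal(z, 0.0)
        return z

    @classmethod
    def zeros(cls, K: int) -> "HMRFParams":
        """All-zero field: eta = 0 and zeta = 0 exactly (spatially inert)."""
        p = cls(eta=np.zeros(K), zeta_raw=np.zeros((K, K)))
        p._zeta_off = True
        return p

    @classmethod
    def init(cls, K: int, zeta0: float = 0.1) -> "HMRFParams":
        """Start near a spatially neutral field: a small zeta0 lets the
        pseudolikelihood fit grow the smoothing strength as the data warrant
        instead of imposing strong smoothing before calibration."""
        raw = np.full((K, K), float(np.log(np.expm1(zeta0))))
        return cls(eta=np.zeros(K), zeta_raw=raw)

    def effective_zeta(self) -> np.ndarray:
        if getattr(self, "_zeta_off", False):
            return np.zeros((self.K, self.K))
        return self.zeta

    def to_dict(self) -> dict:
        return {"eta": self.eta.tolist(), "zeta": self.effective_zeta().tolist()}


def label_statistics(z, graph: NeighborGraph, K: int):
    """Class sizes n_k and discordant unordered neighbor-pair counts n_kl."""
    z = np.asarray(z)
    if z.size and (z.min() < 0 or z.max() >= K):
        raise ValueError(f"labels must lie in [0, {K})")
    n_k = np.bincount(z, minlength=K)
    n_kl = np.zeros((K, K), dtype=np.int64)
    for i, j in graph.edges():
        if z[i] != z[j]:
            n_kl[z[i], z[j]] += 1
            n_kl[z[j], z[i]] += 1
    return n_k, n_kl


def joint_log_potential(z, graph: NeighborGraph, phi: HMRFParams) -> float:
    """Unnormalized log joint: sum_k eta_k n_k - sum_{k<l} zeta_kl n_kl."""
    n_k, n_kl = label_statistics(z, graph, phi.K)
    zeta = phi.effective_zeta()
    return float(phi.eta @ n_k - 0.5 * (zeta * n_kl).sum())


def conditional_logits(u, phi: HMRFParams) -> np.ndarray:
    """Per-type log-weights eta_k - sum_{l != k} zeta_kl u(l).

    ``u`` is a (K,) neighbor-type count vector or an (N, K) matrix of them;
    the caller normalizes with log-sum-exp.
    """
    u = np.asarray(u, dtype=float)
    return phi.eta - u @ phi.effective_zeta().T


def pseudolikelihood(z, graph: NeighborGraph, phi: HMRFParams) -> float:
    """Sum of per-spot conditional log-probabilities of the observed labels."""
    z = np.asarray(z)
    u = neighbor_type_counts(graph, z, phi.K)
    logits = conditional_logits(u, phi)
    return float(logits[np.arange(len(z)), z].sum() - logsumexp(logits, axis=1).sum())


def _pl_value_and_grad(raw, z, u, onehot, K, ridge=RIDGE):
    """Penalized pseudolikelihood and gradient in the raw parameterization."""
    eta = np.concatenate([[0.0], raw["eta_free"]])
    zr = np.triu(raw["zeta_raw"], 1)
    zr = zr + zr.T
    sp = _softplus(zr)
    capped = sp >= ZETA_MAX
    zeta = np.minimum(sp, ZETA_MAX)
    np.fill_diagonal(zeta, 0.0)
    logits = eta - u @ zeta.T
    logp = log_softmax(logits, axis=1)
    value = float(logp[np.arange(len(z)), z].sum()) - ridge * float(
        np.sum(np.triu(zr, 1) ** 2)
    )
    resid = onehot - np.exp(logp)  # (N, K): d value / d logits
    g_eta = resid.sum(axis=0)
    # d logits[i, k] / d zeta_kl = -u[i, l]; symmetric parameter also feeds logits[i, l]
    g_zeta = -(resid.T @ u)  # (K, K): entry (k, l) = -sum_i resid_ik u_il
    g_zeta = g_zeta + g_zeta.T
    np.fill_diagonal(g_zeta, 0.0)
    g_raw = g_zeta * expit(zr) * (~capped)
    g_raw = np.triu(g_raw, 1) - 2.0 * ridge * np.triu(zr, 1)
    return value, {"eta_free": g_eta[1:], "zeta_raw": g_raw}


def fit_hmrf(
    z,
    graph: NeighborGraph,
    phi_init: HMRFParams | None = None,
    n_grad_steps: int = 50,
    learning_rate: float = 0.01,
    K: int | None = None,
) -> HMRFParams:
    """Estimate (eta, zeta) by penalized pseudolikelihood ascent.

    Runs ``n_grad_steps`` Adam steps and returns the best iterate, so the
    penalized pseudolikelihood never decreases across calls warm-started
    from the previous estimate.
    """
    z = np.asarray(z)
    if K is None:
        K = phi_init.K if phi_init is not None else int(z.max()) + 1
    if K < 2:
        raise ValueError("the field is degenerate with a single type")
    if phi_init is None:
        phi_init = HMRFParams.init(K)
    u = neighbor_type_counts(graph, z, K)
    onehot = np.zeros((len(z), K))
    onehot[np.arange(len(z)), z] = 1.0

    def closure(raw):
        return _pl_value_and_grad(raw, z, u, onehot, K)

    raw0 = {"eta_free": phi_init.eta[1:] - phi_init.eta[0], "zeta_raw": phi_init.zeta_raw}
    best, _, _ = adam_maximize(closure, raw0, n_grad_steps, learning_rate)
    return HMRFParams(
        eta=np.concatenate([[0.0], best["eta_free"]]), zeta_raw=best["zeta_raw"]
    )


def exact_conditional(z, i, graph: NeighborGraph, phi: HMRFParams) -> np.ndarray:
    """Brute-force conditional p(z_i | z_{-i}) from the joint potential.

    Intended as an oracle for small instances; enumerates the K choices of
    z_i with everything else fixed.
    """
    z = np.array(z, copy=True)
    logs = np.empty(phi.K)
    for k in range(phi.K):
        z[i] = k
        logs[k] = joint_log_potential(z, graph, phi)
    return softmax(logs)
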