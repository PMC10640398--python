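"""Marker-gene-informed negative-binomial mixture over spots.

The model: spot ``i`` with latent type ``z_i = k`` has counts
``y_ig ~ NB(mu_igk, phi_igk)`` with

    log mu_igk = log s_i + delta_gk * rho_gk + beta_g0 + sum_p beta_gp x_ip

where ``s_i`` is a size factor, ``rho`` is the binary marker indicator
(gene g marks type k), ``delta_gk > 0`` is the marker log fold change,
``beta_g0`` the base expression and ``beta_gp`` optional covariate effects
(e.g. one-hot batch). The NB uses the mean / inverse-dispersion convention
``Var = mu + mu^2 / phi``; ``phi`` is tied to the mean through a sum of
radial basis functions with fixed, equally spaced centers on
``[0, max(Y)]`` and learnable amplitudes ``a_j`` and widths ``b_j``.

Estimation is MAP EM: responsibilities by Bayes rule in log space, then a
fixed number of Adam ascent steps on the Q function, with a log-normal
prior on ``delta`` (applied where ``rho_gk = 1``) and a Dirichlet prior on
the mixing weights ``pi``. Positivity is enforced by reparameterization
(``delta = exp``, ``a``/``b`` = softplus, ``pi`` = softmax), so the M-step
is unconstrained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, expit, gammaln, log_softmax, logsumexp, softmax

from ._kernels import HAVE_NUMBA, _weighted_nb_value_grad
from ._optim import adam_maximize

__all__ = [
    "CountMatrix",
    "MarkerMatrix",
    "MixtureParams",
    "HyperParams",
    "PHI_FLOOR",
    "compute_size_factors",
    "compute_log_mean",
    "compute_dispersion",
    "nb_logpmf",
    "loglik_matrix",
    "e_step",
    "q_objective",
    "m_step",
    "fit_mixture",
]

logger = logging.getLogger(__name__)

PHI_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# containers


@dataclass
class CountMatrix:
    """Spot-by-gene raw counts with identifiers."""

    Y: np.ndarray
    spot_ids: list[str] | None = None
    gene_ids: list[str] | None = None

    def __post_init__(self):
        Y = np.asarray(self.Y)
        if Y.ndim != 2:
            raise ValueError("counts must be a 2-D spot-by-gene matrix")
        if np.any(Y < 0) or not np.allclose(Y, np.round(Y)):
            raise ValueError("counts must be nonnegative integers")
        self.Y = Y.astype(np.int64)
        if self.spot_ids is None:
            self.spot_ids = [f"spot_{i}" for i in range(Y.shape[0])]
        if self.gene_ids is None:
            self.gene_ids = [f"gene_{g}" for g in range(Y.shape[1])]
        if len(self.spot_ids) != Y.shape[0] or len(self.gene_ids) != Y.shape[1]:
            raise ValueError("identifier lengths do not match matrix shape")

    @property
    def n_spots(self) -> int:
        return self.Y.shape[0]

    @property
    def n_genes(self) -> int:
        return self.Y.shape[1]


@dataclass
class MarkerMatrix:
    """Binary gene-by-type marker indicator (rho)."""

    rho: np.ndarray
    type_names: list[str] | None = None
    gene_ids: list[str] | None = None

    def __post_init__(self):
        rho = np.asarray(self.rho)
        if rho.ndim != 2:
            raise ValueError("rho must be a gene-by-type matrix")
        if not np.isin(rho, (0, 1)).all():
            raise ValueError("rho entries must be 0/1")
        self.rho = rho.astype(float)
        if np.any(rho.sum(axis=1) == 0):
            bad = np.flatnonzero(rho.sum(axis=1) == 0)
            raise ValueError(
                f"genes with no marker assignment are uninformative: rows {bad.tolist()}"
            )
        if rho.shape[0] and np.any(rho.sum(axis=0) == 0):
            bad = np.flatnonzero(rho.sum(axis=0) == 0)
            logger.warning("types with no marker gene: columns %s", bad.tolist())
        if self.type_names is None:
            self.type_names = [f"type_{k}" for k in range(rho.shape[1])]
        if self.gene_ids is None:
            self.gene_ids = [f"gene_{g}" for g in range(rho.shape[0])]

    @property
    def n_types(self) -> int:
        return self.rho.shape[1]


@dataclass
class HyperParams:
    """Fixed hyperparameters of the MAP objective.

    delta_bar, sigma2
        Mean and variance of the log-normal prior on the marker fold
        change delta (defaults 0 and 1).
    alpha
        Symmetric Dirichlet concentration on the mixing weights
        (default 0.01, i.e. sparsity-favoring).
    B
        Number of radial basis centers for the mean-dispersion curve
        (default 10).
    """

    delta_bar: float = 0.0
    sigma2: float = 1.0
    alpha: float = 0.01
    B: int = 10

    def __post_init__(self):
        if self.sigma2 <= 0 or self.alpha <= 0 or self.B < 1:
            raise ValueError("require sigma2 > 0, alpha > 0, B >= 1")


def _softplus(x):
    return np.logaddexp(0.0, x)


def _softplus_inv(y):
    y = np.asarray(y, dtype=float)
    with np.errstate(over="ignore"):
        return np.where(y > 30, y, np.log(np.expm1(np.maximum(y, 1e-12))))


@dataclass
class MixtureParams:
    """Mixture parameters in raw (unconstrained) form.

    ``delta = exp(delta_raw)``, ``a = softplus(a_raw)``,
    ``b = softplus(b_raw)``, ``pi = softmax(pi_raw)``; RBF ``centers`` are
    fixed, not learned.
    """

    delta_raw: np.ndarray  # (G, K)
    beta0: np.ndarray  # (G,)
    beta: np.ndarray  # (G, P)
    a_raw: np.ndarray  # (B,)
    b_raw: np.ndarray  # (B,)
    pi_raw: np.ndarray  # (K,)
    centers: np.ndarray  # (B,)

    @property
    def delta(self) -> np.ndarray:
        return np.exp(self.delta_raw)

    @property
    def a(self) -> np.ndarray:
        return _softplus(self.a_raw)

    @property
    def b(self) -> np.ndarray:
        return _softplus(self.b_raw)

    @property
    def pi(self) -> np.ndarray:
        return softmax(self.pi_raw)

    def copy(self) -> "MixtureParams":
        return MixtureParams(
            **{k: np.array(getattr(self, k), copy=True) for k in self.__dataclass_fields__}
        )

    def free_dict(self, include_pi: bool = True) -> dict[str, np.ndarray]:
        d = {
            "delta_raw": self.delta_raw,
            "beta0": self.beta0,
            "a_raw": self.a_raw,
            "b_raw": self.b_raw,
        }
        if self.beta.shape[1] > 0:
            d["beta"] = self.beta
        if include_pi:
            d["pi_raw"] = self.pi_raw
        return d

    def replace(self, updates: dict[str, np.ndarray]) -> "MixtureParams":
        new = self.copy()
        for k, v in updates.items():
            setattr(new, k, np.array(v, copy=True))
        return new


def init_params(
    Y: np.ndarray,
    rho: np.ndarray,
    n_covariates: int,
    hyper: HyperParams,
    rng: np.random.Generator,
) -> MixtureParams:
    """Initialization.

    delta starts at the prior median exp(delta_bar) for every entry: a
    symmetric start in which components differ only through which genes
    they boost, so no type is favored by the draw of the initializer
    (random delta starts were observed to collapse the mixture onto one
    component when markers are weak). beta_g0 starts from the log mean
    count; RBF amplitudes at 1 with widths matched to the center spacing;
    pi uniform. ``rng`` is accepted for interface stability; the default
    initialization is deterministic.
    """
    G, K = rho.shape
    delta0 = np.full((G, K), math.exp(hyper.delta_bar))
    ymax = float(np.max(Y)) if Y.size else 1.0
    centers = np.linspace(0.0, max(ymax, 1.0), hyper.B)
    dx = centers[1] - centers[0] if hyper.B > 1 else 1.0
    return MixtureParams(
        delta_raw=np.log(delta0),
        beta0=np.log(Y.mean(axis=0) + 0.01),
        beta=np.zeros((G, n_covariates)),
        a_raw=np.full(hyper.B, _softplus_inv(1.0)),
        b_raw=np.full(hyper.B, _softplus_inv(1.0 / (2.0 * dx * dx))),
        pi_raw=np.zeros(K),
        centers=centers,
    )


# ---------------------------------------------------------------------------
# forward pieces


def _as_array(obj, attr):
    return np.asarray(getattr(obj, attr, obj), dtype=float)


def compute_size_factors(Y) -> np.ndarray:
    """Size factors s_i = spot total / median spot total (over input genes)."""
    arr = np.asarray(getattr(Y, "Y", Y), dtype=float)
    totals = arr.sum(axis=1)
    if np.any(totals == 0):
        ids = getattr(Y, "spot_ids", None)
        bad = np.flatnonzero(totals == 0)
        names = [ids[i] for i in bad] if ids is not None else bad.tolist()
        raise ValueError(f"spots with zero total counts: {names}")
    return totals / np.median(totals)


def compute_log_mean(params: MixtureParams, s, X, rho) -> np.ndarray:
    """(N, G, K) tensor of log mu_igk."""
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0) or not np.all(np.isfinite(s)):
        raise ValueError("size factors must be positive and finite")
    rho = _as_array(rho, "rho")
    logmu = (params.delta * rho)[None, :, :] + params.beta0[None, :, None]
    logmu = logmu + np.log(s)[:, None, None]
    if X is not None and np.size(X) > 0:
        X = _as_array(X, "X")
        logmu = logmu + (X @ params.beta.T)[:, :, None]
    return logmu


def compute_dispersion(mu, a, b, centers) -> np.ndarray:
    """phi = max(sum_j a_j exp(-b_j (mu - x_j)^2), PHI_FLOOR), elementwise."""
    mu = np.asarray(mu, dtype=float)
    phi = np.zeros_like(mu)
    for aj, bj, xj in zip(np.atleast_1d(a), np.atleast_1d(b), np.atleast_1d(centers)):
        phi += aj * np.exp(-bj * (mu - xj) ** 2)
    return np.maximum(phi, PHI_FLOOR)


def nb_logpmf(y, mu, phi):
    """Negative-binomial log pmf, convention ``Var = mu + mu^2/phi``.

    ``log NB(y) = lgamma(y+phi) - lgamma(phi) - lgamma(y+1)
    + phi*log(phi/(phi+mu)) + y*log(mu/(phi+mu))``.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(mu <= 0) or np.any(phi <= 0):
        raise ValueError("mu and phi must be positive")
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("y must be a nonnegative integer")
    denom = phi + mu
    return (
        gammaln(y + phi)
        - gammaln(phi)
        - gammaln(y + 1.0)
        + phi * (np.log(phi) - np.log(denom))
        + y * (np.log(mu) - np.log(denom))
    )


def loglik_matrix(Y, params: MixtureParams, s, X, rho) -> np.ndarray:
    """(N, K) per-spot NB log-likelihood summed over genes (no pi term)."""
    Yarr = np.asarray(getattr(Y, "Y", Y), dtype=float)
    mu = np.exp(compute_log_mean(params, s, X, rho))
    phi = compute_dispersion(mu, params.a, params.b, params.centers)
    ll = nb_logpmf(Yarr[:, :, None], mu, phi)
    if not np.all(np.isfinite(ll)):
        i, g, k = np.argwhere(~np.isfinite(ll))[0]
        raise FloatingPointError(
            f"non-finite NB log-likelihood at spot {i}, gene {g}, type {k}"
        )
    return ll.sum(axis=1)


# ---------------------------------------------------------------------------
# E-step / Q function


def e_step(Y, params: MixtureParams, s, X, rho) -> np.ndarray:
    """Posterior responsibilities gamma_ik by Bayes rule, in log space."""
    logp = loglik_matrix(Y, params, s, X, rho) + np.log(params.pi)[None, :]
    return np.exp(log_softmax(logp, axis=1))


def marginal_log_posterior(Y, params: MixtureParams, s, X, rho, hyper: HyperParams) -> float:
    """Marginal log-likelihood sum_i log sum_k pi_k prod_g NB + log priors."""
    logp = loglik_matrix(Y, params, s, X, rho) + np.log(params.pi)[None, :]
    rho_arr = _as_array(rho, "rho")
    return float(
        logsumexp(logp, axis=1).sum()
        + _delta_log_prior(params.delta_raw, rho_arr, hyper)
        + _pi_log_prior(params.pi, hyper)
    )


def _delta_log_prior(delta_raw, rho, hyper: HyperParams) -> float:
    # log-normal on delta, i.e. normal on delta_raw minus log delta Jacobian,
    # applied only where rho_gk = 1 (delta is inert elsewhere)
    t = delta_raw - hyper.delta_bar
    lp = -delta_raw - 0.5 * t * t / hyper.sigma2 - 0.5 * math.log(2 * math.pi * hyper.sigma2)
    return float((lp * rho).sum())


def _pi_log_prior(pi, hyper: HyperParams) -> float:
    K = len(pi)
    const = gammaln(K * hyper.alpha) - K * gammaln(hyper.alpha)
    return float(const + (hyper.alpha - 1.0) * np.log(np.maximum(pi, 1e-300)).sum())


def q_objective(Y, gamma, params: MixtureParams, s, X, rho, hyper: HyperParams) -> float:
    """EM Q function: gamma-weighted complete-data log joint plus log priors."""
    val, _ = _q_value_and_grad(
        params.free_dict(), Y, gamma, s, X, rho, hyper, params, want_grad=False
    )
    return val


def _forward(raw, template: MixtureParams, s, X, rho, hard_z=None):
    """Shared forward pass. With ``hard_z`` the (N, G) slice at k = z_i is
    computed instead of the full (N, G, K) tensor."""
    delta = np.exp(raw["delta_raw"])
    beta0 = raw["beta0"]
    beta = raw.get("beta", template.beta)
    a = _softplus(raw["a_raw"])
    b = _softplus(raw["b_raw"])
    centers = template.centers
    s = np.asarray(s, dtype=float)
    boost = delta * rho  # (G, K)
    if hard_z is None:
        logmu = boost[None, :, :] + beta0[None, :, None] + np.log(s)[:, None, None]
        if X is not None and np.size(X) > 0:
            logmu = logmu + (X @ beta.T)[:, :, None]
    else:
        logmu = boost[:, hard_z].T + beta0[None, :] + np.log(s)[:, None]
        if X is not None and np.size(X) > 0:
            logmu = logmu + X @ beta.T
    mu = np.exp(logmu)
    rbf = np.empty((len(a),) + mu.shape)
    phi_raw = np.zeros_like(mu)
    for j in range(len(a)):
        rbf[j] = np.exp(-b[j] * (mu - centers[j]) ** 2)
        phi_raw += a[j] * rbf[j]
    phi = np.maximum(phi_raw, PHI_FLOOR)
    active = phi_raw > PHI_FLOOR
    return delta, beta, a, b, logmu, mu, rbf, phi, active


def _sparse_ll_parts(logmu, mu, phi, nz, y_nz, gl_y1_nz, want_grad):
    """NB log pmf and d/dmu, d/dphi split into a dense y-independent part
    and corrections on the nonzero-count entries.

    For y = 0 the pmf reduces to ``phi * log(phi/(phi+mu))`` and all
    gamma-function terms vanish, so the expensive ``gammaln``/``digamma``
    evaluations are restricted to rows with y > 0 (``nz`` indexes the
    flattened (N*G) axis; trailing axes broadcast).
    """
    denom = phi + mu
    log_phi = np.log(phi)
    log_denom = np.log(denom)
    r = phi / denom
    ll = phi * (log_phi - log_denom)  # dense part, exact for y = 0
    sh = (-1,) + ll.shape[2:]  # flatten the (spot, gene) axes; nz indexes them
    ll_f = ll.reshape(sh)
    phi_nz = phi.reshape(sh)[nz]
    mu_nz = mu.reshape(sh)[nz]
    denom_nz = denom.reshape(sh)[nz]
    ll_f[nz] += (
        gammaln(y_nz + phi_nz)
        - gammaln(phi_nz)
        - gl_y1_nz
        + y_nz * (logmu.reshape(sh)[nz] - log_denom.reshape(sh)[nz])
    )
    if not np.all(np.isfinite(ll_f[nz])) or not np.all(np.isfinite(ll)):
        raise FloatingPointError("non-finite NB log-likelihood encountered")
    if not want_grad:
        return ll, None, None
    d_mu = -r
    d_mu.reshape(sh)[nz] += y_nz * (1.0 / mu_nz - 1.0 / denom_nz)
    d_phi = log_phi + 1.0 - log_denom - r
    d_phi.reshape(sh)[nz] += (
        digamma(y_nz + phi_nz) - digamma(phi_nz) - y_nz / denom_nz
    )
    return ll, d_mu, d_phi


def _q_value_and_grad(raw, Y, gamma, s, X, rho, hyper, template, want_grad=True,
                      include_pi=True):
    """Q(theta) and its gradient w.r.t. the raw parameters.

    ``gamma`` may be soft (E-step output) or one-hot; with
    ``include_pi=False`` the mixing-weight term and Dirichlet prior are
    dropped, giving the conditional likelihood objective used during ICM.
    """
    Yarr = np.asarray(getattr(Y, "Y", Y), dtype=float)
    rho_arr = _as_array(rho, "rho")
    delta, beta, a, b, logmu, mu, rbf, phi, active = _forward(raw, template, s, X, rho_arr)
    nz = np.flatnonzero(Yarr.ravel() > 0)
    y_nz = Yarr.ravel()[nz][:, None]
    gl_y1_nz = gammaln(y_nz + 1.0)
    try:
        ll, d_mu, d_phi = _sparse_ll_parts(logmu, mu, phi, nz, y_nz, gl_y1_nz, want_grad)
    except FloatingPointError as err:
        raise FloatingPointError(f"{err} (mixture Q evaluation)") from None

    value = float(np.einsum("ik,igk->", gamma, ll))
    value += _delta_log_prior(raw["delta_raw"], rho_arr, hyper)
    if include_pi:
        pi = softmax(raw["pi_raw"])
        nk = gamma.sum(axis=0)
        value += float(nk @ np.log(np.maximum(pi, 1e-300)))
        value += _pi_log_prior(pi, hyper)
    if not want_grad:
        return value, None

    d_phi *= active
    w = gamma[:, None, :]  # broadcast weight over genes
    dphi_dmu = np.zeros_like(mu)
    for j in range(len(a)):
        dphi_dmu += a[j] * rbf[j] * (-2.0 * b[j] * (mu - template.centers[j]))
    g_logmu = w * (d_mu + d_phi * dphi_dmu) * mu  # (N, G, K)

    grads: dict[str, np.ndarray] = {}
    grads["beta0"] = g_logmu.sum(axis=(0, 2))
    t = raw["delta_raw"] - hyper.delta_bar
    prior_grad = (-1.0 - t / hyper.sigma2) * rho_arr
    grads["delta_raw"] = g_logmu.sum(axis=0) * rho_arr * delta + prior_grad
    if "beta" in raw:
        grads["beta"] = np.einsum("igk,ip->gp", g_logmu, np.asarray(X, dtype=float))
    wd = w * d_phi
    ga = np.empty(len(a))
    gb = np.empty(len(a))
    for j in range(len(a)):
        ga[j] = np.sum(wd * rbf[j])
        gb[j] = np.sum(wd * a[j] * rbf[j] * (-((mu - template.centers[j]) ** 2)))
    grads["a_raw"] = ga * expit(raw["a_raw"])
    grads["b_raw"] = gb * expit(raw["b_raw"])
    if include_pi:
        tvec = gamma.sum(axis=0) + (hyper.alpha - 1.0)
        grads["pi_raw"] = tvec - softmax(raw["pi_raw"]) * tvec.sum()
    return value, grads


def _l2_value_and_grad(raw, Y, z, s, X, rho, hyper, template):
    """Hard-label conditional log-likelihood L2 (+ delta prior) and gradient.

    Only the k = z_i slice of the mean/dispersion tensors is needed, which
    makes the Gamma-update inside the ICM loop K-fold cheaper than the
    soft-gamma path.
    """
    Yarr = np.asarray(getattr(Y, "Y", Y), dtype=float)
    rho_arr = _as_array(rho, "rho")
    z = np.asarray(z)
    K = rho_arr.shape[1]
    delta, beta, a, b, logmu, mu, rbf, phi, active = _forward(
        raw, template, s, X, rho_arr, hard_z=z
    )
    nz = np.flatnonzero(Yarr.ravel() > 0)
    y_nz = Yarr.ravel()[nz]
    try:
        ll, d_mu, d_phi = _sparse_ll_parts(
            logmu, mu, phi, nz, y_nz, gammaln(y_nz + 1.0), want_grad=True
        )
    except FloatingPointError as err:
        raise FloatingPointError(f"{err} (conditional L2 evaluation)") from None
    value = float(ll.sum()) + _delta_log_prior(raw["delta_raw"], rho_arr, hyper)

    d_phi = np.where(active, d_phi, 0.0)
    dphi_dmu = np.zeros_like(mu)
    for j in range(len(a)):
        dphi_dmu += a[j] * rbf[j] * (-2.0 * b[j] * (mu - template.centers[j]))
    g_logmu = (d_mu + d_phi * dphi_dmu) * mu  # (N, G)

    grads: dict[str, np.ndarray] = {"beta0": g_logmu.sum(axis=0)}
    gd = np.zeros_like(raw["delta_raw"])
    for k in range(K):
        mask = z == k
        if mask.any():
            gd[:, k] = g_logmu[mask].sum(axis=0)
    t = raw["delta_raw"] - hyper.delta_bar
    grads["delta_raw"] = gd * rho_arr * delta + (-1.0 - t / hyper.sigma2) * rho_arr
    if "beta" in raw:
        grads["beta"] = g_logmu.T @ np.asarray(X, dtype=float)
    ga = np.empty(len(a))
    gb = np.empty(len(a))
    for j in range(len(a)):
        ga[j] = np.sum(d_phi * rbf[j])
        gb[j] = np.sum(d_phi * a[j] * rbf[j] * (-((mu - template.centers[j]) ** 2)))
    grads["a_raw"] = ga * expit(raw["a_raw"])
    grads["b_raw"] = gb * expit(raw["b_raw"])
    return value, grads


def _value_and_grad_fused(raw, Y, weights, s, X, rho, hyper, template,
                          include_pi=True):
    """Fused-kernel twin of ``_q_value_and_grad`` (and, with one-hot
    weights, of ``_l2_value_and_grad``); used for the hot M-step closures
    when numba is importable. Asserted equivalent to the numpy reference
    in the test suite."""
    Yarr = np.asarray(getattr(Y, "Y", Y), dtype=float)
    rho_arr = _as_array(rho, "rho")
    G, K = rho_arr.shape
    delta = np.exp(raw["delta_raw"])
    beta = raw.get("beta", template.beta)
    a = _softplus(raw["a_raw"])
    b = _softplus(raw["b_raw"])
    has_cov = X is not None and np.size(X) > 0
    Xarr = np.asarray(X, dtype=float) if has_cov else np.zeros((0, 0))
    Xb = Xarr @ beta.T if has_cov else np.zeros((0, 0))
    P = beta.shape[1] if "beta" in raw else 0
    g_delta = np.zeros((G, K))
    g_beta0 = np.zeros(G)
    g_beta = np.zeros((G, P))
    g_a = np.zeros(len(a))
    g_b = np.zeros(len(b))
    value = _weighted_nb_value_grad(
        np.log(np.asarray(s, dtype=float)), raw["beta0"], delta, rho_arr, Xb, Xarr,
        weights, Yarr, a, b, np.asarray(template.centers, dtype=float), PHI_FLOOR,
        g_delta, g_beta0, g_beta, g_a, g_b,
    )
    if not np.isfinite(value):
        raise FloatingPointError("non-finite NB log-likelihood encountered")
    value += _delta_log_prior(raw["delta_raw"], rho_arr, hyper)
    t = raw["delta_raw"] - hyper.delta_bar
    grads = {
        "delta_raw": g_delta * rho_arr * delta + (-1.0 - t / hyper.sigma2) * rho_arr,
        "beta0": g_beta0,
        "a_raw": g_a * expit(raw["a_raw"]),
        "b_raw": g_b * expit(raw["b_raw"]),
    }
    if "beta" in raw:
        grads["beta"] = g_beta
    if include_pi:
        pi = softmax(raw["pi_raw"])
        nk = weights.sum(axis=0)
        value += float(nk @ np.log(np.maximum(pi, 1e-300)))
        value += _pi_log_prior(pi, hyper)
        tvec = nk + (hyper.alpha - 1.0)
        grads["pi_raw"] = tvec - pi * tvec.sum()
    return value, grads


def _onehot(z, K):
    z = np.asarray(z)
    out = np.zeros((len(z), K))
    out[np.arange(len(z)), z] = 1.0
    return out


# ---------------------------------------------------------------------------
# M-step / EM driver


def m_step(
    Y,
    gamma,
    params: MixtureParams,
    s,
    X,
    rho,
    hyper: HyperParams,
    n_grad_steps: int = 30,
    learning_rate: float = 0.01,
    include_pi: bool = True,
) -> tuple[MixtureParams, float]:
    """Partial M-step: Adam ascent on Q; returns the best iterate and its Q.

    The best-seen iterate (including the starting point) is returned, so
    ``Q(new) >= Q(old)`` always holds.
    """
    if n_grad_steps == 0:
        q0, _ = _q_value_and_grad(
            params.free_dict(include_pi), Y, gamma, s, X, rho, hyper, params,
            want_grad=False, include_pi=include_pi,
        )
        return params.copy(), q0

    if HAVE_NUMBA:
        def closure(raw):
            return _value_and_grad_fused(
                raw, Y, gamma, s, X, rho, hyper, params, include_pi=include_pi
            )
    else:
        def closure(raw):
            return _q_value_and_grad(
                raw, Y, gamma, s, X, rho, hyper, params, include_pi=include_pi
            )

    best, best_val, history = adam_maximize(
        closure, params.free_dict(include_pi), n_grad_steps, learning_rate
    )
    if best_val < history[0] - 1e-6:
        logger.warning("M-step failed to improve Q (%.6g -> %.6g)", history[0], best_val)
    return params.replace(best), best_val


def maximize_conditional(
    Y,
    z,
    params: MixtureParams,
    s,
    X,
    rho,
    hyper: HyperParams,
    n_grad_steps: int = 30,
    learning_rate: float = 0.01,
) -> tuple[MixtureParams, float]:
    """Gamma-update of the ICM loop: maximize the hard-label conditional
    log-likelihood L2 (plus the delta prior) by Adam, warm-started."""

    if HAVE_NUMBA:
        K = _as_array(rho, "rho").shape[1]
        onehot = _onehot(z, K)

        def closure(raw):
            return _value_and_grad_fused(
                raw, Y, onehot, s, X, rho, hyper, params, include_pi=False
            )
    else:
        def closure(raw):
            return _l2_value_and_grad(raw, Y, z, s, X, rho, hyper, params)

    best, best_val, _ = adam_maximize(
        closure, params.free_dict(include_pi=False), n_grad_steps, learning_rate
    )
    return params.replace(best), best_val


def fit_mixture(
    Y,
    rho,
    X=None,
    hyper: HyperParams | None = None,
    tol: float = 1e-4,
    max_em_iters: int = 50,
    n_grad_steps: int = 30,
    learning_rate: float = 0.01,
    seed: int = 0,
    params: MixtureParams | None = None,
    s: np.ndarray | None = None,
):
    """MAP EM fit of the NB mixture.

    Alternates E-step and partial (gradient) M-step until the relative
    change of the marginal log posterior falls below ``tol`` or
    ``max_em_iters`` is reached. Deterministic given ``seed``.

    Returns ``(params, gamma, history)`` where ``history`` is a dict of
    per-iteration traces (``q`` and ``loglik``).
    """
    Yarr = np.asarray(getattr(Y, "Y", Y))
    rho_arr = _as_array(rho, "rho")
    hyper = hyper or HyperParams()
    if s is None:
        s = compute_size_factors(Y)
    n_cov = 0 if X is None else np.asarray(X).shape[1]
    if params is None:
        rng = np.random.default_rng(seed)
        params = init_params(Yarr, rho_arr, n_cov, hyper, rng)

    history: dict[str, list[float]] = {"q": [], "loglik": []}
    prev_ll = -np.inf
    stall = 0
    converged = False
    gamma = e_step(Y, params, s, X, rho)
    for _ in range(max_em_iters):
        params, q_val = m_step(
            Y, gamma, params, s, X, rho, hyper, n_grad_steps, learning_rate
        )
        gamma = e_step(Y, params, s, X, rho)
        ll = marginal_log_posterior(Y, params, s, X, rho, hyper)
        history["q"].append(q_val)
        history["loglik"].append(ll)
        if ll <= prev_ll + 1e-9:
            stall += 1
            if stall >= 5:
                logger.warning("EM stalled for 5 iterations; stopping")
                converged = True
                break
        else:
            stall = 0
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol * (abs(prev_ll) + 1e-12):
            converged = True
            break
        prev_ll = ll
    history["converged"] = converged
    return params, gamma, history
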