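"""Fused numba kernel for the NB-mixture objective and gradient.

The gradient M-steps evaluate the weighted NB log-likelihood and its
gradient hundreds of times per fit; doing this with numpy temporaries over
an (N, G, K) tensor is memory-bound. The kernel below fuses the whole
computation into one pass and exploits two structural facts:

* for ``y = 0`` every gamma-function term of the NB log pmf vanishes;
* types not marked for a gene share the same mean (``rho_gk = 0`` makes
  ``delta`` inert), so their contributions are computed once with the
  summed weight.

``digamma`` is evaluated by the standard recurrence plus asymptotic
(Bernoulli) series, accurate to ~1e-13 for positive arguments, since
scipy.special is not callable from nopython code. The numpy reference
implementation in ``nb_mixture`` remains the fallback and the two are
asserted equivalent in the test suite.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def _digamma(x: float) -> float:
    # recurrence up to x >= 6, then the asymptotic series in 1/x^2
    r = 0.0
    while x < 6.0:
        r -= 1.0 / x
        x += 1.0
    f = 1.0 / (x * x)
    s = f * (
        1.0 / 12.0
        - f * (1.0 / 120.0 - f * (1.0 / 252.0 - f * (1.0 / 240.0 - f * (1.0 / 132.0))))
    )
    return r + math.log(x) - 0.5 / x - s


@njit(cache=False)
def _weighted_nb_value_grad(
    log_s, beta0, delta, rho, Xb, X, gamma, Y, a, b, centers, phi_floor,
    g_delta, g_beta0, g_beta, g_a, g_b,
):
    """Sum_i sum_k gamma_ik sum_g log NB(y_ig | mu_igk, phi_igk) and its
    gradient w.r.t. (delta, beta0, beta, a, b) in the natural (not raw)
    parameterization. Gradient buffers must come in zeroed; Xb is the
    precomputed X @ beta.T (empty when there are no covariates)."""
    N, K = gamma.shape
    G = beta0.shape[0]
    B = a.shape[0]
    P = g_beta.shape[1]
    has_cov = Xb.shape[0] > 0
    e = np.empty(B)
    t = np.empty(B)
    value = 0.0
    for i in range(N):
        for g in range(G):
            yv = Y[i, g]
            base = log_s[i] + beta0[g]
            if has_cov:
                base += Xb[i, g]
            gl_total = 0.0
            w_un = 0.0
            for k in range(K + 1):
                if k < K:
                    w = gamma[i, k]
                    if w == 0.0:
                        continue
                    if rho[g, k] == 0:
                        w_un += w
                        continue
                    logmu = base + delta[g, k]
                else:
                    # pooled contribution of all unmarked types
                    if w_un == 0.0:
                        continue
                    w = w_un
                    logmu = base
                mu = math.exp(logmu)
                phi_raw = 0.0
                for j in range(B):
                    tj = mu - centers[j]
                    ej = math.exp(-b[j] * tj * tj)
                    t[j] = tj
                    e[j] = ej
                    phi_raw += a[j] * ej
                active = phi_raw > phi_floor
                phi = phi_raw if active else phi_floor
                denom = phi + mu
                log_phi = math.log(phi)
                log_denom = math.log(denom)
                ll = phi * (log_phi - log_denom)
                d_mu = -phi / denom
                d_phi = log_phi + 1.0 - log_denom - phi / denom
                if yv > 0.0:
                    ll += (
                        math.lgamma(yv + phi)
                        - math.lgamma(phi)
                        - math.lgamma(yv + 1.0)
                        + yv * (logmu - log_denom)
                    )
                    d_mu += yv * (1.0 / mu - 1.0 / denom)
                    d_phi += _digamma(yv + phi) - _digamma(phi) - yv / denom
                if not active:
                    d_phi = 0.0
                value += w * ll
                wd = w * d_phi
                dphi_dmu = 0.0
                for j in range(B):
                    aej = a[j] * e[j]
                    dphi_dmu -= aej * 2.0 * b[j] * t[j]
                    g_a[j] += wd * e[j]
                    g_b[j] -= wd * aej * t[j] * t[j]
                gl = w * (d_mu + d_phi * dphi_dmu) * mu
                gl_total += gl
                if k < K:
                    g_delta[g, k] += gl
            g_beta0[g] += gl_total
            if P > 0:
                for p in range(P):
                    g_beta[g, p] += gl_total * X[i, p]
    return value
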