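"""Minimal Adam optimizer over flat parameter dictionaries.

Both gradient M-steps (mixture Q function and HMRF pseudolikelihood) run a
fixed number of first-order ascent steps per call; the caller supplies a
closure returning the objective and its gradient so that the best iterate
can be tracked and returned, which keeps the outer EM/ICM loops monotone
even when individual Adam steps overshoot.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["adam_maximize"]


def adam_maximize(
    value_and_grad: Callable[[dict[str, np.ndarray]], tuple[float, dict[str, np.ndarray]]],
    params: dict[str, np.ndarray],
    n_steps: int,
    learning_rate: float = 0.01,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
) -> tuple[dict[str, np.ndarray], float, list[float]]:
    """Run ``n_steps`` Adam ascent steps and return the best iterate seen.

    Parameters
    ----------
    value_and_grad
        Closure mapping a parameter dict to ``(objective, gradients)`` where
        gradients share the keys/shapes of the parameters. The objective is
        maximized.
    params
        Initial parameters. Not modified; arrays are copied.
    n_steps
        Number of Adam updates. ``0`` returns the input evaluated once.

    Returns
    -------
    best_params, best_value, history
        ``history`` holds the objective at the initial point and after each
        step (length ``n_steps + 1``).
    """
    cur = {k: np.array(v, dtype=float, copy=True) for k, v in params.items()}
    m = {k: np.zeros_like(v) for k, v in cur.items()}
    v = {k: np.zeros_like(val) for k, val in cur.items()}

    val, grad = value_and_grad(cur)
    if not np.isfinite(val):
        raise FloatingPointError("objective is non-finite at the initial point")
    best_val = val
    best = {k: arr.copy() for k, arr in cur.items()}
    history = [float(val)]

    for t in range(1, n_steps + 1):
        for key in cur:
            g = grad[key]
            if not np.all(np.isfinite(g)):
                raise FloatingPointError(f"non-finite gradient for parameter {key!r}")
            m[key] = beta1 * m[key] + (1.0 - beta1) * g
            v[key] = beta2 * v[key] + (1.0 - beta2) * g * g
            m_hat = m[key] / (1.0 - beta1**t)
            v_hat = v[key] / (1.0 - beta2**t)
            # ascent: objective is maximized
            cur[key] = cur[key] + learning_rate * m_hat / (np.sqrt(v_hat) + eps)
        val, grad = value_and_grad(cur)
        history.append(float(val))
        if np.isfinite(val) and val > best_val:
            best_val = float(val)
            best = {k: arr.copy() for k, arr in cur.items()}

    return best, float(best_val), history
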