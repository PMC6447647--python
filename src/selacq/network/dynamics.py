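"""Elementary pieces of the rate-network dynamics.

All functions are vectorized over numpy arrays and are pure: they take
voltages/thresholds and return the corresponding quantity without touching
simulation state.  The simulator composes them; the tests pin them against
closed forms.
"""

from __future__ import annotations

from typing import Union

import numpy as np
from scipy.special import expit

ArrayLike = Union[float, np.ndarray]

#: curvature constant of the BCM nonlinearity
BCM_GAIN = 6.75


class InvalidThresholdError(ValueError):
    """BCM threshold must be strictly positive."""


class UnstableAveragingError(ValueError):
    """gamma*dt >= 1 makes the running-average recurrence unstable."""


def activation(v: ArrayLike, theta_act: float) -> ArrayLike:
    """Threshold-linear firing rate F(v): v for v >= theta_act, else 0."""
    v = np.asarray(v)
    out = np.where(v >= theta_act, v, 0.0)
    return out if out.ndim else float(out)


def presyn_effect(v: ArrayLike, beta: float, theta_act: float,
                  convention: str = "centered") -> ArrayLike:
    """Presynaptic factor sigma(v) of the BCM rule: a logistic in v.

    Two argument conventions are supported because the source expression is
    under-determined:

    * ``"centered"`` (default): sigma(v) = 1 / (1 + exp(-beta*(v - theta_act))),
      the standard sigmoid with midpoint at the activation threshold;
    * ``"literal"``: sigma(v) = 1 / (1 + exp(-(beta*v + theta_act))).
    """
    v = np.asarray(v, dtype=float)
    if convention == "centered":
        arg = beta * (v - theta_act)
    elif convention == "literal":
        arg = beta * v + theta_act
    else:
        raise ValueError(f"unknown sigma convention {convention!r}")
    out = expit(arg)  # overflow-safe logistic
    return out if out.ndim else float(out)


def bcm_phi(v_post: ArrayLike, theta: ArrayLike) -> ArrayLike:
    """Postsynaptic BCM factor phi(v, theta).

    phi(v, theta) = 6.75 * v^2 * (v - theta) / theta^3
                    + tanh(6.75 * (v - theta) / theta)

    Zero at v = theta and v = 0 (up to the tanh term's value at -6.75),
    negative on (0, theta) (depression), positive above theta (potentiation).
    """
    v = np.asarray(v_post, dtype=float)
    theta_arr = np.asarray(theta, dtype=float)
    if np.any(theta_arr <= 0):
        raise InvalidThresholdError("BCM threshold theta must be > 0")
    diff = v - theta_arr
    out = BCM_GAIN * v * v * diff / theta_arr**3 + np.tanh(BCM_GAIN * diff / theta_arr)
    return out if out.ndim else float(out)


def update_threshold(theta_hat: ArrayLike, v_post: ArrayLike, gamma: float,
                     dt: float, *, step_count: int | None = None,
                     bias_correct: bool = False) -> tuple[ArrayLike, ArrayLike]:
    """One step of the sliding BCM threshold.

    ``theta_hat`` is an exponentially weighted running average of the
    postsynaptic voltage with per-step rate ``gamma * dt``:

        theta_hat <- (1 - gamma*dt) * theta_hat + gamma*dt * v_post

    Returns ``(theta_hat_new, theta_effective)``.  Under stationary dynamics
    the effective threshold converges to the temporal mean voltage.  With
    ``bias_correct=True`` the estimate is divided by ``1 - (1-gamma*dt)**k``
    (``k`` = number of updates so far, from ``step_count``), removing the
    start-up bias of an EMA initialized away from the data mean.
    """
    r = gamma * dt
    if r >= 1.0:
        raise UnstableAveragingError("gamma*dt must be < 1")
    theta_hat = np.asarray(theta_hat, dtype=float)
    new = (1.0 - r) * theta_hat + r * np.asarray(v_post, dtype=float)
    if bias_correct and r > 0 and step_count is not None and step_count >= 1:
        denom = 1.0 - (1.0 - r) ** step_count
        theta_eff = new / denom if denom > 0 else new
    else:
        theta_eff = new
    if not new.ndim:
        return float(new), float(np.asarray(theta_eff))
    return new, theta_eff
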