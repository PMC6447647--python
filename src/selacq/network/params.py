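"""Simulation parameters and probabilistic network topology.

The network has ``n_ex`` excitatory and ``n_inh`` inhibitory threshold-linear
rate neurons.  Excitatory-to-excitatory connections are reciprocal (as in
cortical horizontal and hippocampal CA3 circuits): unordered pairs are drawn
uniformly without replacement and each pair contributes both directed edges,
so the E->E adjacency matrix is symmetric.  E->I and I->E edges are drawn
independently per ordered pair.  Only E->E weights are plastic; E->I and I->E
weights are fixed scalars.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np


class InvalidParamsError(ValueError):
    """Raised when simulation parameters violate their invariants."""


@dataclass
class SimParams:
    """All constants of the E/I rate-network simulation.

    Time is in milliseconds; voltages, weights and currents are in arbitrary
    units.  Defaults are the reference configuration used throughout the
    package: a 400E/100I network with 20% connectivity, threshold-linear
    activation at ``theta_act``, BCM plasticity with gain ``alpha`` and
    presynaptic sigmoid slope ``beta``, and multiplicative synaptic scaling
    of each neuron's incoming plastic weights to total ``kappa``.
    """

    n_ex: int = 400
    n_inh: int = 100
    p_ee: float = 0.2
    p_ei: float = 0.2  # I -> E connection probability
    p_ie: float = 0.2  # E -> I connection probability
    tau_ex: float = 20.0  # ms
    tau_inh: float = 20.0  # ms
    tau_w: float = 1000.0  # ms
    theta_act: float = 1.0  # activation threshold of F(v)
    alpha: float = 0.1  # BCM gain
    beta: float = 5.0  # presynaptic sigmoid slope
    kappa: float = 0.5  # synaptic-scaling target for incoming-weight sums
    gamma: float = 0.001  # sliding-threshold averaging rate, 1/ms
    dt: float = 0.5  # ms
    w_ei_fixed: float = -0.025  # inhibitory -> excitatory weight (negative)
    w_ie_fixed: float = 0.2  # excitatory -> inhibitory weight
    noise_ex_mean: float = 1.0
    noise_ex_sd: float = 0.5
    noise_inh_mean: float = 0.0
    noise_inh_sd: float = 0.5
    seed: Optional[int] = None
    # -- conventions for under-determined pieces of the model, config-exposed --
    sigma_convention: str = "centered"  # "centered": beta*(v-theta); "literal": beta*v+theta
    bias_correct_theta: bool = False  # bias-corrected EMA for the BCM threshold
    scale_noise_white: bool = False  # multiply noise sd by sqrt(tau/dt)
    v_init: float = 0.0
    theta_hat_init: Optional[float] = None  # defaults to theta_act
    clamp_weights: bool = True  # keep plastic weights >= 0
    scaling_enabled: bool = True
    scaling_every: int = 1  # apply synaptic scaling every this many steps

    def __post_init__(self) -> None:
        if self.n_ex < 1 or self.n_inh < 1:
            raise InvalidParamsError("n_ex and n_inh must be >= 1")
        for name in ("tau_ex", "tau_inh", "tau_w", "dt"):
            if getattr(self, name) <= 0:
                raise InvalidParamsError(f"{name} must be strictly positive")
        for name in ("p_ee", "p_ei", "p_ie"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise InvalidParamsError(f"{name} must lie in [0, 1]")
        if self.noise_ex_sd < 0 or self.noise_inh_sd < 0:
            raise InvalidParamsError("noise standard deviations must be >= 0")
        if self.gamma < 0:
            raise InvalidParamsError("gamma must be >= 0")
        if self.gamma * self.dt >= 1.0:
            raise InvalidParamsError(
                "gamma*dt must be < 1 for a stable threshold average"
            )
        if self.scaling_every < 1:
            raise InvalidParamsError("scaling_every must be >= 1")
        if self.sigma_convention not in ("centered", "literal"):
            raise InvalidParamsError(
                "sigma_convention must be 'centered' or 'literal'"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        return cls(**d)

    @property
    def theta_hat_init_value(self) -> float:
        return self.theta_act if self.theta_hat_init is None else self.theta_hat_init

    def noise_sd_effective(self) -> tuple[float, float]:
        """Per-step noise sds, optionally white-noise scaled by sqrt(tau/dt)."""
        if self.scale_noise_white:
            return (
                self.noise_ex_sd * np.sqrt(self.tau_ex / self.dt),
                self.noise_inh_sd * np.sqrt(self.tau_inh / self.dt),
            )
        return self.noise_ex_sd, self.noise_inh_sd


@dataclass
class Topology:
    """Connectivity masks of the network.

    ``ee_mask[i, j]`` is True when excitatory neuron *j* projects to
    excitatory neuron *i* (row = postsynaptic target).  ``ei_mask`` maps
    inhibitory to excitatory neurons and ``ie_mask`` excitatory to
    inhibitory, same row-is-target orientation.
    """

    ee_mask: np.ndarray  # (n_ex, n_ex) bool, symmetric, zero diagonal
    ei_mask: np.ndarray  # (n_ex, n_inh) bool
    ie_mask: np.ndarray  # (n_inh, n_ex) bool

    def __post_init__(self) -> None:
        self.ee_mask = np.asarray(self.ee_mask, dtype=bool)
        self.ei_mask = np.asarray(self.ei_mask, dtype=bool)
        self.ie_mask = np.asarray(self.ie_mask, dtype=bool)
        if np.any(np.diagonal(self.ee_mask)):
            raise InvalidParamsError("ee_mask must have an empty diagonal")
        if not np.array_equal(self.ee_mask, self.ee_mask.T):
            raise InvalidParamsError("ee_mask must be symmetric (reciprocal edges)")

    @property
    def n_ex(self) -> int:
        return self.ee_mask.shape[0]

    @property
    def n_inh(self) -> int:
        return self.ei_mask.shape[1]

    @property
    def ee_edges(self) -> set[tuple[int, int]]:
        """Directed E->E edges as (post, pre) pairs."""
        return {(int(i), int(j)) for i, j in zip(*np.nonzero(self.ee_mask))}

    def n_ee_edges(self) -> int:
        return int(self.ee_mask.sum())

    def copy(self) -> "Topology":
        return Topology(self.ee_mask.copy(), self.ei_mask.copy(), self.ie_mask.copy())


def build_topology(params: SimParams, rng: np.random.Generator) -> Topology:
    """Draw a random topology under ``params``.

    E->E: ``round(p_ee * n_ex * (n_ex - 1) / 2)`` unordered pairs chosen
    uniformly without replacement, each expanded to both directed edges.
    E->I and I->E: each ordered pair connected independently with
    probability ``p_ie`` / ``p_ei`` respectively.
    """
    n = params.n_ex
    n_pairs_total = n * (n - 1) // 2
    n_pairs = int(round(params.p_ee * n * (n - 1) / 2))
    if n_pairs > n_pairs_total:
        raise InvalidParamsError(
            f"requested {n_pairs} E-E pairs but only {n_pairs_total} exist"
        )
    ee = np.zeros((n, n), dtype=bool)
    if n_pairs > 0:
        chosen = rng.choice(n_pairs_total, size=n_pairs, replace=False)
        # unrank: pair index -> (i, j), i < j, row-major over the upper triangle
        iu, ju = np.triu_indices(n, k=1)
        ee[iu[chosen], ju[chosen]] = True
        ee |= ee.T
    ei = rng.random((params.n_ex, params.n_inh)) < params.p_ei
    ie = rng.random((params.n_inh, params.n_ex)) < params.p_ie
    return Topology(ee_mask=ee, ei_mask=ei, ie_mask=ie)
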