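"""Time-stepping engine for the plastic E/I rate network.

Voltages follow leaky rate dynamics integrated with classical fourth-order
Runge-Kutta (noise currents drawn once per step and held constant across the
four stages); plastic E->E weights follow the BCM rule integrated with the
Euler method, then clamped non-negative and multiplicatively rescaled so each
excitatory neuron's incoming plastic weights sum to ``kappa`` (synaptic
scaling).  The weight dynamics are much slower than the voltage dynamics
(``tau_w >> tau_ex``), which is what justifies the cheaper integrator.

The per-step order of operations is: voltages (RK4) -> sliding BCM threshold
(EMA of the new voltage) -> weights (Euler, clamp, scaling) -> time advance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from selacq.network.params import SimParams, Topology, build_topology
from selacq.network.dynamics import bcm_phi, presyn_effect

# Effective BCM thresholds are clamped here before entering phi, whose 1/theta^3
# term diverges as theta -> 0+.  The clamp only binds if the running voltage
# average collapses to ~0, which does not happen at the reference parameters.
THETA_FLOOR = 1e-6


class NumericalDivergenceError(RuntimeError):
    """Voltages or weights became non-finite during integration."""

    def __init__(self, t: float, neuron_index: int, recording: "Recording | None" = None):
        super().__init__(
            f"non-finite state at t={t:.1f} ms (first bad neuron index {neuron_index})"
        )
        self.t = t
        self.neuron_index = neuron_index
        self.recording = recording


@dataclass
class NetworkState:
    """Evolving state: voltages, plastic weights, BCM threshold estimates, time."""

    v_ex: np.ndarray  # (n_ex,)
    v_inh: np.ndarray  # (n_inh,)
    w_ee: np.ndarray  # (n_ex, n_ex) dense, zero off the topology mask
    theta_hat: np.ndarray  # (n_ex,) running average of postsynaptic voltage
    t: float = 0.0  # ms
    step_count: int = 0

    def copy(self) -> "NetworkState":
        return NetworkState(
            self.v_ex.copy(), self.v_inh.copy(), self.w_ee.copy(),
            self.theta_hat.copy(), self.t, self.step_count,
        )


@dataclass
class RecordSpec:
    """What to sample while running.

    ``sample_every`` is in integration steps.  ``v_window``/``w_window`` are
    closed time intervals in ms restricting when voltages / designated weights
    are sampled (None = always).  ``w_edges`` lists (post, pre) index pairs of
    plastic weights to trace.
    """

    sample_every: int = 10
    v_window: Optional[tuple[float, float]] = None
    w_edges: Optional[np.ndarray] = None  # (k, 2) int
    w_window: Optional[tuple[float, float]] = None


@dataclass
class Recording:
    """Sampled traces produced by :meth:`RateNetwork.run`."""

    v_times: np.ndarray  # (Sv,) ms, strictly increasing
    v_ex: np.ndarray  # (Sv, n_ex)
    w_times: np.ndarray  # (Sw,) ms
    w: np.ndarray  # (Sw, k)
    w_edges: np.ndarray  # (k, 2) (post, pre)
    events: list = field(default_factory=list)  # (t_ms, description)

    @property
    def sample_times(self) -> np.ndarray:
        return self.v_times

    def v_in_window(self, t0: float, t1: float) -> np.ndarray:
        """Voltage samples with t0 <= t <= t1, shape (S, n_ex)."""
        sel = (self.v_times >= t0) & (self.v_times <= t1)
        return self.v_ex[sel]

    def w_in_window(self, t0: float, t1: float) -> np.ndarray:
        sel = (self.w_times >= t0) & (self.w_times <= t1)
        return self.w[sel]


def rk4_voltage_step(
    v_ex: np.ndarray,
    v_inh: np.ndarray,
    w_ee: np.ndarray,
    w_ei: np.ndarray,
    w_ie: np.ndarray,
    i_ex: np.ndarray,
    i_inh: np.ndarray,
    params: SimParams,
) -> tuple[np.ndarray, np.ndarray]:
    """One RK4 step of the coupled voltage ODEs with frozen weights and noise.

    tau_ex dv_ex/dt = -v_ex + W_ee F(v_ex) + W_ei F(v_inh) + I_ex
    tau_inh dv_inh/dt = -v_inh + W_ie F(v_ex) + I_inh
    """
    th = params.theta_act
    dt = params.dt
    inv_te = 1.0 / params.tau_ex
    inv_ti = 1.0 / params.tau_inh

    def drift(ve: np.ndarray, vi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        fe = ve * (ve >= th)
        fi = vi * (vi >= th)
        dve = (-ve + w_ee @ fe + w_ei @ fi + i_ex) * inv_te
        dvi = (-vi + w_ie @ fe + i_inh) * inv_ti
        return dve, dvi

    k1e, k1i = drift(v_ex, v_inh)
    k2e, k2i = drift(v_ex + 0.5 * dt * k1e, v_inh + 0.5 * dt * k1i)
    k3e, k3i = drift(v_ex + 0.5 * dt * k2e, v_inh + 0.5 * dt * k2i)
    k4e, k4i = drift(v_ex + dt * k3e, v_inh + dt * k3i)
    sixth = dt / 6.0
    return (
        v_ex + sixth * (k1e + 2.0 * k2e + 2.0 * k3e + k4e),
        v_inh + sixth * (k1i + 2.0 * k2i + 2.0 * k3i + k4i),
    )


def euler_weight_step(
    w_ee: np.ndarray,
    mask: np.ndarray,
    v_ex: np.ndarray,
    theta_eff: np.ndarray,
    params: SimParams,
) -> np.ndarray:
    """In-place Euler step of the BCM weight ODE on the masked entries.

    tau_w dw/dt = -w + alpha * phi(v_post, theta_post) * sigma(v_pre)
    """
    phi = bcm_phi(v_ex, np.maximum(theta_eff, THETA_FLOOR))
    sig = presyn_effect(v_ex, params.beta, params.theta_act, params.sigma_convention)
    delta = params.alpha * np.multiply.outer(phi, sig)
    delta -= w_ee
    delta *= (params.dt / params.tau_w)
    delta *= mask
    w_ee += delta
    if params.clamp_weights:
        np.maximum(w_ee, 0.0, out=w_ee)
    return w_ee


def apply_synaptic_scaling(
    w_ee: np.ndarray, mask: np.ndarray, kappa: float
) -> tuple[np.ndarray, int]:
    """Rescale each row (incoming plastic weights) to sum to kappa, in place.

    Rows whose incoming sum is <= 0 are skipped (degenerate); rows with no
    incoming edges at all are left untouched and not counted as degenerate.
    Returns ``(w_ee, n_degenerate)``.
    """
    sums = w_ee.sum(axis=1)
    has_in = mask.any(axis=1)
    ok = sums > 0.0
    factor = np.ones_like(sums)
    factor[ok] = kappa / sums[ok]
    w_ee *= factor[:, None]
    n_degenerate = int(np.count_nonzero(has_in & ~ok))
    return w_ee, n_degenerate


class RateNetwork:
    """A recurrent E/I rate network with BCM plasticity and synaptic scaling.

    Parameters
    ----------
    params
        Simulation constants.
    topology
        Connectivity; drawn from ``rng`` with :func:`build_topology` when None.
    rng
        Random source for topology and noise.  When None, built from
        ``params.seed``.  Same seed + params gives bit-identical runs.

    Examples
    --------
    >>> net = RateNetwork(SimParams(n_ex=40, n_inh=10, seed=0))
    >>> rec = net.run(t_end=1000.0)
    >>> rec.v_ex.shape[1]
    40
    """

    def __init__(
        self,
        params: SimParams,
        topology: Optional[Topology] = None,
        rng: Optional[np.random.Generator] = None,
    ):
        self.params = params
        self.rng = rng if rng is not None else np.random.default_rng(params.seed)
        self.topology = topology if topology is not None else build_topology(params, self.rng)
        if self.topology.n_ex != params.n_ex or self.topology.n_inh != params.n_inh:
            raise ValueError("topology shape does not match params")
        self._mask = self.topology.ee_mask.astype(float)
        self._w_ei = params.w_ei_fixed * self.topology.ei_mask.astype(float)
        self._w_ie = params.w_ie_fixed * self.topology.ie_mask.astype(float)
        self.degenerate_scaling_count = 0
        self.state = self._initial_state()

    # -- construction -------------------------------------------------------

    def _initial_state(self) -> NetworkState:
        p = self.params
        v_ex = np.full(p.n_ex, p.v_init, dtype=float)
        v_inh = np.full(p.n_inh, p.v_init, dtype=float)
        theta_hat = np.full(p.n_ex, p.theta_hat_init_value, dtype=float)
        # weights start uniform at kappa/indegree so scaling holds from step 0
        w = np.zeros((p.n_ex, p.n_ex), dtype=float)
        indeg = self.topology.ee_mask.sum(axis=1)
        rows = indeg > 0
        w[rows] = (p.kappa / indeg[rows])[:, None] * self._mask[rows]
        return NetworkState(v_ex=v_ex, v_inh=v_inh, w_ee=w, theta_hat=theta_hat)

    def reset(self) -> None:
        self.state = self._initial_state()
        self.degenerate_scaling_count = 0

    # -- structural edits ---------------------------------------------------

    def add_ee_edges(self, edges: Sequence[tuple[int, int]], weight: float = 0.0) -> int:
        """Add directed E->E edges that do not already exist, at ``weight``.

        Pre-existing edges keep their weights.  Returns the number of edges
        actually added.  The caller is responsible for keeping the edge set
        reciprocal (assembly insertion adds all ordered member pairs, which is
        symmetric by construction).
        """
        added = 0
        ee = self.topology.ee_mask
        for i, j in edges:
            if i == j or ee[i, j]:
                continue
            ee[i, j] = True
            self.state.w_ee[i, j] = weight
            added += 1
        if added:
            self._mask = ee.astype(float)
        return added

    # -- stepping -----------------------------------------------------------

    def _theta_effective(self) -> np.ndarray:
        p = self.params
        th = self.state.theta_hat
        if p.bias_correct_theta and p.gamma > 0 and self.state.step_count >= 1:
            denom = 1.0 - (1.0 - p.gamma * p.dt) ** self.state.step_count
            if denom > 0:
                return th / denom
        return th

    def step(self, plasticity: bool = True) -> None:
        """Advance the network by one dt: voltages, threshold, weights."""
        p = self.params
        s = self.state
        sd_ex, sd_inh = p.noise_sd_effective()
        i_ex = self.rng.normal(p.noise_ex_mean, sd_ex, p.n_ex) if sd_ex > 0 else np.full(p.n_ex, p.noise_ex_mean)
        i_inh = self.rng.normal(p.noise_inh_mean, sd_inh, p.n_inh) if sd_inh > 0 else np.full(p.n_inh, p.noise_inh_mean)
        s.v_ex, s.v_inh = rk4_voltage_step(
            s.v_ex, s.v_inh, s.w_ee, self._w_ei, self._w_ie, i_ex, i_inh, p
        )
        r = p.gamma * p.dt
        s.theta_hat *= 1.0 - r
        s.theta_hat += r * s.v_ex
        s.step_count += 1
        if plasticity:
            euler_weight_step(s.w_ee, self._mask, s.v_ex, self._theta_effective(), p)
            if p.scaling_enabled and s.step_count % p.scaling_every == 0:
                _, n_bad = apply_synaptic_scaling(s.w_ee, self.topology.ee_mask, p.kappa)
                self.degenerate_scaling_count += n_bad
        s.t += p.dt

    # -- simulation driver ---------------------------------------------------

    def run(
        self,
        t_end: float,
        events: Optional[Sequence[tuple[float, Callable[["RateNetwork"], None]]]] = None,
        record: Optional[RecordSpec] = None,
        check_every: int = 200,
    ) -> Recording:
        """Run from the current time to ``t_end`` ms, sampling per ``record``.

        ``events`` is a list of (time_ms, callback) structural changes (e.g.
        cell-assembly insertion) applied when the simulation clock reaches
        each time.  Raises :class:`NumericalDivergenceError` (carrying the
        recording collected so far) if the state becomes non-finite.
        """
        p = self.params
        record = record or RecordSpec()
        n_steps = int(round((t_end - self.state.t) / p.dt))
        if n_steps < 0:
            raise ValueError("t_end is before the current simulation time")
        pending = sorted(events or [], key=lambda e: e[0])
        w_edges = (
            np.asarray(record.w_edges, dtype=int)
            if record.w_edges is not None
            else np.empty((0, 2), dtype=int)
        )
        ew_rows = w_edges[:, 0] if len(w_edges) else np.empty(0, dtype=int)
        ew_cols = w_edges[:, 1] if len(w_edges) else np.empty(0, dtype=int)

        v_times: list[float] = []
        v_rows: list[np.ndarray] = []
        w_times: list[float] = []
        w_rows: list[np.ndarray] = []
        event_log: list[tuple[float, str]] = []

        def in_window(t: float, win: Optional[tuple[float, float]]) -> bool:
            return win is None or (win[0] <= t <= win[1])

        half_dt = 0.5 * p.dt
        for k in range(n_steps):
            while pending and pending[0][0] <= self.state.t + half_dt:
                t_ev, fn = pending.pop(0)
                fn(self)
                event_log.append((self.state.t, getattr(fn, "__name__", "event")))
            self.step()
            if (k + 1) % record.sample_every == 0:
                t = self.state.t
                if in_window(t, record.v_window):
                    v_times.append(t)
                    v_rows.append(self.state.v_ex.copy())
                if len(w_edges) and in_window(t, record.w_window):
                    w_times.append(t)
                    w_rows.append(self.state.w_ee[ew_rows, ew_cols].copy())
            if (k + 1) % check_every == 0 or k == n_steps - 1:
                if not np.isfinite(self.state.v_ex).all():
                    bad = int(np.argmax(~np.isfinite(self.state.v_ex)))
                    rec = self._finalize(v_times, v_rows, w_times, w_rows, w_edges, event_log)
                    raise NumericalDivergenceError(self.state.t, bad, rec)
        # apply any events scheduled exactly at t_end
        while pending and pending[0][0] <= self.state.t + half_dt:
            t_ev, fn = pending.pop(0)
            fn(self)
            event_log.append((self.state.t, getattr(fn, "__name__", "event")))
        return self._finalize(v_times, v_rows, w_times, w_rows, w_edges, event_log)

    @staticmethod
    def _finalize(v_times, v_rows, w_times, w_rows, w_edges, event_log) -> Recording:
        n_ex = v_rows[0].shape[0] if v_rows else 0
        return Recording(
            v_times=np.asarray(v_times, dtype=float),
            v_ex=np.asarray(v_rows, dtype=float).reshape(len(v_rows), n_ex),
            w_times=np.asarray(w_times, dtype=float),
            w=np.asarray(w_rows, dtype=float).reshape(len(w_rows), len(w_edges)),
            w_edges=w_edges,
            events=event_log,
        )
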