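"""Cell-assembly insertion and the assimilation-strength analysis.

A new memory item is modelled as a three-neuron cell assembly: at insertion
time all six directed connections among three excitatory neurons are added to
the topology with weight zero (existing connections keep their weights), and
the plastic dynamics are left to either strengthen or ignore them.

"Assimilation strength" of an assembly is the mean of its six internal
weights averaged over a late time window; it is compared, across many
assemblies, against the mean pre-insertion activity correlation (i) within
the assembly and (ii) between assembly members and the rest of the excitatory
population.  The experiment driver repeats this over several random
topologies and reports a Pearson r and p per topology for both comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from selacq.network import (
    RateNetwork,
    Recording,
    RecordSpec,
    SimParams,
    NumericalDivergenceError,
    build_topology,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CellAssembly:
    """Three excitatory neurons encoding one item, plus its insertion record."""

    members: tuple[int, int, int]
    inserted_at: float = 0.0  # ms
    added_edges: frozenset = frozenset()  # (post, pre) edges newly created

    def __post_init__(self):
        if len(set(self.members)) != 3:
            raise ValueError("a cell assembly needs exactly 3 distinct members")

    @property
    def member_edges(self) -> list[tuple[int, int]]:
        """All 6 directed edges among the members."""
        m = self.members
        return [(i, j) for i in m for j in m if i != j]


@dataclass
class AssimilationResult:
    """Per-assembly measurements for one simulation run."""

    assembly: CellAssembly
    mean_within_weight: float  # mean of 6 internal weights over the weight window
    mean_within_corr: float  # mean Pearson r over the 3 member pairs, corr window
    mean_out_corr: float  # mean Pearson r member x non-member, corr window


@dataclass
class TopologyTrialSummary:
    """Across-assembly correlations for one topology (one summary-table row)."""

    trial_id: int
    r_within: float
    p_within: float
    r_between: float
    p_between: float
    failed: bool = False


def select_assemblies(
    n_assemblies: int,
    n_ex: int,
    policy: str = "random",
    rng: Optional[np.random.Generator] = None,
) -> list[tuple[int, int, int]]:
    """Draw member triplets.

    ``policy="random"``: each triplet is a uniform sample of 3 distinct
    neurons; triplets may overlap.  ``policy="non-overlapping"``: neurons are
    partitioned, requiring ``3 * n_assemblies <= n_ex``.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if policy == "random":
        return [
            tuple(map(int, rng.choice(n_ex, 3, replace=False)))
            for _ in range(n_assemblies)
        ]
    if policy == "non-overlapping":
        if 3 * n_assemblies > n_ex:
            raise ValueError(
                f"non-overlapping policy needs 3*{n_assemblies} <= {n_ex} neurons"
            )
        perm = rng.permutation(n_ex)
        return [tuple(map(int, perm[3 * k: 3 * k + 3])) for k in range(n_assemblies)]
    raise ValueError(f"unknown policy {policy!r}")


def insert_assembly(
    net: RateNetwork, members: Sequence[int], weight: float = 0.0
) -> CellAssembly:
    """Add all six directed edges among ``members`` with initial ``weight``.

    Edges already present keep their weights; insertion is idempotent and
    preserves the reciprocity of the E->E adjacency (the member-pair edge set
    is symmetric by construction).
    """
    m = tuple(int(i) for i in members)
    edges = [(i, j) for i in m for j in m if i != j]
    before = {e for e in edges if net.topology.ee_mask[e]}
    net.add_ee_edges(edges, weight=weight)
    added = frozenset(e for e in edges if e not in before)
    return CellAssembly(members=m, inserted_at=net.state.t, added_edges=added)


def window_mean_weight(
    rec: Recording, assembly: CellAssembly, window: tuple[float, float]
) -> float:
    """Mean over the assembly's 6 directed weights and all samples in the window."""
    sel = (rec.w_times >= window[0]) & (rec.w_times <= window[1])
    if not sel.any():
        raise ValueError(f"no weight samples in window {window}")
    index = {tuple(e): k for k, e in enumerate(map(tuple, rec.w_edges))}
    try:
        cols = [index[e] for e in assembly.member_edges]
    except KeyError as exc:
        raise ValueError(f"edge {exc} not traced in this recording") from exc
    return float(rec.w[np.ix_(sel, cols)].mean())


def _window_corr_matrix(
    rec: Recording,
    window: tuple[float, float],
    on: str = "voltage",
    theta_act: float = 1.0,
) -> np.ndarray:
    """Population correlation matrix over the window.

    ``on="voltage"`` correlates the raw state variable v; ``on="rate"``
    correlates the threshold-linear firing rate F(v) (activity below
    threshold is silent).
    """
    v = rec.v_in_window(*window)
    if v.shape[0] < 3:
        raise ValueError(f"need >= 3 voltage samples in window {window}")
    if on == "rate":
        v = v * (v >= theta_act)
    elif on != "voltage":
        raise ValueError("correlation signal must be 'voltage' or 'rate'")
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(v.T)  # zero-variance traces give NaN rows
    return c


def window_correlations(
    rec: Recording,
    members: Sequence[int],
    window: tuple[float, float],
    corr_matrix: Optional[np.ndarray] = None,
) -> tuple[float, float]:
    """(mean within-pair r, mean member-vs-non-member r) over the window.

    Zero-variance traces yield NaN correlations and are excluded from the
    means (logged).  ``corr_matrix`` lets callers reuse one precomputed
    population correlation matrix across many assemblies.
    """
    c = corr_matrix if corr_matrix is not None else _window_corr_matrix(rec, window)
    m = list(members)
    within = np.array([c[m[0], m[1]], c[m[0], m[2]], c[m[1], m[2]]])
    outside = np.setdiff1d(np.arange(c.shape[0]), m)
    cross = c[np.ix_(m, outside)]
    n_bad = int(np.isnan(within).sum() + np.isnan(cross).sum())
    if n_bad:
        logger.warning("excluded %d zero-variance correlation pairs", n_bad)
    return float(np.nanmean(within)), float(np.nanmean(cross))


@dataclass
class AssimilationExperimentResults:
    """Results container for :class:`AssimilationExperiment`."""

    trials: list[TopologyTrialSummary]
    assembly_results: dict[int, list[AssimilationResult]]  # trial_id -> results
    params: SimParams

    def summary(self) -> pd.DataFrame:
        """Per-topology table: trial, r/p within, r/p between."""
        return pd.DataFrame(
            [
                {
                    "trial": t.trial_id,
                    "r_within": t.r_within,
                    "p_within": t.p_within,
                    "r_between": t.r_between,
                    "p_between": t.p_between,
                    "failed": t.failed,
                }
                for t in self.trials
            ]
        )

    def scatter_data(self, trial_id: int) -> pd.DataFrame:
        """Per-assembly coordinates (weight vs correlations) for one trial."""
        rows = [
            {
                "members": "-".join(map(str, r.assembly.members)),
                "mean_within_weight": r.mean_within_weight,
                "mean_within_corr": r.mean_within_corr,
                "mean_out_corr": r.mean_out_corr,
            }
            for r in self.assembly_results[trial_id]
        ]
        return pd.DataFrame(rows)


class AssimilationExperiment:
    """Insert cell assemblies into running networks and correlate
    assimilation strength with pre-insertion activity correlations.

    Parameters
    ----------
    params
        Network constants.
    n_assemblies, n_topologies
        Number of inserted triplets per run and of independent random
        topologies.
    burn_in, t_end
        Insertion time and stop time in ms.
    corr_window, weight_window
        Closed windows (ms) over which activity correlations (pre-insertion)
        and internal weights (post-insertion) are averaged.
    insertion_mode
        ``"joint"``: all assemblies inserted into one run per topology
        (default; correlations are measured before insertion, so the
        predictors are unaffected by sharing the run).  ``"sequential"``:
        one fresh run per assembly on the same topology.
    """

    def __init__(
        self,
        params: SimParams,
        n_assemblies: int = 100,
        n_topologies: int = 10,
        burn_in: float = 50_000.0,
        t_end: float = 90_000.0,
        corr_window: tuple[float, float] = (30_000.0, 50_000.0),
        weight_window: tuple[float, float] = (70_000.0, 90_000.0),
        sample_every: int = 10,
        assembly_policy: str = "random",
        insertion_mode: str = "joint",
        correlate: str = "voltage",
    ):
        if n_assemblies < 3:
            raise ValueError("need >= 3 assemblies for a correlation across assemblies")
        if insertion_mode not in ("joint", "sequential"):
            raise ValueError("insertion_mode must be 'joint' or 'sequential'")
        self.params = params
        self.n_assemblies = n_assemblies
        self.n_topologies = n_topologies
        self.burn_in = burn_in
        self.t_end = t_end
        self.corr_window = corr_window
        self.weight_window = weight_window
        self.sample_every = sample_every
        self.assembly_policy = assembly_policy
        self.insertion_mode = insertion_mode
        if correlate not in ("voltage", "rate"):
            raise ValueError("correlate must be 'voltage' or 'rate'")
        self.correlate = correlate

    # -- single topology -----------------------------------------------------

    def run_one_topology(
        self, rng: np.random.Generator, trial_id: int = 0
    ) -> tuple[TopologyTrialSummary, list[AssimilationResult]]:
        p = self.params
        triplets = select_assemblies(self.n_assemblies, p.n_ex, self.assembly_policy, rng)
        if self.insertion_mode == "joint":
            results = self._run_joint(rng, triplets)
        else:
            results = self._run_sequential(rng, triplets)
        w = np.array([r.mean_within_weight for r in results])
        cw = np.array([r.mean_within_corr for r in results])
        co = np.array([r.mean_out_corr for r in results])
        r_in, p_in = stats.pearsonr(w, cw)
        r_out, p_out = stats.pearsonr(w, co)
        return (
            TopologyTrialSummary(
                trial_id, float(r_in), float(p_in), float(r_out), float(p_out)
            ),
            results,
        )

    def _record_spec(self, edges: list[tuple[int, int]]) -> RecordSpec:
        return RecordSpec(
            sample_every=self.sample_every,
            v_window=self.corr_window,
            w_edges=np.asarray(edges, dtype=int),
            w_window=self.weight_window,
        )

    def _run_joint(
        self, rng: np.random.Generator, triplets: list[tuple[int, int, int]]
    ) -> list[AssimilationResult]:
        net = RateNetwork(self.params, rng=rng)
        edges = sorted({e for m in triplets for e in CellAssembly(m).member_edges})
        assemblies: list[CellAssembly] = []

        def insert_all(network: RateNetwork) -> None:
            for m in triplets:
                assemblies.append(insert_assembly(network, m))

        rec = net.run(
            self.t_end,
            events=[(self.burn_in, insert_all)],
            record=self._record_spec(edges),
        )
        c = _window_corr_matrix(
            rec, self.corr_window, on=self.correlate,
            theta_act=self.params.theta_act,
        )
        out = []
        for a in assemblies:
            mw = window_mean_weight(rec, a, self.weight_window)
            ci, co = window_correlations(rec, a.members, self.corr_window, corr_matrix=c)
            out.append(AssimilationResult(a, mw, ci, co))
        return out

    def _run_sequential(
        self, rng: np.random.Generator, triplets: list[tuple[int, int, int]]
    ) -> list[AssimilationResult]:
        topo = build_topology(self.params, rng)
        out = []
        for m in triplets:
            net = RateNetwork(
                self.params,
                topology=topo.copy(),
                rng=np.random.default_rng(rng.integers(2**31)),
            )
            holder: list[CellAssembly] = []

            def insert_one(network: RateNetwork, members=m) -> None:
                holder.append(insert_assembly(network, members))

            rec = net.run(
                self.t_end,
                events=[(self.burn_in, insert_one)],
                record=self._record_spec(CellAssembly(m).member_edges),
            )
            a = holder[0]
            mw = window_mean_weight(rec, a, self.weight_window)
            c = _window_corr_matrix(
                rec, self.corr_window, on=self.correlate,
                theta_act=self.params.theta_act,
            )
            ci, co = window_correlations(rec, a.members, self.corr_window, corr_matrix=c)
            out.append(AssimilationResult(a, mw, ci, co))
        return out

    # -- full experiment -----------------------------------------------------

    def run(self, seed: Optional[int] = None) -> AssimilationExperimentResults:
        """Run all topologies; failed (divergent) trials are flagged, not fatal."""
        root = np.random.default_rng(seed)
        trials: list[TopologyTrialSummary] = []
        per_assembly: dict[int, list[AssimilationResult]] = {}
        for k in range(self.n_topologies):
            rng = np.random.default_rng(root.integers(2**31))
            try:
                summary, results = self.run_one_topology(rng, trial_id=k + 1)
            except NumericalDivergenceError as exc:
                logger.error("trial %d diverged at t=%.0f ms", k + 1, exc.t)
                summary = TopologyTrialSummary(
                    k + 1, np.nan, np.nan, np.nan, np.nan, failed=True
                )
                results = []
            trials.append(summary)
            per_assembly[k + 1] = results
        return AssimilationExperimentResults(trials, per_assembly, self.params)
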