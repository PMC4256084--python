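"""Discrete-event queueing simulation of signal traffic on a directed network.

Signal units are generated network-wide as a Poisson process, each with a
uniformly random source and a uniformly random destination distinct from
the source.  A unit performs an unbiased random walk over directed
projections: at each node it is served for an Exponential(mu) time and
then forwarded along one efferent edge chosen with probability 1/k_out.
Arrival at the destination removes the unit immediately (it never
occupies server or buffer there).

Each node is a single server with a finite buffer of K slots (the server
slot is extra).  Queueing is last-in-first-out: an arriving unit that
finds the server busy joins the FRONT of the buffer; if the buffer is
full, the unit at the BACK — the oldest queued unit — is ejected from
the network and the newcomer still joins the front.  The unit in service
is never ejected, and service is non-preemptive.

All randomness flows from one seeded Mersenne Twister; exponential
variates are produced by the inverse transform ``-ln(u)/rate``.

Two entry points share the same mechanics: :func:`simulate` draws every
quantity from the seeded generator, while :func:`scripted_simulate`
replaces every stochastic draw with values from an explicit
:class:`Script`, which makes event-by-event walkthroughs exactly
reproducible in tests.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from heapq import heappop, heappush
from typing import Sequence

import numpy as np

from .network import DirectedNetwork

__all__ = [
    "SimParams",
    "SimResult",
    "Script",
    "simulate",
    "scripted_simulate",
    "sample_exponential",
]

_GEN = 0
_DEPART = 1


def sample_exponential(rate: float, u: float) -> float:
    """Inverse-transform exponential variate: ``-ln(u) / rate``.

    ``u`` must lie strictly in (0, 1) and ``rate`` must be positive.
    """
    if not rate > 0:
        raise ValueError(f"rate must be positive, got {rate}")
    if not 0.0 < u < 1.0:
        raise ValueError(f"u must lie in (0, 1), got {u}")
    return -math.log(u) / rate


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulation run.

    Attributes
    ----------
    rate_gen:
        lambda — network-wide exogenous generation rate (signal units per
        dimensionless time unit).
    rate_service:
        mu — service-completion rate at every node.
    buffer_capacity:
        K — buffer slots per node, excluding the server slot, so a node
        holds at most K + 1 units.
    duration:
        T — total simulated time.
    transient:
        Initial interval excluded from all windowed metrics.  Defaults to
        2% of the duration (40,000 time units at the full-scale
        T = 2,000,000).
    seed:
        Seed of the run's Mersenne Twister.
    per_node_generation:
        If True, replace the single network-wide Poisson stream by N
        independent per-node streams of rate lambda/N (statistically
        equivalent).
    count_deliveries_as_arrivals:
        Whether a unit absorbed at its destination still counts toward
        that node's arrival tally (default True).
    """

    rate_gen: float
    rate_service: float = 1.0
    buffer_capacity: int = 10
    duration: float = 100_000.0
    transient: float | None = None
    seed: int = 0
    per_node_generation: bool = False
    count_deliveries_as_arrivals: bool = True

    def __post_init__(self) -> None:
        if not self.rate_gen > 0:
            raise ValueError("rate_gen (lambda) must be positive")
        if not self.rate_service > 0:
            raise ValueError("rate_service (mu) must be positive")
        if int(self.buffer_capacity) != self.buffer_capacity or self.buffer_capacity < 1:
            raise ValueError("buffer_capacity (K) must be an integer >= 1")
        if not self.duration > 0:
            raise ValueError("duration (T) must be positive")
        t0 = self.transient_or_default()
        if not 0 <= t0 < self.duration:
            raise ValueError(f"transient must lie in [0, T), got {t0} vs T={self.duration}")

    def transient_or_default(self) -> float:
        return 0.02 * self.duration if self.transient is None else self.transient


@dataclass
class Script:
    """Deterministic replacement for every stochastic draw of a run.

    ``generations`` lists exogenous unit creations as (time, source,
    destination) label triples.  ``service_times`` maps a node label to
    the successive service durations consumed at that node, in the order
    services start there.  ``routing`` maps a node label to the
    successive efferent targets chosen at that node, one per service
    completion.
    """

    generations: Sequence[tuple[float, str, str]]
    service_times: dict[str, Sequence[float]]
    routing: dict[str, Sequence[str]]


@dataclass
class SimResult:
    """Complete outcome of one run.

    Windowed quantities (arrivals, busy time, contents integral, edge
    counts) cover the post-transient window (t0, T]; the conservation
    ledger covers the full run.  ``trajectory_log`` and the event logs
    are populated only when the run was recorded.
    """

    node_labels: tuple[str, ...]
    params: SimParams
    window: tuple[float, float]
    arrivals: np.ndarray  # per node, windowed count
    busy_time: np.ndarray  # per node, windowed
    contents_integral: np.ndarray  # per node, windowed time-integral of n_i
    edge_counts: np.ndarray  # N x N windowed traversal counts
    max_queue: np.ndarray  # per node, max |q_i| observed (full run)
    generated: int
    delivered: int
    ejected: int
    residual: int
    total_contents_series: tuple[np.ndarray, np.ndarray] | None = None
    # recorded-mode logs
    trajectory_log: dict[int, list[tuple[float, int, int, int]]] | None = None
    arrival_log: list[tuple[float, int, int, bool]] | None = None
    traversal_log: list[tuple[float, int, int, int]] | None = None
    fates: dict[int, str] | None = None
    hop_paths: dict[int, list[tuple[str, str]]] | None = None

    @property
    def window_length(self) -> float:
        return self.window[1] - self.window[0]

    def utilization(self) -> np.ndarray:
        return self.busy_time / self.window_length

    def mean_contents(self) -> np.ndarray:
        return self.contents_integral / self.window_length

    def contents_trajectory(self, node: str) -> tuple[np.ndarray, np.ndarray]:
        """Step function (times, n_i) for a recorded run.

        The value ``n[k]`` holds on ``[times[k], times[k+1])``.
        """
        if self.trajectory_log is None:
            raise ValueError("run was not recorded; pass record_events=True")
        i = self.node_labels.index(node)
        entries = self.trajectory_log[i]
        t = np.array([e[0] for e in entries])
        n = np.array([e[1] for e in entries])
        return t, n

    def conservation_ok(self) -> bool:
        return self.generated == self.delivered + self.ejected + self.residual


class _Engine:
    """Shared event mechanics; subclasses supply the stochastic draws."""

    def __init__(
        self,
        net: DirectedNetwork,
        params: SimParams,
        record_events: bool,
        sample_interval: float | None,
    ) -> None:
        self.net = net
        self.params = params
        self.n = net.n_nodes
        self.succ = [list(row) for row in net.successors()]
        self.labels = net.node_labels
        self.t0 = params.transient_or_default()
        self.T = params.duration
        self.K = int(params.buffer_capacity)
        self.record = record_events

        self.heap: list[tuple[float, int, int, int]] = []
        self._seq = 0
        self._uid = 0

        self.busy: list[tuple[int, int] | None] = [None] * self.n  # (uid, dest)
        self.queues: list[list[tuple[int, int]]] = [[] for _ in range(self.n)]
        self.occ = np.zeros(self.n, dtype=np.int64)  # n_i = s_i + |q_i|
        self.last_t = np.zeros(self.n, dtype=float)
        self.arrivals = np.zeros(self.n, dtype=np.int64)
        self.busy_acc = np.zeros(self.n, dtype=float)
        self.contents_acc = np.zeros(self.n, dtype=float)
        self.edge_counts = np.zeros((self.n, self.n), dtype=np.int64)
        self.max_queue = np.zeros(self.n, dtype=np.int64)
        self.generated = 0
        self.delivered = 0
        self.ejected = 0
        self.total_occ = 0

        self.sample_interval = sample_interval
        if sample_interval is not None:
            n_samples = int(math.floor(self.T / sample_interval)) + 1
            self.grid = np.arange(n_samples) * sample_interval
            self.series = np.zeros(n_samples, dtype=np.int64)
            self._next_sample = 0

        if record_events:
            self.trajectory_log: dict[int, list[tuple[float, int, int, int]]] = {
                i: [(0.0, 0, 0, 0)] for i in range(self.n)
            }
            self.arrival_log: list[tuple[float, int, int, bool]] = []
            self.traversal_log: list[tuple[float, int, int, int]] = []
            self.fates: dict[int, str] = {}
            self.hop_paths: dict[int, list[tuple[str, str]]] = {}

    # -- hooks implemented by subclasses ------------------------------------

    def schedule_first_generations(self) -> None:
        raise NotImplementedError

    def on_generation(self, t: float, node: int) -> None:
        """Create a unit for a generation event and reschedule its stream.

        ``node`` is -1 for the single network-wide stream, else the
        source node of a per-node stream.
        """
        raise NotImplementedError

    def service_time(self, node: int) -> float:
        raise NotImplementedError

    def route(self, node: int) -> int:
        raise NotImplementedError

    # -- mechanics -----------------------------------------------------------

    def _push(self, t: float, kind: int, node: int) -> None:
        heappush(self.heap, (t, self._seq, kind, node))
        self._seq += 1

    def _advance(self, i: int, t: float) -> None:
        """Accumulate windowed integrals for node i up to time t."""
        lt = self.last_t[i]
        if t > self.t0:
            lo = lt if lt > self.t0 else self.t0
            d = t - lo
            if d > 0:
                self.contents_acc[i] += self.occ[i] * d
                if self.busy[i] is not None:
                    self.busy_acc[i] += d
        self.last_t[i] = t

    def _log_state(self, i: int, t: float) -> None:
        if self.record:
            s = 0 if self.busy[i] is None else 1
            self.trajectory_log[i].append((t, int(self.occ[i]), s, len(self.queues[i])))

    def _start_service(self, i: int, t: float, unit: tuple[int, int]) -> None:
        self.busy[i] = unit
        self._push(t + self.service_time(i), _DEPART, i)

    def new_unit(self, t: float, src: int, dst: int) -> None:
        uid = self._uid
        self._uid += 1
        self.generated += 1
        if self.record:
            self.hop_paths[uid] = []
        self.handle_arrival(t, src, (uid, dst))

    def handle_arrival(self, t: float, i: int, unit: tuple[int, int]) -> None:
        uid, dst = unit
        if self.record:
            self.arrival_log.append((t, i, uid, dst == i))
        if dst == i:
            self.delivered += 1
            if t >= self.t0 and self.params.count_deliveries_as_arrivals:
                self.arrivals[i] += 1
            if self.record:
                self.fates[uid] = "delivered"
            return
        if t >= self.t0:
            self.arrivals[i] += 1
        self._advance(i, t)
        if self.busy[i] is None:
            self._start_service(i, t, unit)
        else:
            q = self.queues[i]
            if len(q) == self.K:
                old_uid, _ = q.pop(0)  # back of buffer = oldest queued unit
                self.ejected += 1
                self.total_occ -= 1
                if self.record:
                    self.fates[old_uid] = "ejected"
            q.append(unit)  # front of buffer
            if len(q) > self.max_queue[i]:
                self.max_queue[i] = len(q)
        self.occ[i] = (0 if self.busy[i] is None else 1) + len(self.queues[i])
        self.total_occ += 1
        self._log_state(i, t)

    def handle_departure(self, t: float, i: int) -> None:
        unit = self.busy[i]
        assert unit is not None
        uid, dst = unit
        self._advance(i, t)
        q = self.queues[i]
        if q:
            nxt = q.pop()  # front of buffer = most recent arrival (LIFO)
            self._start_service(i, t, nxt)
        else:
            self.busy[i] = None
        self.occ[i] = (0 if self.busy[i] is None else 1) + len(q)
        self.total_occ -= 1
        self._log_state(i, t)
        j = self.route(i)
        if t >= self.t0:
            self.edge_counts[i, j] += 1
        if self.record:
            self.traversal_log.append((t, i, j, uid))
            self.hop_paths[uid].append((self.labels[i], self.labels[j]))
        self.handle_arrival(t, j, unit)

    def _sample_up_to(self, t: float) -> None:
        k = self._next_sample
        grid = self.grid
        while k < grid.size and grid[k] < t:
            self.series[k] = self.total_occ
            k += 1
        self._next_sample = k

    def run(self) -> SimResult:
        self.schedule_first_generations()
        heap = self.heap
        T = self.T
        sampling = self.sample_interval is not None
        while heap:
            t, _, kind, node = heappop(heap)
            if t > T:
                break
            if sampling:
                self._sample_up_to(t)
            if kind == _GEN:
                self.on_generation(t, node)
            else:
                self.handle_departure(t, node)
        for i in range(self.n):
            self._advance(i, T)
            if self.record:
                self._log_state(i, T)
        if sampling:
            self._sample_up_to(T + 1e-12)
            self.series[self._next_sample :] = self.total_occ
        residual = int(self.total_occ)
        if self.record:
            for i in range(self.n):
                unit = self.busy[i]
                if unit is not None:
                    self.fates[unit[0]] = "in_system"
                for uid, _ in self.queues[i]:
                    self.fates[uid] = "in_system"
        return SimResult(
            node_labels=self.labels,
            params=self.params,
            window=(self.t0, T),
            arrivals=self.arrivals,
            busy_time=self.busy_acc,
            contents_integral=self.contents_acc,
            edge_counts=self.edge_counts,
            max_queue=self.max_queue,
            generated=self.generated,
            delivered=self.delivered,
            ejected=self.ejected,
            residual=residual,
            total_contents_series=(self.grid, self.series) if sampling else None,
            trajectory_log=self.trajectory_log if self.record else None,
            arrival_log=self.arrival_log if self.record else None,
            traversal_log=self.traversal_log if self.record else None,
            fates=self.fates if self.record else None,
            hop_paths=self.hop_paths if self.record else None,
        )


class _RandomEngine(_Engine):
    def __init__(self, net, params, record_events, sample_interval):
        super().__init__(net, params, record_events, sample_interval)
        # a stochastic walk can reach any node, so every node needs an exit;
        # scripted runs only need exits where a departure is actually scripted
        dead = np.flatnonzero(net.out_degrees() == 0)
        if dead.size:
            names = [net.node_labels[i] for i in dead[:5]]
            raise ValueError(
                f"{dead.size} node(s) with out-degree 0 (e.g. {names}); "
                "every node must have at least one efferent projection"
            )
        self.rng = random.Random(params.seed)

    def _exp(self, rate: float) -> float:
        # 1 - random() lies in (0, 1], and -ln(1.0) = 0 is a valid variate
        return -math.log(1.0 - self.rng.random()) / rate

    def schedule_first_generations(self) -> None:
        if self.params.per_node_generation:
            rate = self.params.rate_gen / self.n
            for i in range(self.n):
                self._push(self._exp(rate), _GEN, i)
        else:
            self._push(self._exp(self.params.rate_gen), _GEN, -1)

    def on_generation(self, t: float, node: int) -> None:
        if node < 0:  # network-wide stream, uniform random source
            src = self.rng.randrange(self.n)
            self._push(t + self._exp(self.params.rate_gen), _GEN, -1)
        else:  # per-node stream of rate lambda/N
            src = node
            self._push(t + self._exp(self.params.rate_gen / self.n), _GEN, node)
        dst = self.rng.randrange(self.n - 1)
        if dst >= src:
            dst += 1
        self.new_unit(t, src, dst)


class _ScriptedEngine(_Engine):
    def __init__(self, net, params, script: Script, record_events, sample_interval):
        super().__init__(net, params, record_events, sample_interval)
        gens = sorted(script.generations, key=lambda g: g[0])
        self._gens: list[tuple[float, int, int]] = []
        for t, s, d in gens:
            if t < 0:
                raise ValueError(f"generation time must be non-negative, got {t}")
            si, di = net.index_of(s), net.index_of(d)
            if si == di:
                raise ValueError(f"unit generated at its own destination {s!r}")
            self._gens.append((t, si, di))
        self._svc = {
            net.index_of(n): list(v) for n, v in script.service_times.items()
        }
        self._routes = {}
        for n, targets in script.routing.items():
            i = net.index_of(n)
            chosen = []
            for lbl in targets:
                j = net.index_of(lbl)
                if not net.adjacency[i, j]:
                    raise ValueError(f"scripted hop {n!r}->{lbl!r} is not an edge")
                chosen.append(j)
            self._routes[i] = chosen
        self._gen_idx = 0

    def schedule_first_generations(self) -> None:
        for t, _, _ in self._gens:
            self._push(t, _GEN, -1)

    def on_generation(self, t: float, node: int) -> None:
        _, src, dst = self._gens[self._gen_idx]
        self._gen_idx += 1
        self.new_unit(t, src, dst)

    def service_time(self, node: int) -> float:
        try:
            return self._svc[node].pop(0)
        except (KeyError, IndexError):
            raise ValueError(
                f"script exhausted service times for node {self.labels[node]!r}"
            ) from None

    def route(self, node: int) -> int:
        try:
            return self._routes[node].pop(0)
        except (KeyError, IndexError):
            raise ValueError(
                f"script exhausted routing choices for node {self.labels[node]!r}"
            ) from None


def _attach_random_draws(engine: _RandomEngine) -> None:
    mu = engine.params.rate_service
    rng = engine.rng
    succ = engine.succ
    engine.service_time = lambda node: -math.log(1.0 - rng.random()) / mu  # type: ignore[method-assign]

    def route(node: int) -> int:
        s = succ[node]
        return s[rng.randrange(len(s))] if len(s) > 1 else s[0]

    engine.route = route  # type: ignore[method-assign]


def simulate(
    net: DirectedNetwork,
    params: SimParams,
    record_events: bool = False,
    sample_interval: float | None = None,
) -> SimResult:
    """Run one seeded stochastic simulation.

    Parameters
    ----------
    record_events:
        Keep full per-node state trajectories, arrival/traversal logs and
        unit fates.  Memory grows with event count, so reserve this for
        short runs and tests.
    sample_interval:
        If given, the total network contents are sampled on a uniform
        grid of this spacing (used for transient estimation and
        steady/jammed classification).
    """
    engine = _RandomEngine(net, params, record_events, sample_interval)
    _attach_random_draws(engine)
    return engine.run()


def scripted_simulate(
    net: DirectedNetwork,
    params: SimParams,
    script: Script,
    record_events: bool = True,
    sample_interval: float | None = None,
) -> SimResult:
    """Run the identical event mechanics with all draws read from a script."""
    engine = _ScriptedEngine(net, params, script, record_events, sample_interval)
    return engine.run()
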