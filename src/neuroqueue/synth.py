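"""Synthetic networks and scripted scenarios with known ground truth.

The central construction is a *planted funnel*: a sparse directed
background graph plus a small motif in which one or two relay nodes
receive many afferents but keep only one or two efferents, all (or at
least one) of which point at a designated target node.  This reproduces
the degree imbalance that concentrates random-walk traffic downstream —
a relay that absorbs signal units from dozens of sources but can only
forward them to one place acts as a funnel, and the target becomes a
convergence zone.  Because the construction is explicit, the analysis
pipeline can be validated against ground truth: the target must show a
large positive traffic excess over degree-matched surrogates, and the
excess must vanish when all unidirectional projections are reversed.

Also provided is the three-node walkthrough fixture: a 1->2->3 chain
with two-slot buffers and a fully scripted event timeline in which an
arriving unit displaces and ejects the oldest queued unit.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import numpy as np

from .network import DirectedNetwork
from .simulate import Script

__all__ = [
    "FunnelSpec",
    "generate_background",
    "generate_background_configuration",
    "plant_funnel",
    "make_funnel_network",
    "fig_walkthrough_fixture",
]


@dataclass(frozen=True)
class FunnelSpec:
    """Parameters of the planted funnel motif.

    Defaults mimic the archetypal anatomy: two relays with 34 and 41
    afferents and out-degrees 1 and 2, all feeding one target (the
    second relay keeps one extra efferent, like area TFL's projection to
    prosubiculum alongside CA1).
    """

    n_nodes: int = 100
    background_p: float = 0.06
    afferents_per_relay: tuple[int, ...] = (34, 41)
    relay_out_degrees: tuple[int, ...] = (1, 2)
    target: str = "target"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.afferents_per_relay) != len(self.relay_out_degrees):
            raise ValueError("one out-degree per relay is required")
        for k_in, k_out in zip(self.afferents_per_relay, self.relay_out_degrees):
            if k_in <= k_out:
                raise ValueError(
                    "a relay must have many more afferents than efferents "
                    f"(got k_in={k_in}, k_out={k_out})"
                )
        if self.n_nodes < max(self.afferents_per_relay, default=0) + 3:
            raise ValueError("not enough nodes for distinct relay afferents")

    @property
    def n_relays(self) -> int:
        return len(self.afferents_per_relay)

    @property
    def relay_labels(self) -> tuple[str, ...]:
        return tuple(f"relay{i + 1}" for i in range(self.n_relays))


def generate_background(
    n_nodes: int,
    p: float,
    seed: int,
    labels: tuple[str, ...] | None = None,
    require_in_degree: bool = False,
    max_retries: int = 50,
) -> DirectedNetwork:
    """Directed Erdős–Rényi graph with no self-loops.

    Regenerated (bounded retries, deterministic seed progression) until
    every node has out-degree >= 1 — the simulator's precondition — and,
    if ``require_in_degree``, in-degree >= 1 as well (needed when the
    network must stay simulable under full direction reversal).
    """
    if not 0 < p < 1:
        raise ValueError(f"edge probability must lie in (0, 1), got {p}")
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if labels is None:
        labels = tuple(f"n{i:03d}" for i in range(n_nodes))
    for retry in range(max_retries):
        rng = np.random.default_rng((seed + 1_000_003 * retry) % (2**31))
        adj = (rng.random((n_nodes, n_nodes)) < p).astype(np.int8)
        np.fill_diagonal(adj, 0)
        if adj.sum(axis=1).min() >= 1 and (
            not require_in_degree or adj.sum(axis=0).min() >= 1
        ):
            return DirectedNetwork(labels, adj)
    raise RuntimeError(
        f"no background with the required degrees in {max_retries} draws; "
        f"p={p} is too small for n={n_nodes}"
    )


def generate_background_configuration(
    in_degrees: "np.ndarray",
    out_degrees: "np.ndarray",
    seed: int,
    labels: tuple[str, ...] | None = None,
    max_retries: int = 50,
) -> DirectedNetwork:
    """Directed configuration-model background from a target degree sequence.

    Samples a directed multigraph with the given in/out-degree sequence
    (e.g. one resampled from an empirical connectome) and simplifies it
    by dropping self-loops and parallel edges, so realized degrees can
    fall slightly below the targets on dense sequences.  Retries until
    every node keeps out-degree >= 1.  Harder test bed than the
    homogeneous random background: broad degree distributions produce
    hubs that compete with a planted funnel for traffic.
    """
    import networkx as nx

    in_degrees = [int(d) for d in in_degrees]
    out_degrees = [int(d) for d in out_degrees]
    if sum(in_degrees) != sum(out_degrees):
        raise ValueError("in- and out-degree sequences must have equal sums")
    n = len(in_degrees)
    if labels is None:
        labels = tuple(f"n{i:03d}" for i in range(n))
    for retry in range(max_retries):
        g = nx.directed_configuration_model(
            in_degrees,
            out_degrees,
            seed=(seed + 1_000_003 * retry) % (2**31),
        )
        simple = nx.DiGraph(g)  # collapses parallel edges
        simple.remove_edges_from(nx.selfloop_edges(simple))
        adj = np.zeros((n, n), dtype=np.int8)
        for u, v in simple.edges():
            adj[u, v] = 1
        if adj.sum(axis=1).min() >= 1:
            return DirectedNetwork(labels, adj)
    raise RuntimeError(
        f"no simulable configuration-model draw in {max_retries} attempts "
        "(some node's out-degree keeps collapsing to 0)"
    )


def plant_funnel(net: DirectedNetwork, spec: FunnelSpec) -> DirectedNetwork:
    """Plant the relay->target funnel motif into an existing network.

    The last ``n_relays + 1`` nodes (in label order) are re-cast as the
    relays and the target.  Each relay receives ``afferents_per_relay``
    incoming edges from distinct non-relay, non-target nodes, and its
    efferents are pruned to ``relay_out_degree`` edges with the target
    always included.  Planted edges are forced unidirectional (their
    reciprocals are removed) so that the direction-reversal null acts on
    all of them.
    """
    if spec.n_relays == 0:
        return net
    n = net.n_nodes
    if n < spec.n_relays + 1:
        raise ValueError("network too small for the requested motif")
    adj = np.array(net.adjacency, copy=True)
    relay_idx = list(range(n - spec.n_relays - 1, n - 1))
    target_idx = n - 1
    rng = random.Random(spec.seed + 777)
    others = [i for i in range(n) if i not in relay_idx and i != target_idx]
    for r, (k_in, k_out) in zip(
        relay_idx, zip(spec.afferents_per_relay, spec.relay_out_degrees)
    ):
        if k_in > len(others):
            raise ValueError(
                f"relay needs {k_in} distinct afferents but only {len(others)} "
                "candidate nodes exist"
            )
        # afferents: k_in distinct sources, planted unidirectionally
        adj[:, r] = 0
        adj[r, :] = 0
        sources = rng.sample(others, k_in)
        for s in sources:
            adj[s, r] = 1
        # efferents: target first, then extras chosen outside the afferent
        # set so that forcing unidirectionality never deletes an afferent
        extra = rng.sample([i for i in others if i not in sources], k_out - 1)
        for tgt in [target_idx] + extra:
            adj[r, tgt] = 1
            adj[tgt, r] = 0  # force unidirectional
    labels = list(net.node_labels)
    for r, name in zip(relay_idx, spec.relay_labels):
        labels[r] = name
    labels[target_idx] = spec.target
    return DirectedNetwork(tuple(labels), adj)


def make_funnel_network(spec: FunnelSpec, max_retries: int = 50) -> DirectedNetwork:
    """Background + planted funnel, guaranteed simulable both ways.

    Retries the whole construction (deterministic seed progression)
    until every node of both the network and its fully direction-
    reversed counterpart has out-degree >= 1, so the reversal null is
    always simulable.
    """
    from .nulls import reverse_fraction

    for retry in range(max_retries):
        seed = (spec.seed + 60013 * retry) % (2**31)
        bg = generate_background(
            spec.n_nodes, spec.background_p, seed=seed, require_in_degree=True
        )
        net = plant_funnel(bg, FunnelSpec(**{**spec.__dict__, "seed": seed}))
        if net.out_degrees().min() < 1 or net.in_degrees().min() < 1:
            continue
        reversed_net = reverse_fraction(net, 1.0, seed=0)
        if reversed_net.out_degrees().min() >= 1:
            return net
    raise RuntimeError(f"no simulable funnel network found in {max_retries} draws")


def fig_walkthrough_fixture() -> tuple[DirectedNetwork, "Script", dict]:
    """The 3-node chain walkthrough with a fully scripted timeline.

    Network: 1 -> 2 -> 3 with two-slot buffers.  The script stages four
    units so that node 2's buffer fills and a newly arriving unit
    displaces the oldest queued unit, which is ejected:

    * ``blue`` is generated at node 2 (t=0.0) and serves there until t=6;
      ``green`` (t=0.1) waits in node 2's buffer.
    * ``red`` (t=0.0) and ``teal`` (t=0.1) are generated at node 1; red
      serves until t=2, then hops to node 2 and joins the buffer front
      ([green, red]); teal serves at node 1 until t=4.
    * At t=4 teal hops to node 2: the buffer is full, the oldest unit
      (green) is ejected, teal joins the front ([red, teal]).
    * At t=6 blue completes at node 2 and moves to node 3, entering its
      empty server; teal, at the buffer front, commences service at
      node 2.

    Returns (network, script, expected) where ``expected`` records the
    ground-truth ledger and per-unit fates for assertions.
    """
    net = DirectedNetwork.from_edges(("1", "2", "3"), [("1", "2"), ("2", "3")])
    script = Script(
        generations=[
            (0.0, "2", "1"),  # blue
            (0.1, "2", "1"),  # green
            (0.0, "1", "3"),  # red
            (0.1, "1", "3"),  # teal
        ],
        service_times={
            "1": [2.0, 2.0],  # red, teal
            "2": [6.0, 5.0],  # blue, then teal (unfinished at T=8)
            "3": [10.0],  # blue (unfinished at T=8)
        },
        routing={"1": ["2", "2"], "2": ["3"]},
    )
    expected = {
        "duration": 8.0,
        "buffer_capacity": 2,
        "generated": 4,
        "delivered": 0,
        "ejected": 1,
        "residual": 3,
        "node3_arrivals": 1,
        # uid order follows time-sorted generations: blue=0, red=1, green=2, teal=3
        "fates": {0: "in_system", 1: "in_system", 2: "ejected", 3: "in_system"},
    }
    return net, script, expected
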