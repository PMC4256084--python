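"""Surrogate-network families for statistical inference.

Two null models probe different structural ingredients:

* **Degree-preserving rewiring** (Maslov–Sneppen edge switching): pairs
  of directed edges ``a->b, c->d`` are repeatedly swapped to
  ``a->d, c->b`` whenever the swap creates neither a self-loop nor a
  duplicate edge.  Every node keeps its exact in- and out-degree while
  higher-order topology is destroyed.

* **Fractional direction reversal**: a uniformly random subset of the
  *unidirectional* projections has its direction flipped; reciprocal
  pairs are untouched.  This keeps the degree distribution's building
  blocks (edge count, number of reciprocal pairs) while testing the
  causal role of projection directionality.

Both constructions are deterministic functions of (network, seed).
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import numpy as np

from .network import DirectedNetwork, unidirectional_edges

__all__ = [
    "SurrogateSpec",
    "rewire_degree_preserving",
    "reverse_fraction",
    "surrogate_ensemble",
]

PAPER_REVERSAL_FRACTIONS = (0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass(frozen=True)
class SurrogateSpec:
    """Recipe for one surrogate network.

    ``kind`` is ``"rewired"`` or ``"reversed"``; ``swap_attempts``
    applies to rewiring (default 10x the edge count), and
    ``reversal_fraction`` to reversal.
    """

    kind: str
    seed: int
    swap_attempts: int | None = None
    reversal_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("rewired", "reversed"):
            raise ValueError(f"kind must be 'rewired' or 'reversed', got {self.kind!r}")
        if self.kind == "reversed":
            f = self.reversal_fraction
            if f is None or not 0.0 <= f <= 1.0:
                raise ValueError(f"reversal_fraction must lie in [0, 1], got {f}")


def make_surrogate(net: DirectedNetwork, spec: SurrogateSpec) -> DirectedNetwork:
    if spec.kind == "rewired":
        return rewire_degree_preserving(net, seed=spec.seed, swap_attempts=spec.swap_attempts)
    return reverse_fraction(net, fraction=spec.reversal_fraction, seed=spec.seed)


def rewire_degree_preserving(
    net: DirectedNetwork,
    seed: int,
    swap_attempts: int | None = None,
    max_successful_swaps: int | None = None,
) -> DirectedNetwork:
    """Randomize topology while preserving every node's (k_in, k_out).

    ``swap_attempts`` draws are made (default ``10 * |E|``); a draw that
    would create a self-loop or duplicate edge is rejected but still
    consumes one attempt.  ``max_successful_swaps`` optionally stops the
    chain after that many applied swaps (useful for stepwise tests).  If
    no draw ever succeeds on a degenerate network, the input is returned
    unchanged with a warning.
    """
    m = net.n_edges
    if m < 2:
        raise ValueError("rewiring needs at least 2 edges")
    attempts = 10 * m if swap_attempts is None else int(swap_attempts)
    rng = random.Random(seed)
    src, dst = np.nonzero(net.adjacency)
    edges = list(zip(src.tolist(), dst.tolist()))
    edge_set = set(edges)
    successes = 0
    for _ in range(attempts):
        e1 = rng.randrange(m)
        e2 = rng.randrange(m)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        # swap to a->d, c->b
        if a == d or c == b:
            continue
        if (a, d) in edge_set or (c, b) in edge_set:
            continue
        edge_set.discard((a, b))
        edge_set.discard((c, d))
        edge_set.add((a, d))
        edge_set.add((c, b))
        edges[e1] = (a, d)
        edges[e2] = (c, b)
        successes += 1
        if max_successful_swaps is not None and successes >= max_successful_swaps:
            break
    if successes == 0:
        warnings.warn(
            f"no legal edge swap found in {attempts} attempts; returning the "
            "network unchanged",
            stacklevel=2,
        )
    adj = np.zeros_like(net.adjacency)
    rows, cols = zip(*edges)
    adj[list(rows), list(cols)] = 1
    return DirectedNetwork(net.node_labels, adj)


def reverse_fraction(
    net: DirectedNetwork,
    fraction: float,
    seed: int,
) -> DirectedNetwork:
    """Flip the direction of a random subset of unidirectional projections.

    Exactly ``round(fraction * U)`` of the ``U`` unidirectional edges
    (round-half-up), sampled without replacement, are replaced by their
    opposite-direction counterparts.  Reciprocal pairs are untouched and
    the edge count is preserved.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    uni = unidirectional_edges(net)
    n_flip = int(np.floor(fraction * len(uni) + 0.5))
    rng = random.Random(seed)
    chosen = rng.sample(range(len(uni)), n_flip) if n_flip else []
    adj = np.array(net.adjacency, copy=True)
    for k in chosen:
        i = net.index_of(uni[k][0])
        j = net.index_of(uni[k][1])
        adj[i, j] = 0
        adj[j, i] = 1
    return DirectedNetwork(net.node_labels, adj)


def surrogate_ensemble(
    net: DirectedNetwork,
    spec_kind: str,
    n_surrogates: int,
    base_seed: int,
    reversal_fraction: float | None = None,
    swap_attempts: int | None = None,
    require_simulable: bool = True,
    max_retries: int = 20,
) -> list[tuple[DirectedNetwork, SurrogateSpec]]:
    """Generate ``n_surrogates`` surrogates with per-surrogate derived seeds.

    When ``require_simulable`` every surrogate must leave all nodes with
    out-degree >= 1 (the simulator's precondition); violating draws are
    regenerated with a shifted seed, up to ``max_retries`` per surrogate.
    Note that a fraction-1.0 reversal is deterministic, so if it strands
    a node the retry cannot help and an error is raised.
    """
    out = []
    for k in range(n_surrogates):
        for retry in range(max_retries):
            seed = (base_seed + 7919 * k + 104729 * retry) % (2**31)
            spec = SurrogateSpec(
                kind=spec_kind,
                seed=seed,
                swap_attempts=swap_attempts,
                reversal_fraction=reversal_fraction,
            )
            candidate = make_surrogate(net, spec)
            if not require_simulable or candidate.out_degrees().min() >= 1:
                out.append((candidate, spec))
                break
        else:
            raise RuntimeError(
                f"could not generate a simulable {spec_kind!r} surrogate in "
                f"{max_retries} attempts (a node keeps losing all efferents)"
            )
    return out
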