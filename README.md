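# neuroqueue

Discrete-event queueing analysis of signal traffic on directed
connectomes: which brain areas does the *wiring* of a network — its
topology and the directionality of its projections — turn into
communication hubs, beyond what their connection counts predict?

The motivating case is the hippocampus. Static graph measures (degree,
shortest paths) do not rank hippocampal subfields among the hubs of the
primate connectome, yet anatomy suggests field CA1 is a convergence
zone where distributed information streams are integrated. Modelling
communication as traffic rather than as static connectivity resolves
the tension: parahippocampal relays with many afferents but one or two
efferents funnel random-walk traffic downstream, and the funnel's
target receives far more signal than its in-degree alone would predict.
This package implements that traffic model, the surrogate-network
statistics around it, and a synthetic ground-truth pipeline that
validates the whole inference chain on networks with a planted funnel.

## The model

A directed binary network of `N` nodes is treated as a queueing system:

* **Generation.** Signal units appear as a network-wide Poisson process
  of rate λ; each unit gets a uniformly random source and a uniformly
  random destination ≠ source.
* **Routing.** A unit at node `i` is served for an `Exponential(μ)`
  time, then moves along one efferent edge chosen with probability
  `1/k_out(i)` — an unbiased random walk over projections. Arrival at
  the destination removes the unit.
* **Queueing.** Each node is a single server with a `K`-slot buffer,
  last-in-first-out: a unit arriving at a busy node joins the buffer
  front; if the buffer is full, the *oldest* queued unit is ejected
  from the network (biological signals decay; the unit in service is
  never pre-empted).

Per node, three communication metrics are computed on the
post-transient window: **arrivals** (count of incoming units), **node
contents** (time-average of `n_i(t) = s_i(t) + q_i(t)`, server plus
queue) and **utilization** (fraction of time the server is busy).

Inference compares the empirical network against two surrogate
families: **degree-preserving rewiring** (Maslov–Sneppen edge swaps;
keeps every `(k_in, k_out)`, destroys higher-order topology) and
**fractional direction reversal** (flips a random subset of
unidirectional projections; tests the causal role of directionality).
A focal node's ensemble-mean metric is expressed as a z-score against
the surrogate distribution.

## Worked example

The numbered drivers under `analysis/` run the full story on synthetic
data. `analysis/03_funnel_recovery.py` builds a 100-node network with
two planted relays (34 and 41 afferents; out-degrees 1 and 2, both
projecting to a target node) and runs the inference stack in the steady
regime (λ = 0.05, μ = 1, K = 10, T = 20 000, R = S = 20):

```text
$ python analysis/03_funnel_recovery.py
funnel network: 100 nodes, 699 edges
  relay1: (k_in, k_out) = (34, 1)
  relay2: (k_in, k_out) = (41, 2)
  target: (k_in, k_out) = (14, 8)

excess vs degree-preserving rewired surrogates:
  arrivals: z = +6.00 (p = 2.01e-09)
  contents: z = +9.33 (p = 1.01e-20)
  utilization: z = +6.09 (p = 1.15e-09)
excess on the fully direction-reversed network:
  arrivals: z = +1.35
  contents: z = +1.33
  utilization: z = +1.41

target arrival rank: 1 of 100
target studentized residual vs in-degree trend: +8.44 (flagged: True)
  relay1 residual: -0.13
  relay2 residual: -2.60

top 5 most-traversed edges (summed over the ensemble):
  relay1 -> target: 141899
  relay2 -> n040: 66012
  relay2 -> target: 65916
  target -> n086: 30777
  target -> n058: 30750
```

Reading: the target attracts a traffic excess of about six null
standard deviations relative to networks with identical degrees, is
the top-ranked node for arrivals, and is the only node flagged above
the in-degree trend. Reversing every unidirectional projection
abolishes the excess (|z| < 2): the convergence zone is a product of
topology *and* directionality, exactly the mechanism the planted
funnel encodes. The relay efferents are the most-traversed edges by a
wide margin — the sole efferent of relay 1 carries the most traffic,
and relay 2's throughput splits evenly over its two efferents, which
rank second and third in either order.

`analysis/02_phase_map.py` locates the steady/jammed transition that
bounds the usable operating regime, and `analysis/01_walkthrough_replay.py`
replays a hand-checkable scripted timeline of the queueing mechanics.

A `neuroqueue` console command exposes the same stages
(`simulate`, `nulls`, `synth`, `phase`, `analyze`, `run`); see
`neuroqueue --help`.

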