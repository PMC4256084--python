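# Methods

## Model

Communication on a directed binary network is modelled as a
discrete-event queueing system. Signal units — discrete tokens standing
for volleys of activity that propagate over anatomical projections —
are generated network-wide as a Poisson process of rate λ. Each unit
draws a uniformly random source and a uniformly random destination
distinct from the source, and performs an unbiased random walk: at node
`i` it is held for an `Exponential(μ)` service time, then forwarded
along one of the `k_out(i)` efferent edges with equal probability.
Arrival at the destination removes the unit immediately; it never
occupies the destination's server or buffer.

Each node is a single non-preemptive server with a finite buffer of
`K` slots (the server slot is additional, so a node holds at most
`K + 1` units). The discipline is last-in-first-out: an arriving unit
that finds the server busy joins the front of the buffer; when the
buffer is full, the unit at the back — the oldest queued unit — is
ejected from the network and counted, and the newcomer still joins the
front. Eject-the-oldest mimics the time-dependent decay of biological
signals; finite buffers give the network a finite, lossy capacity.

The alternative reading of the overflow rule (reject the *arriving*
unit) was considered and discarded: it contradicts the LIFO rationale
that old signals are the ones that expire, and it makes the displayed
walkthrough timeline (newcomer enters, oldest leaves) impossible.

Every run is driven by one seeded Mersenne Twister; exponential
variates use the inverse transform `-ln(u)/rate`. The event queue
orders by (time, insertion sequence), so simultaneous events resolve
first-scheduled-first; with continuous random times, ties have
probability zero.

Units are conserved exactly: `generated = delivered + ejected +
residual` holds as an integer identity on every run, and the engine's
per-node occupancy satisfies `n_i(t) = s_i(t) + q_i(t)` (server
indicator plus queue length) at every event time. Both identities are
asserted across thousands of randomized runs in the test suite.

## Communication metrics

Per node, on the post-transient window `[t0, T]`:

* **arrivals** — count of units arriving at the node, comprising
  exogenous generations, hops from afferent projections, and (by
  default) absorptions at the node when it is the destination. A
  configuration flag excludes absorptions for sensitivity analysis; on
  sparse networks the two conventions are nearly proportional and none
  of the reported statistics changes qualitatively.
* **node contents** — time-average of `n_i(t)`, computed from the exact
  event-time integral of the step trajectory, never from a resampled
  series.
* **utilization** — busy time over window length; equal to the
  integral of the server indicator to ≤1e-9 by construction (both are
  exposed and compared in tests).

Uniform resampling of trajectories exists for export and plotting.
Zero-order hold is the default because a queue-length trajectory is a
step function; linear "table-lookup" interpolation is selectable for
parity with historical practice, and the choice is recorded wherever a
resampled series is written.

The default transient cut is 2% of the run (40 000 time units at the
full-scale T = 2 000 000). An ensemble-average estimator (point-wise
mean of replicate total-contents series; earliest time after which the
mean stays within a tolerance band of its terminal level) is provided
to check that choice rather than to replace it; its tolerance rule is
a parameter, not a claim about how the cut "should" be chosen.

## Null models

* **Degree-preserving rewiring** (Maslov–Sneppen switching): repeatedly
  draw two directed edges `a→b`, `c→d` and swap to `a→d`, `c→b` unless
  the swap would create a self-loop or a duplicate edge. Rejected draws
  count toward the attempt budget (default 10·|E| attempts). Every
  node's `(k_in, k_out)` is preserved exactly. Implemented directly
  (≈25 lines) because the attempt/rejection accounting is part of the
  contract; networkx supplies graph I/O and connectivity diagnostics
  but not these semantics.
* **Fractional direction reversal**: exactly `round(f·U)` (half-up) of
  the `U` unidirectional edges, sampled without replacement, are
  replaced by their opposites. Reciprocal pairs are untouched. Full
  reversal equals transposing the unidirectional part and is an
  involution; both properties are tested exactly.

Surrogates must leave every node with out-degree ≥ 1 (the simulator's
precondition); violating draws are regenerated with a shifted seed, up
to a bounded retry count recorded in the ensemble manifest.
Connectivity beyond that is not enforced.

## Inference

The ensemble design follows the standard surrogate logic: R
simulations on the network under study versus one simulation on each
of S surrogate networks, and
`z = (mean(empirical) − mean(null)) / sd(null)` with a two-sided
normal-approximation p (an empirical-percentile p is also reported,
since null distributions can be skewed). Defaults are R = S = 20 at
desk scale; the full-scale design (R = S = 100, repeated over network
realizations) is a parameter change.

The **convergence excess** of a node packages this with the
degree-preserving null of the *evaluated* network: a large positive
excess means topology funnels traffic to the node beyond what its
degree sequence explains. The directionality test applies the same
statistic to the fully direction-reversed network. A direct comparison
of the empirical mean against the reversed-network distribution is
possible but degenerate at fraction 1.0 (full reversal is
deterministic, so its "ensemble" varies only by simulation noise and
any real difference produces arbitrarily large z); the excess-based
formulation asks the scientifically meaningful question — does the
funnel survive reversal? — and has a well-behaved null.

**Degree outliers**: ordinary least squares of a metric on in-degree
across nodes, with internally studentized residuals; |residual| > 3
flags a node (threshold configurable). A perfect fit short-circuits to
zero residuals rather than 0/0.

**Rankings** are descending with average ranks on ties and canonical
label order as the final tie-break, computed on ensemble-mean metrics.

## Steady vs jammed regimes

Behaviour is governed by the ratio of exogenous arrival rate to
service rate. The sweep classifies a rate as **jammed** when
stationarity is lost: either mean total contents exceed 90% of the
absolute bound `N(K+1)` (all buffers essentially full — the terminal
state of a jam), or total contents still climb through the window,
where "climb" requires a positive trend that is simultaneously larger
than 20% of the mean level and significant at 3 standard errors under
an AR(1) noise model (total-contents series are strongly
autocorrelated; a naive OLS slope criterion misclassifies stationary
runs). In this lossy model moderate overload produces a *stationary
congested* state — hot nodes saturate and eject while cold nodes stay
empty — so the global jam requires exogenous input comparable to
per-node service capacity (λ of order N·μ); the sweep in
`analysis/02_phase_map.py` brackets the transition accordingly.

## Parameters and operating point

| parameter | meaning | default | rationale |
| --- | --- | --- | --- |
| μ | service rate | 1.0 | sets the time unit (one mean service) |
| K | buffer slots per node | 10 | loss is a perturbation, not the norm, in the steady regime |
| λ | network-wide generation rate | 0.05 | see below |
| T | duration | 20 000 (synthetic); 200 000 (macaque, scaled); 2 000 000 (full scale) | see below |
| transient | excluded prefix | 2% of T | 40 000 at full scale |
| R, S | ensemble sizes | 20 | desk scale; 100 at full scale |

The operating point λ = 0.05 was chosen from the phase sweep before
the inference experiments were fixed: it sits well inside the steady
regime (total contents ~1% of capacity; under 1% of units ejected on
the synthetic networks; the funnel target, the hottest node, runs at
utilization ≈ 0.65). Larger rates remain steady but push hot nodes
into saturation, where arrival counts censor and the excess statistic
degrades. Problem sizes (T = 20 000, R = S = 20 for the synthetic
experiment; T = 200 000 with 20 runs for the macaque analysis) are the
package's desk-scale defaults; every reported experiment states its
sizes in its manifest and all scale linearly.

## Synthetic ground truth

The planted-funnel generator emulates the statistical structure that
drives the empirical finding: a sparse directed Erdős–Rényi background
(N = 100, p = 0.06, mean degree 6 — the same order as the macaque
network's density) plus two relay nodes with 34 and 41 afferents and
out-degrees 1 and 2, all relay efferents forced unidirectional and
including the target (the second relay keeps one extra efferent,
mirroring the anatomical archetype of a parahippocampal relay that
projects to one other area besides CA1). The construction retries
deterministically until both the network and its full reversal are
simulable (every node keeps an efferent).

What the generator does *not* emulate: the empirical network's broad
degree distribution, reciprocity structure, and community organization
(a configuration-model background option exists for harder tests).
Recovery on the funnel therefore validates the inference chain — that
the statistics detect a degree-imbalance funnel when one exists and
stay silent after reversal — not that any particular empirical network
contains one.

Because the second relay splits its throughput evenly over its two
efferents, the expected edge ranking is: relay1→target first, then the
second relay's two efferents statistically tied. The ground-truth
check is therefore "the planted relay efferents are exactly the
top-traversed edges, with relay1→target first", not a specific
ordering of the tied pair (in the empirical network the corresponding
asymmetry is a fact of the data, not of the construction).

## Numerical choices and degenerate inputs

* Window boundaries are closed on the left (`t ≥ t0`), so a zero
  transient is the exact identity; for stochastic runs the boundary
  has measure zero.
* Uniform variates are mapped through `1 − u` before the inverse
  transform so the argument lies in (0, 1] and a zero service time is
  possible but a log-of-zero is not.
* Networks with a node of out-degree 0 are rejected at stochastic
  simulation time (a walk can reach any node); scripted replays only
  need exits where a departure is scripted, which lets the walkthrough
  chain end in a sink.
* Self-loops are rejected at load (the routing rule and the contents
  identity never reference them); an explicit override drops them with
  a warning.
* Any adjacency entry other than 0/1 is an error, never a weight.
* Rewiring a network with no legal swap returns the input with a
  warning; full reversal of a network whose reversal strands a node
  raises (the operation is deterministic, so retrying cannot help).

## Known limitations

* Pure Python event loop: ~10⁶ events per second-scale run; full-scale
  runs (T = 2×10⁶ on 242 nodes) are hours, not minutes. All analyses
  here use the scaled sizes above.
* The normal-approximation p-values inherit the usual caveats for
  skewed nulls; the empirical-percentile p is reported alongside.
* Identical capacity at every node and edge is a modelling assumption
  (areas differ in size, tracts in density); it keeps the model
  comparable to unweighted graph analysis.
* The reversal null at fractions strictly between 0 and 1 is sampled,
  not exhaustive; at fraction 1.0 it is a single deterministic network
  (see Inference).
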