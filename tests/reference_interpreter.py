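"""A deliberately plain, straight-line interpreter of scripted runs.

Independent oracle for the event engine: no event heap, no shared code —
just a loop that repeatedly finds the chronologically next thing to
happen (an exogenous generation or the earliest pending service
completion) and applies the queueing rules directly.  Ties are broken
in favour of generations, then by service start order; oracle scripts
use distinct continuous times so ties never arise in practice.
"""

from dataclasses import dataclass, field


@dataclass
class NodeBox:
    serving: tuple | None = None  # (uid, dest)
    completion_time: float = 0.0
    start_order: int = 0
    buffer: list = field(default_factory=list)  # index 0 = oldest


def interpret(labels, edges, K, T, generations, service_times, routing):
    """Replay a script and return ledger + per-node tallies on [0, T]."""
    succ = {v: [] for v in labels}
    edge_set = set()
    for s, t in edges:
        succ[s].append(t)
        edge_set.add((s, t))

    boxes = {v: NodeBox() for v in labels}
    svc_left = {v: list(service_times.get(v, [])) for v in labels}
    route_left = {v: list(routing.get(v, [])) for v in labels}

    gens = sorted(generations)
    gen_ptr = 0
    uid_counter = 0
    order_counter = 0

    generated = delivered = ejected = 0
    arrivals = {v: 0 for v in labels}
    edge_hits = {}
    busy_acc = {v: 0.0 for v in labels}
    contents_acc = {v: 0.0 for v in labels}
    last_seen = {v: 0.0 for v in labels}

    def occupancy(v):
        return (0 if boxes[v].serving is None else 1) + len(boxes[v].buffer)

    def advance_clock(v, now):
        span = now - last_seen[v]
        contents_acc[v] += occupancy(v) * span
        if boxes[v].serving is not None:
            busy_acc[v] += span
        last_seen[v] = now

    def begin_service(v, unit, now):
        nonlocal order_counter
        boxes[v].serving = unit
        boxes[v].completion_time = now + svc_left[v].pop(0)
        boxes[v].start_order = order_counter
        order_counter += 1

    def deposit(v, unit, now):
        nonlocal delivered, ejected
        uid, dest = unit
        arrivals[v] += 1
        if dest == v:
            delivered += 1
            return
        advance_clock(v, now)
        if boxes[v].serving is None:
            begin_service(v, unit, now)
        else:
            if len(boxes[v].buffer) == K:
                boxes[v].buffer.pop(0)
                ejected += 1
            boxes[v].buffer.append(unit)

    while True:
        next_gen = gens[gen_ptr][0] if gen_ptr < len(gens) else None
        pending = [
            (boxes[v].completion_time, boxes[v].start_order, v)
            for v in labels
            if boxes[v].serving is not None
        ]
        next_done = min(pending) if pending else None

        if next_gen is None and next_done is None:
            break
        take_gen = next_done is None or (next_gen is not None and next_gen <= next_done[0])
        when = next_gen if take_gen else next_done[0]
        if when > T:
            break

        if take_gen:
            _, src, dest = gens[gen_ptr]
            gen_ptr += 1
            generated += 1
            unit = (uid_counter, dest)
            uid_counter += 1
            deposit(src, unit, when)
        else:
            v = next_done[2]
            advance_clock(v, when)
            unit = boxes[v].serving
            boxes[v].serving = None
            if boxes[v].buffer:
                begin_service(v, boxes[v].buffer.pop(), when)
            target = route_left[v].pop(0)
            assert (v, target) in edge_set
            edge_hits[(v, target)] = edge_hits.get((v, target), 0) + 1
            deposit(target, unit, when)

    residual = sum(occupancy(v) for v in labels)
    for v in labels:
        advance_clock(v, T)
    return {
        "generated": generated,
        "delivered": delivered,
        "ejected": ejected,
        "residual": residual,
        "arrivals": arrivals,
        "edge_hits": edge_hits,
        "busy_time": busy_acc,
        "contents_integral": contents_acc,
    }
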