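"""Event-driven CAP propagation and collision resolution.

Computation in this model happens where CAP streams converge.  The first
threshold through a convergence point opens a refractory window of its own
duration L; within that window a later threshold is *annulled* (it meets
refractory membrane and dies), unless it lands within the fusion tolerance
of the surviving threshold, in which case the two *fuse* and continue as a
single CAP timed at the earlier threshold.  A threshold arriving at or after
the window's end *passes* and opens a new window.  The window is half-open,
``[t_last, t_last + L)``: refractory membrane has no effect once it ends.

Two independent implementations are provided:

* :func:`simulate` — an event-driven engine on a priority queue of arrival
  events (no global clock: timing is set entirely by conduction latencies,
  mirroring a nervous system that has no central clock).
* :func:`oracle_simulate` — a brute-force discrete-time membrane simulation
  used as a testing oracle.  Each neurite is conceptually a 1-D lattice of
  membrane points with spacing ``velocity * dt``; a point fires when its
  upstream neighbour fired ``dt`` earlier and the point is outside its own
  refractory window.  Interior lattice points have a single upstream
  neighbour and only ever relay trains already separated by >= L, so their
  refractory gate never closes on an arriving threshold; they reduce exactly
  to an integer-step delay of ``round(latency/dt)`` steps.  The loop
  therefore steps time and gates at the shared node points only.
"""

from __future__ import annotations

import heapq
import itertools
import logging
from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core import (
    CAP,
    NetworkModel,
    PulseTrain,
    latency,
    validate_network,
)
from .exceptions import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

#: Guard for float roundoff when comparing an arrival against the end of a
#: refractory window: an arrival within 1e-12 s of t_last + L is treated as
#: at-or-after the window end (it passes).
BOUNDARY_EPS = 1e-12

#: Default fusion tolerance in seconds.  Thresholds are described as
#: "overlapping" when in phase; the activation mechanism is resolved on a
#: 1-10 microsecond scale, so 10 us is the default window within which two
#: thresholds are indistinguishable and fuse.
DEFAULT_FUSION_TOLERANCE_S = 1e-5

OUTCOMES = ("fused", "annulled", "passed")


@dataclass
class CollisionRecord:
    """Outcome of one convergence event.

    ``fused``: >= 2 participants, one survivor (the earliest threshold).
    ``annulled``: one participant (the late threshold); ``blocking`` names
    the CAP whose refractory window killed it.
    ``passed``: one participant which is its own survivor.
    """

    time: float
    node: str
    outcome: str
    participants: tuple
    survivor: str | None
    blocking: str | None = None


@dataclass
class SimulationResult:
    """Output of a network simulation.

    ``output_trains`` maps each sink node id to its recorded train;
    ``collisions`` is the time-ordered record log over all gated nodes;
    ``transit_intervals`` maps each neurite id to ``(t_enter, t_exit)`` pairs,
    one per CAP that entered the neurite (CAPs still in transit at ``t_end``
    appear here even though they are dropped from the outputs).
    """

    output_trains: dict
    collisions: list
    transit_intervals: dict
    t_end: float
    fusion_tolerance: float
    _enters: dict = field(default_factory=dict, repr=False)
    _exits: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for eid, pairs in self.transit_intervals.items():
            self._enters[eid] = sorted(p[0] for p in pairs)
            self._exits[eid] = sorted(p[1] for p in pairs)

    def transit_log(self, neurite_id: str) -> list:
        """Per-neurite series of (time, in-transit CAP count) change points."""
        if neurite_id not in self.transit_intervals:
            raise ValidationError(f"unknown neurite {neurite_id!r}")
        deltas: dict[float, int] = defaultdict(int)
        for t_in, t_out in self.transit_intervals[neurite_id]:
            deltas[t_in] += 1
            deltas[t_out] -= 1
        series, count = [], 0
        for t in sorted(deltas):
            count += deltas[t]
            series.append((t, count))
        return series

    def outcome_counts(self) -> dict:
        counts = {k: 0 for k in OUTCOMES}
        for rec in self.collisions:
            counts[rec.outcome] += 1
        return counts


def in_transit_count(result: SimulationResult, neurite_id: str, time: float) -> int:
    """Number of CAPs that have entered but not exited ``neurite_id`` at ``time``.

    A CAP with transit interval ``[t_in, t_out)`` is counted when
    ``t_in <= time < t_out``.
    """
    if neurite_id not in result.transit_intervals:
        raise ValidationError(f"unknown neurite {neurite_id!r}")
    if not (0.0 <= time <= result.t_end):
        raise ValidationError(
            f"time {time!r} outside simulated horizon [0, {result.t_end}]"
        )
    return bisect_right(result._enters[neurite_id], time) - bisect_right(
        result._exits[neurite_id], time
    )


class _RefractoryGate:
    """Online sweep state for one convergence point.

    Admits arrivals in time order and classifies each as passed / fused /
    annulled against the half-open window [t_last, t_last + L) anchored at
    the last surviving threshold.  A window-opening arrival is recorded as
    ``passed``; if later arrivals fuse into it the same record is upgraded
    in place to ``fused`` (one record per window-opening collision).
    """

    def __init__(self, node_id: str, fusion_tolerance: float) -> None:
        self.node_id = node_id
        self.tol = fusion_tolerance
        self.t_last: float | None = None
        self.last_L = 0.0
        self.last_cap: CAP | None = None
        self.last_record: CollisionRecord | None = None

    def admit(self, cap: CAP, t: float, records: list) -> str:
        if self.t_last is not None and t < self.t_last:
            raise ValidationError(
                f"gate at {self.node_id!r}: arrivals out of time order"
            )
        if (
            self.t_last is None
            or t >= self.t_last + self.last_L - BOUNDARY_EPS
        ):
            rec = CollisionRecord(
                time=t,
                node=self.node_id,
                outcome="passed",
                participants=(cap.id,),
                survivor=cap.id,
            )
            records.append(rec)
            self.t_last = t
            self.last_L = cap.refractory_duration
            self.last_cap = cap
            self.last_record = rec
            return "passed"
        if t - self.t_last <= self.tol:
            rec = self.last_record
            rec.outcome = "fused"
            rec.participants = rec.participants + (cap.id,)
            self.last_cap.lineage.append(cap.id)
            return "fused"
        records.append(
            CollisionRecord(
                time=t,
                node=self.node_id,
                outcome="annulled",
                participants=(cap.id,),
                survivor=None,
                blocking=self.last_cap.id,
            )
        )
        return "annulled"


def resolve_convergence(
    arrival_times: Sequence[tuple],
    refractory_duration: float,
    fusion_tolerance: float,
) -> tuple:
    """Resolve one convergence point's merged arrival stream.

    Parameters
    ----------
    arrival_times : sequence of (CAP, seconds)
        Arrivals sorted by time.
    refractory_duration : float
        Window L (s) opened by each surviving threshold whose CAP does not
        carry its own refractory duration; CAP-level durations win.
    fusion_tolerance : float
        Arrivals within this of the surviving threshold fuse with it.
        Must satisfy ``0 <= fusion_tolerance < refractory_duration``.

    Returns
    -------
    (survivors, records)
        ``survivors`` is the list of (CAP, time) that continue past the
        point; ``records`` the complete :class:`CollisionRecord` log.
    """
    if not (0 <= fusion_tolerance < refractory_duration):
        raise ConfigurationError(
            f"fusion_tolerance ({fusion_tolerance!r}) must be in "
            f"[0, refractory_duration={refractory_duration!r})"
        )
    times = [t for _, t in arrival_times]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValidationError("arrival_times must be sorted by time")

    gate = _RefractoryGate("convergence", fusion_tolerance)
    records: list[CollisionRecord] = []
    survivors: list[tuple] = []
    for cap, t in arrival_times:
        if cap.refractory_duration != refractory_duration:
            cap = CAP(cap.id, cap.threshold_time, refractory_duration, cap.lineage)
        if gate.admit(cap, t, records) == "passed":
            survivors.append((cap, t))
    return survivors, records


def simulate(
    model: NetworkModel,
    inputs: Mapping[str, PulseTrain],
    t_end: float,
    fusion_tolerance: float = DEFAULT_FUSION_TOLERANCE_S,
) -> SimulationResult:
    """Event-driven simulation of CAP propagation through the network.

    Every input threshold is advanced edge-by-edge with delay
    ``latency(neurite)``; at every node with incoming neurites the merged
    arrival stream is swept through a refractory gate (fuse / annul / pass);
    surviving CAPs are copied onto *all* outgoing neurites of the node
    (fan-out duplicates the quantum).  Thresholds still in transit at
    ``t_end`` are dropped from the outputs but appear in the transit log.

    Events are processed in ``(time, node id, neurite id)`` lexicographic
    order, which makes simultaneous arrivals deterministic.
    """
    violations = validate_network(model)
    if violations:
        raise ValidationError("invalid network: " + "; ".join(violations))
    if not (t_end > 0):
        raise ValidationError(f"t_end must be positive, got {t_end!r}")
    min_L = model.min_refractory()
    if not (0 <= fusion_tolerance < min_L):
        raise ConfigurationError(
            f"fusion_tolerance ({fusion_tolerance!r}) must be in [0, L={min_L!r})"
        )
    source_ids = {n.id for n in model.sources}
    for loc, train in inputs.items():
        if loc not in source_ids:
            raise ValidationError(f"input train at non-source location {loc!r}")
        train.validate_refractory(model.refractory_duration)

    heap: list = []
    seq = itertools.count()
    transit: dict[str, list] = {e.id: [] for e in model.neurites}
    outputs: dict[str, list] = {n.id: [] for n in model.sinks}
    records: list[CollisionRecord] = []
    gates: dict[str, _RefractoryGate] = {}

    def forward(cap: CAP, node_id: str, t: float) -> None:
        for e in model.outgoing(node_id):
            arr = t + latency(e)
            child = CAP(
                id=f"{cap.id}/{e.id}",
                threshold_time=arr,
                refractory_duration=model.refractory_for(e),
                lineage=cap.lineage + [cap.id],
            )
            transit[e.id].append((t, arr))
            if arr <= t_end:
                heapq.heappush(heap, (arr, e.to_node, e.id, next(seq), child))

    for src in sorted(source_ids):
        train = inputs.get(src)
        if train is None:
            continue
        for k, t in enumerate(train.times):
            if t > t_end:
                break
            forward(CAP(f"{src}#{k}", t, model.refractory_duration), src, t)

    while heap:
        t, node_id, _eid, _s, cap = heapq.heappop(heap)
        gate = gates.get(node_id)
        if gate is None:
            gate = gates[node_id] = _RefractoryGate(node_id, fusion_tolerance)
        if gate.admit(cap, t, records) == "passed":
            if node_id in outputs:
                outputs[node_id].append(t)
            forward(cap, node_id, t)

    result = SimulationResult(
        output_trains={
            nid: PulseTrain(nid, times) for nid, times in outputs.items()
        },
        collisions=records,
        transit_intervals=transit,
        t_end=t_end,
        fusion_tolerance=fusion_tolerance,
    )
    counts = result.outcome_counts()
    logger.info(
        "simulate: %d fused, %d annulled, %d passed",
        counts["fused"],
        counts["annulled"],
        counts["passed"],
    )
    return result


def oracle_simulate(
    model: NetworkModel,
    inputs: Mapping[str, PulseTrain],
    t_end: float,
    dt: float = 1e-6,
    fusion_tolerance: float = DEFAULT_FUSION_TOLERANCE_S,
) -> SimulationResult:
    """Brute-force discrete-time membrane simulation (testing oracle).

    Time advances in steps of ``dt``; each neurite is an integer number of
    lattice steps ``round(latency/dt)`` long, and each node is a shared
    membrane point that fires at a step only if it is outside its own
    refractory window.  Multiple deliveries to a point at the same step
    produce a single firing (in-phase thresholds fuse by construction).

    Output trains must match the event-driven :func:`simulate` within one
    ``dt`` per threshold.  Requires ``dt <= fusion_tolerance / 10``.
    """
    violations = validate_network(model)
    if violations:
        raise ValidationError("invalid network: " + "; ".join(violations))
    if not (dt > 0) or dt > fusion_tolerance / 10:
        raise ConfigurationError(
            f"dt ({dt!r}) must be positive and <= fusion_tolerance/10 "
            f"({fusion_tolerance / 10!r})"
        )
    edge_steps: dict[str, int] = {}
    edge_L_steps: dict[str, int] = {}
    for e in model.neurites:
        k = round(latency(e) / dt)
        if k < 1:
            raise ConfigurationError(
                f"neurite {e.id!r}: latency {latency(e):g} s shorter than dt"
            )
        edge_steps[e.id] = k
        edge_L_steps[e.id] = round(model.refractory_for(e) / dt)

    n_steps = int(round(t_end / dt))
    pending: dict[int, list] = defaultdict(list)  # step -> [(node, edge)]
    transit: dict[str, list] = {e.id: [] for e in model.neurites}
    outputs: dict[str, list] = {n.id: [] for n in model.sinks}
    sink_ids = set(outputs)

    def forward(node_id: str, step: int) -> None:
        for e in model.outgoing(node_id):
            arrive = step + edge_steps[e.id]
            transit[e.id].append((step * dt, arrive * dt))
            if arrive <= n_steps:
                pending[arrive].append((e.to_node, e.id))

    for src in sorted(n.id for n in model.sources):
        train = inputs.get(src)
        if train is None:
            continue
        train.validate_refractory(model.refractory_duration)
        for t in train.times:
            s0 = round(t / dt)
            if s0 <= n_steps:
                forward(src, s0)

    # time-stepped sweep over membrane points
    last_fire: dict[str, int] = {}
    window_L: dict[str, int] = {}
    for step in range(n_steps + 1):
        deliveries = pending.pop(step, None)
        if not deliveries:
            continue
        by_node: dict[str, list] = defaultdict(list)
        for node_id, eid in deliveries:
            by_node[node_id].append(eid)
        for node_id in sorted(by_node):
            prev = last_fire.get(node_id)
            if prev is not None and step < prev + window_L[node_id]:
                continue  # refractory membrane: threshold annulled
            eid = min(by_node[node_id])  # deterministic tie-break
            last_fire[node_id] = step
            window_L[node_id] = edge_L_steps[eid]
            if node_id in sink_ids:
                outputs[node_id].append(step * dt)
            forward(node_id, step)

    return SimulationResult(
        output_trains={
            nid: PulseTrain(nid, times) for nid, times in outputs.items()
        },
        collisions=[],
        transit_intervals=transit,
        t_end=t_end,
        fusion_tolerance=fusion_tolerance,
    )


# ---------------------------------------------------------------------------
# invariant checks (used throughout the test suite)
# ---------------------------------------------------------------------------

def check_refractory_exclusion(result: SimulationResult, model: NetworkModel) -> None:
    """Every output train's consecutive thresholds differ by >= L - 1e-12 s."""
    for train in result.output_trains.values():
        train.validate_refractory(model.refractory_duration, tol=BOUNDARY_EPS)


def conservation_report(result: SimulationResult, model: NetworkModel) -> dict:
    """Per-node threshold bookkeeping: arrivals vs recorded outcomes.

    For every gated node, the number of CAPs delivered by its incoming
    neurites (transit intervals that end within the horizon) must equal the
    total number of participants across its collision records:
    |passed| + |annulled| + |fused participants|.
    """
    delivered: dict[str, int] = defaultdict(int)
    for e in model.neurites:
        delivered[e.to_node] += sum(
            1 for _t_in, t_out in result.transit_intervals[e.id]
            if t_out <= result.t_end
        )
    recorded: dict[str, int] = defaultdict(int)
    for rec in result.collisions:
        recorded[rec.node] += len(rec.participants)
    return {
        node: {"delivered": delivered[node], "recorded": recorded[node]}
        for node in set(delivered) | set(recorded)
    }


def check_conservation(result: SimulationResult, model: NetworkModel) -> None:
    """Raise AssertionError if any node's threshold bookkeeping is unbalanced."""
    for node, counts in conservation_report(result, model).items():
        if counts["delivered"] != counts["recorded"]:
            raise AssertionError(
                f"node {node!r}: {counts['delivered']} arrivals but "
                f"{counts['recorded']} recorded participants"
            )
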