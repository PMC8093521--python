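"""Domain types for phase-ternary network simulation.

A *CAP* (computational action potential) abstracts a nerve impulse to the two
features that matter for collision computation: the instant its activation
threshold passes a reference point, and the absolute refractory window of
duration ``L`` that trails it.  CAPs travel along *neurites* (edges with a
physical length and a conduction velocity) between *nodes* of a directed
network; nodes are sources (emit trains), convergences (where CAP streams
collide), or sinks (where output trains are recorded).

Units are SI throughout: seconds, metres, hertz.  Field names carry their
unit in the docstring; no unit-carrying types are used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .exceptions import ValidationError

#: Default absolute refractory period L in seconds.  At the commonly cited
#: 100 Hz ceiling for bipolar-cell discharge this is the period of the
#: maximum-frequency train (1/100 Hz = 1 ms).
DEFAULT_REFRACTORY_S = 1e-3

NODE_KINDS = ("source", "convergence", "sink")


@dataclass
class CAP:
    """One ternary phase quantum.

    Parameters
    ----------
    id : str
        Opaque identifier.
    threshold_time : float
        Time (s) the activation threshold passes the reference point.
    refractory_duration : float
        Absolute refractory window L (s) trailing the threshold.
    lineage : list of str
        Ancestor CAP ids, for fusion/fan-out bookkeeping.
    """

    id: str
    threshold_time: float
    refractory_duration: float = DEFAULT_REFRACTORY_S
    lineage: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not math.isfinite(self.threshold_time) or self.threshold_time < 0:
            raise ValidationError(
                f"CAP {self.id!r}: threshold_time must be finite and >= 0, "
                f"got {self.threshold_time!r}"
            )
        if not (self.refractory_duration > 0) or not math.isfinite(
            self.refractory_duration
        ):
            raise ValidationError(
                f"CAP {self.id!r}: refractory_duration must be positive, "
                f"got {self.refractory_duration!r}"
            )


@dataclass(frozen=True)
class Neurite:
    """A directed edge: unmyelinated fibre of given length and velocity.

    ``length`` in metres, ``velocity`` in metres/second.  ``refractory_duration``
    (seconds) optionally overrides the network-wide L for CAPs travelling on
    this neurite.
    """

    id: str
    from_node: str
    to_node: str
    length: float
    velocity: float
    refractory_duration: float | None = None

    def __post_init__(self) -> None:
        if not (self.length > 0) or not math.isfinite(self.length):
            raise ValidationError(
                f"neurite {self.id!r}: length must be positive, got {self.length!r}"
            )
        if not (self.velocity > 0) or not math.isfinite(self.velocity):
            raise ValidationError(
                f"neurite {self.id!r}: velocity must be positive, got {self.velocity!r}"
            )
        if self.refractory_duration is not None and not (
            self.refractory_duration > 0
        ):
            raise ValidationError(
                f"neurite {self.id!r}: refractory override must be positive"
            )


@dataclass
class NetworkNode:
    """A network node.  ``kind`` is one of ``source``, ``convergence``, ``sink``.

    ``incoming``/``outgoing`` neurite-id tuples are filled in by
    :class:`NetworkModel` from the edge list.
    """

    id: str
    kind: str
    incoming: tuple = ()
    outgoing: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise ValidationError(
                f"node {self.id!r}: kind must be one of {NODE_KINDS}, got {self.kind!r}"
            )


class NetworkModel:
    """Directed network of nodes and neurites with a network-wide refractory L.

    Construction tolerates structurally inconsistent data (duplicate ids,
    dangling endpoints); :func:`validate_network` reports such violations as
    data rather than exceptions, so a malformed description can be diagnosed
    in full.
    """

    def __init__(
        self,
        nodes: Iterable[NetworkNode],
        neurites: Iterable[Neurite],
        refractory_duration: float = DEFAULT_REFRACTORY_S,
    ) -> None:
        if not (refractory_duration > 0):
            raise ValidationError("refractory_duration must be positive")
        self.nodes: list[NetworkNode] = list(nodes)
        self.neurites: list[Neurite] = list(neurites)
        self.refractory_duration = float(refractory_duration)

        self._node_by_id: dict[str, NetworkNode] = {}
        self._dup_nodes: list[str] = []
        for n in self.nodes:
            if n.id in self._node_by_id:
                self._dup_nodes.append(n.id)
            else:
                self._node_by_id[n.id] = n

        self._edge_by_id: dict[str, Neurite] = {}
        self._dup_edges: list[str] = []
        for e in self.neurites:
            if e.id in self._edge_by_id:
                self._dup_edges.append(e.id)
            else:
                self._edge_by_id[e.id] = e

        for n in self._node_by_id.values():
            n.incoming = tuple(
                e.id for e in self.neurites if e.to_node == n.id
            )
            n.outgoing = tuple(
                e.id for e in self.neurites if e.from_node == n.id
            )

    # -- accessors -----------------------------------------------------
    def node(self, node_id: str) -> NetworkNode:
        try:
            return self._node_by_id[node_id]
        except KeyError:
            raise ValidationError(f"unknown node {node_id!r}") from None

    def neurite(self, neurite_id: str) -> Neurite:
        try:
            return self._edge_by_id[neurite_id]
        except KeyError:
            raise ValidationError(f"unknown neurite {neurite_id!r}") from None

    def outgoing(self, node_id: str) -> list[Neurite]:
        return [self._edge_by_id[i] for i in self.node(node_id).outgoing]

    def incoming(self, node_id: str) -> list[Neurite]:
        return [self._edge_by_id[i] for i in self.node(node_id).incoming]

    @property
    def sources(self) -> list[NetworkNode]:
        return [n for n in self.nodes if n.kind == "source"]

    @property
    def sinks(self) -> list[NetworkNode]:
        return [n for n in self.nodes if n.kind == "sink"]

    def refractory_for(self, neurite: Neurite) -> float:
        """Refractory L (s) governing CAPs that arrive via ``neurite``."""
        if neurite.refractory_duration is not None:
            return neurite.refractory_duration
        return self.refractory_duration

    def min_refractory(self) -> float:
        overrides = [
            e.refractory_duration
            for e in self.neurites
            if e.refractory_duration is not None
        ]
        return min([self.refractory_duration] + overrides)

    def to_networkx(self):
        """The network as a :class:`networkx.MultiDiGraph` (edge key = neurite id)."""
        import networkx as nx

        g = nx.MultiDiGraph()
        for n in self.nodes:
            g.add_node(n.id, kind=n.kind)
        for e in self.neurites:
            g.add_edge(e.from_node, e.to_node, key=e.id, neurite=e)
        return g


@dataclass(frozen=True)
class PulseTrain:
    """Strictly increasing activation-threshold times at one network location.

    ``times`` are in seconds.  Strict increase is enforced at construction;
    the stronger membrane constraint (consecutive times at least one
    refractory period apart) depends on L and is checked by
    :meth:`validate_refractory`.
    """

    location: str
    times: tuple

    def __init__(self, location: str, times: Sequence[float]) -> None:
        times = tuple(float(t) for t in times)
        for a, b in zip(times, times[1:]):
            if not (b > a):
                raise ValidationError(
                    f"train at {location!r}: times must be strictly increasing "
                    f"({a!r} followed by {b!r})"
                )
        for t in times:
            if not math.isfinite(t) or t < 0:
                raise ValidationError(
                    f"train at {location!r}: times must be finite and >= 0"
                )
        object.__setattr__(self, "location", location)
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return len(self.times)

    def min_interval(self) -> float:
        """Smallest gap between consecutive thresholds (inf for < 2 thresholds)."""
        if len(self.times) < 2:
            return math.inf
        return min(b - a for a, b in zip(self.times, self.times[1:]))

    def validate_refractory(self, refractory_duration: float, tol: float = 1e-12) -> None:
        """Raise if any consecutive pair is closer than L (within ``tol``)."""
        gap = self.min_interval()
        if gap < refractory_duration - tol:
            raise ValidationError(
                f"train at {self.location!r}: inter-threshold interval {gap:g} s "
                f"violates refractory separation {refractory_duration:g} s"
            )


# ---------------------------------------------------------------------------
# geometry / latency arithmetic
# ---------------------------------------------------------------------------

def latency(neurite: Neurite) -> float:
    """Conduction delay (s) along a neurite: length / velocity."""
    return neurite.length / neurite.velocity


def phase_length(frequency: float, velocity: float) -> float:
    """Distance (m) between two successive activation thresholds.

    A train at ``frequency`` (Hz) conducted at ``velocity`` (m/s) has its
    thresholds ``velocity / frequency`` metres apart.
    """
    if not (frequency > 0) or not math.isfinite(frequency):
        raise ValidationError(f"frequency must be positive, got {frequency!r}")
    if not (velocity > 0) or not math.isfinite(velocity):
        raise ValidationError(f"velocity must be positive, got {velocity!r}")
    return velocity / frequency


def validate_network(model: NetworkModel) -> list[str]:
    """Structural invariant check; returns violation descriptions (empty = valid).

    Checks id uniqueness, that neurite endpoints name existing nodes, and the
    node-kind degree rules: sources have no incoming neurites, sinks no
    outgoing, and convergences at least one of each.  Violations are data,
    not exceptions; the function is idempotent and order-independent.
    """
    violations: list[str] = []
    for nid in sorted(set(model._dup_nodes)):
        violations.append(f"duplicate node id {nid!r}")
    for eid in sorted(set(model._dup_edges)):
        violations.append(f"duplicate neurite id {eid!r}")
    node_ids = set(model._node_by_id)
    for e in model.neurites:
        if e.from_node not in node_ids:
            violations.append(
                f"neurite {e.id!r} references missing from_node {e.from_node!r}"
            )
        if e.to_node not in node_ids:
            violations.append(
                f"neurite {e.id!r} references missing to_node {e.to_node!r}"
            )
    for n in model._node_by_id.values():
        if n.kind == "source" and n.incoming:
            violations.append(
                f"source node {n.id!r} has incoming neurites {list(n.incoming)}"
            )
        if n.kind == "sink" and n.outgoing:
            violations.append(
                f"sink node {n.id!r} has outgoing neurites {list(n.outgoing)}"
            )
        if n.kind == "convergence" and (not n.incoming or not n.outgoing):
            violations.append(
                f"convergence node {n.id!r} must have >= 1 incoming and >= 1 outgoing"
            )
    return violations
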