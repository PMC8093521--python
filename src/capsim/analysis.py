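"""Phase-length (lambda) accounting and frequency-transformation experiments.

The *phase length* at frequency ``f`` on a fibre of velocity ``v`` is
``v / f`` — the physical distance between successive activation thresholds.
An edge of length ``d`` then holds ``lambda = d * f / v`` phase lengths, and
under steady periodic drive exactly that many CAPs are in transit on it at
any instant.  Doubling the input frequency halves the phase length and
doubles the in-transit count; the counts on every route taken together form
a frequency-resolved signature of the inputs.

:func:`demo_network` builds the worked two-input/three-output network whose
printed relations are: lambda(a->c) = 3 at the base frequency, route
lambda(a->e) = 6, and conduction time a->c equal to half that of b->e.  The
remaining geometry (the internal convergence m and the b->d edge) is not
pinned and is a documented fixture choice.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .collisions import (
    DEFAULT_FUSION_TOLERANCE_S,
    SimulationResult,
    in_transit_count,
    simulate,
)
from .core import (
    DEFAULT_REFRACTORY_S,
    NetworkModel,
    NetworkNode,
    Neurite,
    latency,
    phase_length,
)
from .exceptions import ConfigurationError, ValidationError
from .generators import periodic_train

_INT_TOL = 1e-9


@dataclass(frozen=True)
class EdgePhaseSummary:
    """Phase accounting for one neurite: lambda at the driving frequency,
    the measured steady-state in-transit CAP count, and the (from, to)
    route it spans."""

    neurite_id: str
    lam: float
    in_transit: int
    route: tuple


@dataclass(frozen=True)
class RouteSummary:
    """Phase accounting summed along a source->sink simple path."""

    source: str
    sink: str
    route: tuple
    edge_ids: tuple
    lam: float
    in_transit: int


@dataclass
class FrequencyResponse:
    """Result of :func:`frequency_response`."""

    edge_summaries: list
    route_summaries: list
    sink_frequencies: dict
    transient: float
    t_measure: float
    t_end: float
    result: SimulationResult


def edge_lambda(neurite: Neurite, frequency: float) -> float:
    """Number of phase lengths on the edge: length / (velocity / frequency).

    Returned as an exact integer when within 1e-9 of one (the worked
    networks are sized to integral lambda); linear in frequency.
    """
    lam = neurite.length / phase_length(frequency, neurite.velocity)
    nearest = round(lam)
    if abs(lam - nearest) < _INT_TOL:
        return int(nearest)
    return lam


def demo_network(
    base_frequency: float = 1.0,
    velocity: float = 0.3,
    refractory_duration: float = DEFAULT_REFRACTORY_S,
) -> NetworkModel:
    """The worked two-input network: sources a, b; sinks c, d, e.

    Edges are sized in phase lengths at ``base_frequency``:

    * ``a->c`` : 3 (the printed lambda = 3 segment)
    * ``a->m`` : 3 and ``m->e`` : 3, so route a->e totals lambda = 6
    * ``b->m`` : 3, so latency(b->e) = 6 phase periods = 2 x latency(a->c)
    * ``b->d`` : 4 (free fixture parameter, not pinned by any relation)

    ``m`` is the internal convergence where streams from a and b interact.
    """
    if not (base_frequency > 0) or not (velocity > 0):
        raise ValidationError("base_frequency and velocity must be positive")
    pl = phase_length(base_frequency, velocity)
    nodes = [
        NetworkNode("a", "source"),
        NetworkNode("b", "source"),
        NetworkNode("m", "convergence"),
        NetworkNode("c", "sink"),
        NetworkNode("d", "sink"),
        NetworkNode("e", "sink"),
    ]
    mk = lambda u, v, n: Neurite(f"{u}->{v}", u, v, n * pl, velocity)
    neurites = [
        mk("a", "c", 3),
        mk("a", "m", 3),
        mk("b", "m", 3),
        mk("m", "e", 3),
        mk("b", "d", 4),
    ]
    return NetworkModel(nodes, neurites, refractory_duration)


def _routes(model: NetworkModel) -> list:
    """All simple source->sink paths as lists of neurite ids."""
    g = model.to_networkx()
    routes = []
    for s in sorted(n.id for n in model.sources):
        for k in sorted(n.id for n in model.sinks):
            for path in nx.all_simple_edge_paths(g, s, k):
                routes.append([eid for _u, _v, eid in path])
    return routes


def _driving_frequency(
    model: NetworkModel, neurite: Neurite, freqs: Mapping[str, float]
) -> float | None:
    """Frequency of the unique driven source upstream of the edge, if any."""
    g = model.to_networkx()
    upstream = nx.ancestors(g, neurite.from_node) | {neurite.from_node}
    driven = [s for s, f in freqs.items() if f > 0 and s in upstream]
    if len(driven) == 1:
        return freqs[driven[0]]
    return None


def frequency_response(
    model: NetworkModel,
    input_frequencies: Mapping[str, float],
    t_end: float | None = None,
    seed: int | None = None,
    phases: Mapping[str, float] | None = None,
    fusion_tolerance: float = DEFAULT_FUSION_TOLERANCE_S,
) -> FrequencyResponse:
    """Drive sources periodically and measure steady-state phase occupancy.

    The transient horizon is twice the longest route latency; in-transit
    counts are read half an input period after it (between arrival instants)
    and sink frequencies are averaged over the post-transient window.
    Phases default to 0 (deterministic); pass ``seed`` for uniform random
    phases or ``phases`` for explicit ones.
    """
    route_edges = _routes(model)
    if not route_edges:
        raise ValidationError("network has no source->sink route")
    route_latency = {
        tuple(eids): sum(latency(model.neurite(e)) for e in eids)
        for eids in route_edges
    }
    longest = max(route_latency.values())
    transient = 2.0 * longest
    freqs = {s.id: float(input_frequencies.get(s.id, 0.0)) for s in model.sources}
    driven = {s: f for s, f in freqs.items() if f > 0}
    f_min = min(driven.values()) if driven else None
    if t_end is None:
        t_end = transient + (2.5 / f_min if f_min else 1.0)
    if t_end <= transient:
        raise ConfigurationError(
            f"t_end ({t_end!r}) must exceed the transient horizon ({transient!r})"
        )
    t_measure = transient + (0.5 / f_min if f_min else 0.5 * (t_end - transient))
    t_measure = min(t_measure, t_end)

    if phases is not None:
        phase_map = {s: float(phases.get(s, 0.0)) for s in freqs}
    elif seed is not None:
        rng = np.random.default_rng(seed)
        phase_map = {
            s: (rng.random() / f if f > 0 else 0.0)
            for s, f in sorted(freqs.items())
        }
    else:
        phase_map = {s: 0.0 for s in freqs}

    inputs = {
        s: periodic_train(
            f, phase_map[s], t_end, model.refractory_duration, location=s
        )
        for s, f in freqs.items()
    }
    result = simulate(model, inputs, t_end, fusion_tolerance)

    edge_summaries = []
    for e in model.neurites:
        f_drive = _driving_frequency(model, e, freqs)
        lam = edge_lambda(e, f_drive) if f_drive else 0.0
        edge_summaries.append(
            EdgePhaseSummary(
                neurite_id=e.id,
                lam=lam,
                in_transit=in_transit_count(result, e.id, t_measure),
                route=(e.from_node, e.to_node),
            )
        )
    by_id = {s.neurite_id: s for s in edge_summaries}

    route_summaries = []
    for eids in route_edges:
        first = model.neurite(eids[0])
        src, snk = first.from_node, model.neurite(eids[-1]).to_node
        nodes = (src,) + tuple(model.neurite(e).to_node for e in eids)
        route_summaries.append(
            RouteSummary(
                source=src,
                sink=snk,
                route=nodes,
                edge_ids=tuple(eids),
                lam=sum(by_id[e].lam for e in eids),
                in_transit=sum(by_id[e].in_transit for e in eids),
            )
        )

    # renewal-rate estimate over the post-transient window: unbiased for
    # periodic trains regardless of window/phase alignment
    sink_frequencies = {}
    for snk in sorted(n.id for n in model.sinks):
        w = [t for t in result.output_trains[snk].times if transient <= t <= t_end]
        if len(w) < 2:
            sink_frequencies[snk] = 0.0
        else:
            sink_frequencies[snk] = (len(w) - 1) / (w[-1] - w[0])

    return FrequencyResponse(
        edge_summaries=edge_summaries,
        route_summaries=route_summaries,
        sink_frequencies=sink_frequencies,
        transient=transient,
        t_measure=t_measure,
        t_end=t_end,
        result=result,
    )


@dataclass
class UniquenessReport:
    """Input-tuple -> output-tuple mapping over a frequency grid, with an
    exhaustive pairwise injectivity verdict and a same-seed replicability
    verdict."""

    mapping: dict
    injective: bool
    replicable: bool
    collision_counts: dict


def uniqueness_probe(
    model: NetworkModel,
    frequency_grid: Mapping[str, Sequence[float]],
    t_end: float | None = None,
    seed: int | None = None,
    round_hz: int = 9,
) -> UniquenessReport:
    """Evaluate the network's input->output frequency map over a finite grid.

    For every combination of source frequencies the sink-frequency tuple is
    recorded; injectivity is decided by brute-force comparison of all pairs,
    and replicability by re-running the first grid point with the same seed.
    """
    sources = sorted(n.id for n in model.sources)
    sinks = sorted(n.id for n in model.sinks)
    grids = [list(frequency_grid.get(s, [0.0])) for s in sources]
    mapping: dict = {}
    collision_counts: dict = {}
    for combo in itertools.product(*grids):
        freqs = dict(zip(sources, combo))
        fr = frequency_response(model, freqs, t_end=t_end, seed=seed)
        out = tuple(round(fr.sink_frequencies[k], round_hz) for k in sinks)
        mapping[tuple(combo)] = out
        counts = fr.result.outcome_counts()
        collision_counts[tuple(combo)] = counts["fused"] + counts["annulled"]
    combos = list(mapping)
    injective = all(
        mapping[x] != mapping[y]
        for i, x in enumerate(combos)
        for y in combos[i + 1 :]
    )
    replicable = True
    if combos:
        first = combos[0]
        fr = frequency_response(
            model, dict(zip(sources, first)), t_end=t_end, seed=seed
        )
        out = tuple(round(fr.sink_frequencies[k], round_hz) for k in sinks)
        replicable = out == mapping[first]
    return UniquenessReport(
        mapping=mapping,
        injective=injective,
        replicable=replicable,
        collision_counts=collision_counts,
    )
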