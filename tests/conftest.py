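"""Shared fixtures: small hand-built networks and seeded random ones.

Random networks used for oracle-equivalence checks are generated on the
oracle's space-time lattice: edge lengths are integer multiples of
``velocity * dt`` and input times are snapped to the ``dt`` grid, so the
event-driven and dense-time engines see numerically identical geometry and
any disagreement is a genuine semantic difference, not discretisation of
the fixture itself.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from capsim import NetworkModel, NetworkNode, Neurite, PulseTrain

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

DT = 1e-6
VELOCITY = 0.3


def chain_model(total_latency: float = 0.02, refractory: float = 1e-3) -> NetworkModel:
    """source -> sink over a single neurite of the given latency."""
    nodes = [NetworkNode("src", "source"), NetworkNode("out", "sink")]
    neurites = [Neurite("src->out", "src", "out", total_latency * VELOCITY, VELOCITY)]
    return NetworkModel(nodes, neurites, refractory)


def convergence_model(
    n_sources: int = 2,
    branch_latency: float = 5e-3,
    relay_latency: float = 2e-3,
    refractory: float = 1e-3,
) -> NetworkModel:
    """n equal-latency branches into one convergence, then a relay to a sink."""
    nodes = [NetworkNode(f"s{i}", "source") for i in range(n_sources)]
    nodes += [NetworkNode("m", "convergence"), NetworkNode("out", "sink")]
    neurites = [
        Neurite(f"s{i}->m", f"s{i}", "m", branch_latency * VELOCITY, VELOCITY)
        for i in range(n_sources)
    ]
    neurites.append(
        Neurite("m->out", "m", "out", relay_latency * VELOCITY, VELOCITY)
    )
    return NetworkModel(nodes, neurites, refractory)


def random_network(rng: np.random.Generator, refractory: float = 1e-3) -> NetworkModel:
    """Random feedforward network with at most 6 nodes, lattice-aligned edges."""
    n_src = int(rng.integers(1, 3))
    n_conv = int(rng.integers(1, 3))
    n_sink = int(rng.integers(1, 3))
    sources = [f"s{i}" for i in range(n_src)]
    convs = [f"m{i}" for i in range(n_conv)]
    sinks = [f"k{i}" for i in range(n_sink)]

    def mk_edge(eid, u, v):
        steps = int(rng.integers(1000, 5000))  # latency 1-5 ms on the lattice
        return Neurite(eid, u, v, steps * VELOCITY * DT, VELOCITY)

    edges = []
    eid = iter(range(1000))
    # every source feeds at least one convergence, sometimes two targets
    for s in sources:
        edges.append(mk_edge(f"e{next(eid)}", s, str(rng.choice(convs))))
        if rng.random() < 0.4:
            edges.append(
                mk_edge(f"e{next(eid)}", s, str(rng.choice(convs + sinks)))
            )
    # optional convergence chain, feedforward only
    if n_conv == 2 and rng.random() < 0.5:
        edges.append(mk_edge(f"e{next(eid)}", "m0", "m1"))
    # every convergence feeds at least one sink
    for m in convs:
        edges.append(mk_edge(f"e{next(eid)}", m, str(rng.choice(sinks))))
    # patch any convergence left without input (possible when all sources
    # picked the same target)
    for m in convs:
        if not any(e.to_node == m for e in edges):
            edges.append(mk_edge(f"e{next(eid)}", str(rng.choice(sources)), m))

    nodes = (
        [NetworkNode(s, "source") for s in sources]
        + [NetworkNode(m, "convergence") for m in convs]
        + [NetworkNode(k, "sink") for k in sinks]
    )
    return NetworkModel(nodes, edges, refractory)


def grid_poisson_inputs(
    model: NetworkModel,
    rng: np.random.Generator,
    rate: float,
    t_end: float,
    refractory: float = 1e-3,
) -> dict:
    """Poisson trains snapped to the dt lattice and re-thinned to >= L."""
    inputs = {}
    for node in model.sources:
        t, last, times = 0.0, -np.inf, []
        while True:
            t += rng.exponential(1.0 / rate)
            if t > t_end:
                break
            snapped = round(t / DT) * DT
            if snapped - last >= refractory and snapped <= t_end:
                times.append(snapped)
                last = snapped
        inputs[node.id] = PulseTrain(node.id, times)
    return inputs


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
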