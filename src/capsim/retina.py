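"""Retinal convergence circuit and refractory-gated mean sampling.

Groups of light receptors (about 12, up to 25) converge on a single bipolar
cell whose output is observed at a retinal ganglion cell (RGC).  Each
receptor's discharge frequency encodes local light intensity; at the
bipolar convergence the first CAP through opens its refractory window and
blocks successors, so the RGC inter-threshold structure reflects the pooled
receptor rate — mean sampling by collision, not by summation.

The receptor signal-polarity detail (cones hyperpolarise) is abstracted
away: every receptor output is a threshold train, since the computational
claim concerns timing only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .collisions import (
    DEFAULT_FUSION_TOLERANCE_S,
    SimulationResult,
    simulate,
)
from .core import (
    DEFAULT_REFRACTORY_S,
    NetworkModel,
    NetworkNode,
    Neurite,
    PulseTrain,
)
from .exceptions import ValidationError
from .generators import periodic_train

#: Observed band of bipolar-cell discharge frequencies (Hz).
F_MIN_HZ = 2.0
F_MAX_HZ = 100.0

CONVERGENCE_ID = "bipolar"
SINK_ID = "rgc"


@dataclass
class RetinaSpec:
    """Parameters of one receptor-group -> bipolar -> RGC circuit.

    ``n_receptors``: receptors per bipolar group (average 12, at most 25).
    ``receptor_frequencies``: optional per-receptor discharge rates (Hz);
    normally in the observed 2-100 Hz band unless ``allow_any_frequency``.
    ``neurite_length`` (m) and ``velocity`` (m/s) set equal receptor-to-
    bipolar conduction delays; ``relay_length`` the bipolar-to-RGC neurite
    (defaults to ``neurite_length``; the synapse itself is a pure relay).
    """

    n_receptors: int = 12
    receptor_frequencies: Sequence[float] | None = None
    neurite_length: float = 0.003
    velocity: float = 0.3
    refractory_duration: float = DEFAULT_REFRACTORY_S
    relay_length: float | None = None
    allow_any_frequency: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.n_receptors <= 25):
            raise ValidationError(
                f"n_receptors must be in [1, 25], got {self.n_receptors}"
            )
        if self.receptor_frequencies is not None:
            freqs = list(self.receptor_frequencies)
            if len(freqs) != self.n_receptors:
                raise ValidationError(
                    f"{len(freqs)} frequencies for {self.n_receptors} receptors"
                )
            if not self.allow_any_frequency:
                for f in freqs:
                    if f != 0 and not (F_MIN_HZ <= f <= F_MAX_HZ):
                        raise ValidationError(
                            f"receptor frequency {f!r} Hz outside "
                            f"[{F_MIN_HZ}, {F_MAX_HZ}] Hz "
                            "(set allow_any_frequency to override)"
                        )
        if not (self.neurite_length > 0) or not (self.velocity > 0):
            raise ValidationError("neurite_length and velocity must be positive")


def receptor_ids(spec: RetinaSpec) -> list:
    return [f"cone{i:02d}" for i in range(spec.n_receptors)]


def build_retina(spec: RetinaSpec) -> NetworkModel:
    """Network with ``n_receptors`` sources, one convergence, one RGC sink."""
    nodes = [NetworkNode(rid, "source") for rid in receptor_ids(spec)]
    nodes.append(NetworkNode(CONVERGENCE_ID, "convergence"))
    nodes.append(NetworkNode(SINK_ID, "sink"))
    neurites = [
        Neurite(
            id=f"{rid}->{CONVERGENCE_ID}",
            from_node=rid,
            to_node=CONVERGENCE_ID,
            length=spec.neurite_length,
            velocity=spec.velocity,
        )
        for rid in receptor_ids(spec)
    ]
    relay_length = (
        spec.relay_length if spec.relay_length is not None else spec.neurite_length
    )
    neurites.append(
        Neurite(
            id=f"{CONVERGENCE_ID}->{SINK_ID}",
            from_node=CONVERGENCE_ID,
            to_node=SINK_ID,
            length=relay_length,
            velocity=spec.velocity,
        )
    )
    return NetworkModel(nodes, neurites, spec.refractory_duration)


def encode_intensity(
    intensities: Sequence[float],
    f_min: float = F_MIN_HZ,
    f_max: float = F_MAX_HZ,
) -> np.ndarray:
    """Affine light-intensity -> discharge-frequency transfer.

    Intensities in [0, 1] map to ``f_min + intensity * (f_max - f_min)``.
    The affine form is the minimal assumption consistent with intensity and
    RGC frequency being proportionally related; swap in any monotone map if
    a different transfer is wanted.
    """
    if not (f_min < f_max):
        raise ValidationError("f_min must be < f_max")
    arr = np.asarray(list(intensities), dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValidationError("intensities must lie in [0, 1]")
    return f_min + arr * (f_max - f_min)


def mean_sampling_gap(
    output_train: PulseTrain, refractory_duration: float
) -> np.ndarray:
    """Per-interval x->z gaps: time from end of refractory to next threshold.

    For consecutive thresholds ``(t_i, t_{i+1})`` the gap is
    ``t_{i+1} - (t_i + L)``; it is what remains of the inter-threshold
    interval once the obligatory refractory window is removed, and is the
    quantity the convergence actually samples.  All gaps are >= 0 for a
    train respecting refractory separation (violating trains raise).
    """
    output_train.validate_refractory(refractory_duration)
    t = np.asarray(output_train.times, dtype=float)
    if t.size < 2:
        return np.empty(0)
    gaps = np.diff(t) - refractory_duration
    return np.clip(gaps, 0.0, None)  # clip float dust at saturation


def retina_response(
    spec: RetinaSpec,
    frequencies: Sequence[float] | None = None,
    intensities: Sequence[float] | None = None,
    t_end: float = 1.0,
    seed: int | None = None,
    phases: Sequence[float] | None = None,
    fusion_tolerance: float = DEFAULT_FUSION_TOLERANCE_S,
) -> SimulationResult:
    """Simulate the circuit under periodic receptor drive.

    Receptor frequencies come from ``frequencies``, else from
    ``encode_intensity(intensities)``, else from ``spec``.  Initial phases
    are, in order of precedence: ``phases`` (explicit, seconds), a seeded
    uniform draw on ``[0, 1/f)`` per receptor (mean sampling requires
    desynchronised arrivals), or zero.
    """
    if frequencies is None and intensities is not None:
        frequencies = encode_intensity(intensities)
    if frequencies is None:
        frequencies = spec.receptor_frequencies
    if frequencies is None:
        raise ValidationError("no receptor frequencies given")
    freqs = [float(f) for f in frequencies]
    rids = receptor_ids(spec)
    if len(freqs) != len(rids):
        raise ValidationError(
            f"{len(freqs)} frequencies for {len(rids)} receptors"
        )
    if phases is not None:
        phase_list = [float(p) for p in phases]
    elif seed is not None:
        rng = np.random.default_rng(seed)
        u = rng.random(len(rids))
        phase_list = [u_i / f if f > 0 else 0.0 for u_i, f in zip(u, freqs)]
    else:
        phase_list = [0.0] * len(rids)
    model = build_retina(spec)
    inputs = {
        rid: periodic_train(
            f, phase, t_end, spec.refractory_duration, location=rid
        )
        for rid, f, phase in zip(rids, freqs, phase_list)
    }
    return simulate(model, inputs, t_end, fusion_tolerance)


def rgc_frequency(
    result: SimulationResult, window: float, sink: str = SINK_ID
) -> float:
    """Mean RGC discharge rate (Hz) over the final ``window`` seconds.

    Threshold count in ``(t_end - window, t_end]`` divided by the window
    length; an empty window gives 0 (documented, not an error).
    """
    if not (0 < window <= result.t_end):
        raise ValidationError(
            f"window {window!r} must be positive and within the horizon"
        )
    train = result.output_trains[sink]
    t0 = result.t_end - window
    count = sum(1 for t in train.times if t0 < t <= result.t_end)
    return count / window
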