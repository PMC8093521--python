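"""Readers and writers: network JSON, train CSV, collision log, run manifest.

All times are serialised in seconds as decimal floats (17 significant
digits, enough to round-trip IEEE doubles exactly); units appear in the
column headers.  The network format carries a ``format_version`` field.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .core import NetworkModel, NetworkNode, Neurite, PulseTrain, validate_network
from .exceptions import ValidationError

FORMAT_VERSION = 1
TRAIN_COLUMNS = ("location_id", "time_s")


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


# ---------------------------------------------------------------------------
# network JSON
# ---------------------------------------------------------------------------

def write_network(model: NetworkModel, path) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "refractory_s": model.refractory_duration,
        "nodes": [{"id": n.id, "kind": n.kind} for n in model.nodes],
        "neurites": [
            {
                "id": e.id,
                "from": e.from_node,
                "to": e.to_node,
                "length_m": e.length,
                "velocity_mps": e.velocity,
                **(
                    {"refractory_s": e.refractory_duration}
                    if e.refractory_duration is not None
                    else {}
                ),
            }
            for e in model.neurites
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_network(path) -> NetworkModel:
    """Parse and validate a network description; raise with element context."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: top level must be an object")
    version = doc.get("format_version")
    if version != FORMAT_VERSION:
        raise ValidationError(
            f"{path}: unsupported format_version {version!r} "
            f"(expected {FORMAT_VERSION})"
        )
    nodes = []
    for i, nd in enumerate(doc.get("nodes", [])):
        for key in ("id", "kind"):
            if key not in nd:
                raise ValidationError(f"{path}: nodes[{i}] missing {key!r}")
        nodes.append(NetworkNode(nd["id"], nd["kind"]))
    neurites = []
    for i, ed in enumerate(doc.get("neurites", [])):
        label = ed.get("id", f"neurites[{i}]")
        for key in ("id", "from", "to", "length_m", "velocity_mps"):
            if key not in ed:
                raise ValidationError(
                    f"{path}: neurite {label!r} missing field {key!r}"
                )
        neurites.append(
            Neurite(
                id=ed["id"],
                from_node=ed["from"],
                to_node=ed["to"],
                length=float(ed["length_m"]),
                velocity=float(ed["velocity_mps"]),
                refractory_duration=(
                    float(ed["refractory_s"]) if "refractory_s" in ed else None
                ),
            )
        )
    model = NetworkModel(
        nodes, neurites, float(doc.get("refractory_s", 1e-3))
    )
    violations = validate_network(model)
    if violations:
        raise ValidationError(f"{path}: " + "; ".join(violations))
    return model


# ---------------------------------------------------------------------------
# trains CSV
# ---------------------------------------------------------------------------

def write_trains(trains: Mapping[str, PulseTrain] | Sequence[PulseTrain], path) -> None:
    """Two-column CSV ``location_id,time_s``, times at full precision."""
    if isinstance(trains, Mapping):
        trains = list(trains.values())
    lines = [",".join(TRAIN_COLUMNS)]
    for train in trains:
        for t in train.times:
            lines.append(f"{train.location},{_fmt(t)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trains(path, refractory_duration: float | None = None) -> dict:
    """Read trains; validate ordering and (optionally) refractory separation.

    Rows may appear in any order per location but must not contain duplicate
    timestamps at the same location; offending rows are listed in the error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface parse context
        raise ValidationError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in TRAIN_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    trains: dict[str, PulseTrain] = {}
    for loc, group in df.groupby("location_id", sort=True):
        times = group["time_s"].astype(float).tolist()
        ordered = sorted(times)
        bad = [_fmt(b) for a, b in zip(ordered, ordered[1:]) if not (b > a)]
        if bad:
            raise ValidationError(
                f"{path}: duplicate timestamps at {loc!r}: {', '.join(bad)}"
            )
        train = PulseTrain(str(loc), ordered)
        if refractory_duration is not None:
            train.validate_refractory(refractory_duration)
        trains[str(loc)] = train
    return trains


def write_collisions(records: Sequence, path) -> None:
    """Collision log CSV: time_s,node,outcome,participants,survivor."""
    rows = [
        {
            "time_s": _fmt(rec.time),
            "node": rec.node,
            "outcome": rec.outcome,
            "participants": ";".join(rec.participants),
            "survivor": rec.survivor or "",
        }
        for rec in records
    ]
    pd.DataFrame(
        rows, columns=["time_s", "node", "outcome", "participants", "survivor"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Everything needed to re-run a stochastic command bit-identically:
    fully resolved parameters, the seed, the tool version, and digests of
    the input files."""

    parameters: dict
    seed: int | None
    tool_version: str = ""
    input_digests: dict = field(default_factory=dict)
    timestamp: str = ""


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    path,
    parameters: Mapping,
    seed: int | None = None,
    input_paths: Sequence | None = None,
) -> RunManifest:
    from . import __version__

    manifest = RunManifest(
        parameters=dict(parameters),
        seed=seed,
        tool_version=__version__,
        input_digests={
            str(p): file_digest(p) for p in (input_paths or [])
        },
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    doc = {
        "parameters": manifest.parameters,
        "seed": manifest.seed,
        "tool_version": manifest.tool_version,
        "input_digests": manifest.input_digests,
        "timestamp": manifest.timestamp,
    }
    Path(path).write_text(json.dumps(doc, indent=2, default=str) + "\n")
    return manifest
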