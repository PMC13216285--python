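"""Serialization (network JSON schema, GraphML export), result export and
run manifests.

Network schema ``trenshsim-network/1``: a JSON object with ``nodes``
(id, role, x, y and, for intranidal nodes, compartment/column), ``vessels``
(geometry in cm, resistance in dyn*s*cm^-5, category/class, nominal
tail/head), ``emfs`` (id, attached edge, polarity, pressure in mmHg) and
optional ``nidus`` metadata (compartment/column counts, fistula path,
boundary attachments, seed).  The round trip is lossless.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from typing import Optional

import networkx as nx
import pandas as pd

from . import __version__
from .config import SimulationConfig
from .errors import ParseError
from .network import EMFSource, Node, Vessel, VesselNetwork
from .nidus import NidusArchitecture

SCHEMA = "trenshsim-network/1"


def network_to_dict(network: VesselNetwork) -> dict:
    d = {
        "schema": SCHEMA,
        "viscosity": network.config.viscosity,
        "nodes": [asdict(n) for n in network.nodes.values()],
        "vessels": [asdict(v) for v in network.vessels.values()],
        "emfs": [asdict(e) for e in network.emfs.values()],
        "nidus": None,
    }
    if network.nidus is not None:
        nid = network.nidus
        d["nidus"] = {
            "n_compartments": nid.n_compartments,
            "n_columns": nid.n_columns,
            "fistula_path": list(nid.fistula_path),
            "boundary_attachments": dict(nid.boundary_attachments),
            "extra_attachments": [list(p) for p in nid.extra_attachments],
            "seed": nid.seed,
        }
    return d


def write_network(network: VesselNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(network), fh, indent=1)


def network_from_dict(d: dict,
                      config: SimulationConfig | None = None
                      ) -> VesselNetwork:
    if not isinstance(d, dict) or d.get("schema") != SCHEMA:
        raise ParseError(f"not a {SCHEMA} document")
    net = VesselNetwork(config or SimulationConfig())
    try:
        for nd in d["nodes"]:
            net.add_node(Node(**nd))
        for vd in d["vessels"]:
            vessel = Vessel(**vd)
            if vessel.radius <= 0 or vessel.length <= 0:
                raise ParseError(
                    f"vessel {vessel.id!r} has non-positive geometry")
            net.add_vessel(vessel)
        for ed in d["emfs"]:
            net.emfs[ed["id"]] = EMFSource(**ed)
        nid = d.get("nidus")
    except ParseError:
        raise
    except (KeyError, TypeError) as exc:
        raise ParseError(f"malformed network document: {exc}") from exc
    if nid is not None:
        net.nidus = NidusArchitecture(
            n_compartments=nid["n_compartments"],
            n_columns=nid["n_columns"],
            nodes=[n for n in net.nodes.values() if n.compartment is not None],
            vessels=[v for v in net.vessels.values() if v.is_intranidal],
            fistula_path=list(nid["fistula_path"]),
            boundary_attachments=dict(nid["boundary_attachments"]),
            extra_attachments=[tuple(p) for p in nid["extra_attachments"]],
            seed=nid.get("seed"))
    return net


def read_network(path, config: SimulationConfig | None = None
                 ) -> VesselNetwork:
    try:
        with open(path) as fh:
            d = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON in {path}: {exc}") from exc
    return network_from_dict(d, config)


def export_graphml(network: VesselNetwork, path) -> None:
    """GraphML export for external inspection tools."""
    g = nx.MultiDiGraph()
    for n in network.nodes.values():
        g.add_node(n.id, role=n.role, x=float(n.x), y=float(n.y))
    for v in network.vessels.values():
        g.add_edge(v.tail, v.head, key=v.id, length=v.length,
                   radius=v.radius, resistance=v.resistance,
                   category=v.category)
    nx.write_graphml(g, path)


@dataclass
class RunManifest:
    """Reproducibility record written next to every batch output."""

    master_seed: int
    grid: str
    n_architectures: int
    outputs: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    tool_version: str = __version__
    python: str = platform.python_version()
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())
    timings_s: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def write_results(table: pd.DataFrame, path,
                  manifest: Optional[RunManifest] = None) -> None:
    """Plain-CSV result export with a sidecar JSON manifest."""
    table.to_csv(path, index=False)
    if manifest is not None:
        manifest.outputs.append(str(path))
        manifest.write(str(path) + ".manifest.json")
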