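"""Domain types for vessels, nodes and EMF sources, and construction of the
fixed extranidal arterial/venous template.

The template mirrors the classical electrical-network AVM architecture: an
aortic arch feeding the common carotid and subclavian trunks, internal /
external carotid and vertebral arteries, the middle / anterior / posterior
cerebral arteries and a transosseous feeding artery, terminating in four
arterial feeders (AF1..AF4); venous return runs from three draining veins
(DV1..DV3) through the dural sinuses to the vena cava.  Nine electromotive
forces drive the circuit: ESP (systemic pressure) at the aortic root, one per
AF, one per DV, and ECVP (central venous pressure) at the vena cava outlet.

Edge orientation is nominal (arterial -> venous); solved flow may be negative,
which is how retrograde injection is expressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np

from .config import EXTRANIDAL_CLASSES, SimulationConfig
from .errors import InvalidGeometryError, TopologyError

#: vessel class -> category
_CATEGORY = {
    "aortic-arch": "extranidal-artery",
    "common-carotid": "extranidal-artery",
    "subclavian": "extranidal-artery",
    "internal-carotid": "extranidal-artery",
    "external-carotid": "extranidal-artery",
    "vertebral": "extranidal-artery",
    "mca": "extranidal-artery",
    "aca": "extranidal-artery",
    "pca": "extranidal-artery",
    "transosseous-feeder": "extranidal-artery",
    "cerebral-runoff": "extranidal-artery",
    "af1": "AF", "af2": "AF", "af3": "AF", "af4": "AF",
    "af-branch": "AF",
    "dv1": "DV", "dv2": "DV", "dv3": "DV",
    "dv-branch": "DV",
    "dural-sinus": "extranidal-vein",
    "vena-cava": "extranidal-vein",
    "plexiform": "intranidal-plexiform",
    "fistula": "intranidal-fistula",
}

INTRANIDAL_CATEGORIES = ("intranidal-plexiform", "intranidal-fistula")

EMF_IDS = ("ESP", "EAF1", "EAF2", "EAF3", "EAF4", "EDV1", "EDV2", "EDV3",
           "ECVP")


def vessel_resistance(length: float, radius: float, viscosity: float) -> float:
    """Hydraulic (Poiseuille) resistance 8*L*mu / (pi * r^4).

    Parameters are in CGS units (cm, cm, poise); the result is in
    dyn*s*cm^-5.  Non-positive arguments raise :class:`InvalidGeometryError`.
    """
    if length <= 0 or radius <= 0 or viscosity <= 0:
        raise InvalidGeometryError(
            f"length, radius and viscosity must be positive "
            f"(got L={length}, r={radius}, mu={viscosity})")
    return 8.0 * length * viscosity / (math.pi * radius ** 4)


@dataclass
class Vessel:
    """A directed vessel edge with geometry and derived resistance."""

    id: str
    tail: str
    head: str
    length: float  # cm
    radius: float  # cm
    resistance: float  # dyn*s*cm^-5
    category: str
    vclass: str
    compartment: Optional[int] = None
    column: Optional[int] = None

    @classmethod
    def from_dimensions(cls, vid: str, tail: str, head: str, vclass: str,
                        config: SimulationConfig,
                        compartment: Optional[int] = None,
                        column: Optional[int] = None) -> "Vessel":
        length, radius = config.dimensions(vclass)
        return cls(id=vid, tail=tail, head=head, length=length, radius=radius,
                   resistance=vessel_resistance(length, radius,
                                                config.viscosity),
                   category=_CATEGORY[vclass], vclass=vclass,
                   compartment=compartment, column=column)

    @property
    def is_intranidal(self) -> bool:
        return self.category in INTRANIDAL_CATEGORIES


@dataclass
class Node:
    """A branching point of the vascular network."""

    id: str
    role: str = "junction"  # junction | AF-terminal | DV-terminal | source-terminal
    x: float = 0.0
    y: float = 0.0
    compartment: Optional[int] = None
    column: Optional[int] = None


@dataclass
class EMFSource:
    """An ideal pressure source driving the circuit.

    ``ESP`` and ``ECVP`` pin their terminal node (aortic root / vena-cava
    outlet) to the set's systemic and central venous pressure; the AF and DV
    sources act in series with their attached vessel.  ``polarity`` is +1 when
    a positive pressure boosts flow in the vessel's nominal (tail->head)
    direction and -1 when it opposes it; DV sources have polarity -1 so that a
    positive injection pressure drives flow retrogradely into the nidus.
    """

    id: str
    attached_edge: str
    pressure: float = 0.0  # mmHg
    polarity: int = 1


class VesselNetwork:
    """The full directed multigraph: extranidal template plus optional nidus."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.nodes: dict[str, Node] = {}
        self.vessels: dict[str, Vessel] = {}
        self.emfs: dict[str, EMFSource] = {}
        self.nidus = None  # NidusArchitecture or None
        self._cache: dict = {}

    # -- construction ------------------------------------------------------

    def add_node(self, node: Node) -> None:
        if node.id in self.nodes:
            raise TopologyError(f"duplicate node id {node.id!r}")
        self.nodes[node.id] = node
        self._cache.clear()

    def add_vessel(self, vessel: Vessel) -> None:
        if vessel.id in self.vessels:
            raise TopologyError(f"duplicate vessel id {vessel.id!r}")
        if vessel.tail not in self.nodes or vessel.head not in self.nodes:
            raise TopologyError(
                f"vessel {vessel.id!r} references unknown node "
                f"{vessel.tail!r} or {vessel.head!r}")
        self.vessels[vessel.id] = vessel
        self._cache.clear()

    # -- views -------------------------------------------------------------

    @property
    def af_terminals(self) -> list[str]:
        return [n.id for n in self.nodes.values() if n.role == "AF-terminal"]

    @property
    def dv_terminals(self) -> list[str]:
        return [n.id for n in self.nodes.values() if n.role == "DV-terminal"]

    def intranidal_vessel_ids(self) -> list[str]:
        return [v.id for v in self.vessels.values() if v.is_intranidal]

    def boundary_in_vessel_ids(self) -> list[str]:
        """Vessels crossing the AF boundary into the nidus (tail at an AF
        terminal)."""
        af = set(self.af_terminals)
        return [v.id for v in self.vessels.values() if v.tail in af]

    def boundary_out_vessel_ids(self) -> list[str]:
        """Vessels crossing the DV boundary out of the nidus (head at a DV
        terminal)."""
        dv = set(self.dv_terminals)
        return [v.id for v in self.vessels.values() if v.head in dv]

    def graph(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for node in self.nodes.values():
            g.add_node(node.id, role=node.role, x=node.x, y=node.y)
        for v in self.vessels.values():
            g.add_edge(v.tail, v.head, key=v.id, resistance=v.resistance,
                       category=v.category)
        return g

    def is_connected(self, removed: Iterable[str] = ()) -> bool:
        removed = set(removed)
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((v.tail, v.head) for v in self.vessels.values()
                         if v.id not in removed)
        return nx.is_connected(g) if len(g) else False

    # -- compiled arrays (shared by solver and metrics) --------------------

    def compiled(self) -> dict:
        """Index arrays over nodes and vessels, cached.

        Networks are treated as immutable once built; the cache is cleared on
        any mutation.
        """
        if "compiled" not in self._cache:
            node_ids = list(self.nodes)
            node_index = {nid: i for i, nid in enumerate(node_ids)}
            vessel_ids = list(self.vessels)
            vessel_index = {vid: i for i, vid in enumerate(vessel_ids)}
            vs = list(self.vessels.values())
            self._cache["compiled"] = {
                "node_ids": node_ids,
                "node_index": node_index,
                "vessel_ids": vessel_ids,
                "vessel_index": vessel_index,
                "tail": np.array([node_index[v.tail] for v in vs]),
                "head": np.array([node_index[v.head] for v in vs]),
                "resistance": np.array([v.resistance for v in vs]),
                "intranidal": np.array([v.is_intranidal for v in vs]),
            }
        return self._cache["compiled"]


def build_extranidal_template(config: SimulationConfig) -> VesselNetwork:
    """Build the fixed extranidal network (no nidus attached).

    The returned network has exactly four AF terminals, three DV terminals and
    nine EMF sources; every vessel carries its precomputed resistance.  A
    missing dimension entry raises :class:`ConfigurationError` naming the
    vessel class.
    """
    # validate the full table up front so the error names the missing class
    for vclass in EXTRANIDAL_CLASSES:
        config.dimensions(vclass)

    net = VesselNetwork(config)

    arterial_nodes = [
        ("aortic-root", "source-terminal", -7.0, 2.0),
        ("arch-out", "junction", -6.0, 2.0),
        ("cca-top", "junction", -5.0, 1.2),
        ("sub-out", "junction", -5.0, 3.0),
        ("ica-top", "junction", -4.0, 0.8),
        ("eca-out", "junction", -4.0, 2.0),
        ("va-top", "junction", -4.0, 3.2),
        ("mca-out", "junction", -2.0, 1.0),
        ("aca-out", "junction", -2.0, 0.2),
        ("pca-out", "junction", -2.0, 2.8),
        ("tfa-out", "junction", -2.0, 3.6),
    ]
    for nid, role, x, y in arterial_nodes:
        net.add_node(Node(nid, role, x, y))
    for i in range(1, 5):
        net.add_node(Node(f"AF{i}t", "AF-terminal", 0.0, float(i)))
    for i in range(1, 4):
        net.add_node(Node(f"DV{i}t", "DV-terminal", 6.0, float(i)))
    for nid, role, x, y in [("sinus", "junction", 8.0, 2.0),
                            ("svc-in", "junction", 9.0, 2.0),
                            ("vc-outlet", "source-terminal", 10.0, 2.0)]:
        net.add_node(Node(nid, role, x, y))

    wiring = [
        ("aortic-arch", "aortic-root", "arch-out"),
        ("common-carotid", "arch-out", "cca-top"),
        ("subclavian", "arch-out", "sub-out"),
        ("internal-carotid", "cca-top", "ica-top"),
        ("external-carotid", "cca-top", "eca-out"),
        ("vertebral", "sub-out", "va-top"),
        ("mca", "ica-top", "mca-out"),
        ("aca", "ica-top", "aca-out"),
        ("pca", "va-top", "pca-out"),
        ("transosseous-feeder", "eca-out", "tfa-out"),
        # AF2 branches from the MCA (highest-flow feeder), AF1 from the ACA;
        # the minor feeders AF3/AF4 come off the PCA and transosseous artery.
        ("af2", "mca-out", "AF2t"),
        ("af1", "aca-out", "AF1t"),
        ("af3", "pca-out", "AF3t"),
        ("af4", "tfa-out", "AF4t"),
        ("dv1", "DV1t", "sinus"),
        ("dv2", "DV2t", "sinus"),
        ("dv3", "DV3t", "sinus"),
        ("dural-sinus", "sinus", "svc-in"),
        ("vena-cava", "svc-in", "vc-outlet"),
    ]
    for vclass, tail, head in wiring:
        vid = vclass.upper() if vclass.startswith(("af", "dv")) else vclass
        net.add_vessel(Vessel.from_dimensions(vid, tail, head, vclass, config))
    # normal-territory runoff of each cerebral artery, returning to the
    # systemic veins distal to the dural sinus
    for origin in ("mca-out", "aca-out", "pca-out", "tfa-out"):
        net.add_vessel(Vessel.from_dimensions(
            f"runoff-{origin.split('-')[0]}", origin, "svc-in",
            "cerebral-runoff", config))

    net.emfs["ESP"] = EMFSource("ESP", "aortic-arch")
    for i in range(1, 5):
        net.emfs[f"EAF{i}"] = EMFSource(f"EAF{i}", f"AF{i}")
    for i in range(1, 4):
        net.emfs[f"EDV{i}"] = EMFSource(f"EDV{i}", f"DV{i}", polarity=-1)
    net.emfs["ECVP"] = EMFSource("ECVP", "vena-cava")
    return net


def attach_nidus(template: VesselNetwork, nidus) -> VesselNetwork:
    """Attach a generated nidus architecture to an extranidal template.

    Returns a new connected :class:`VesselNetwork`; the template is not
    modified.  Boundary attachments become small AF-branch / DV-branch
    vessels; dangling attachment references raise :class:`TopologyError`.
    """
    config = template.config
    net = VesselNetwork(config)
    for node in template.nodes.values():
        net.add_node(Node(node.id, node.role, node.x, node.y))
    for v in template.vessels.values():
        net.add_vessel(Vessel(**vars(v)))
    net.emfs = {k: EMFSource(**vars(e)) for k, e in template.emfs.items()}

    c, k = nidus.n_compartments, nidus.n_columns
    # place AF/DV terminals on the nidus layout frame (x=0 and x=K+1, spread
    # evenly over the stacked compartments)
    for i in range(1, 5):
        t = net.nodes[f"AF{i}t"]
        t.x, t.y = 0.0, c * (i - 0.5) / 4.0
    for i in range(1, 4):
        t = net.nodes[f"DV{i}t"]
        t.x, t.y = float(k + 1), c * (i - 0.5) / 3.0

    for node in nidus.nodes:
        net.add_node(node)
    for v in nidus.vessels:
        if v.tail not in net.nodes or v.head not in net.nodes:
            raise TopologyError(
                f"nidus vessel {v.id!r} references unknown terminal or node")
        net.add_vessel(v)

    pairs = sorted(nidus.boundary_attachments.items())
    pairs += [(node_id, terminal)
              for terminal, node_id in nidus.extra_attachments]
    for node_id, terminal in pairs:
        if terminal not in net.nodes or node_id not in net.nodes:
            raise TopologyError(
                f"attachment {node_id!r} <-> {terminal!r} references an "
                f"unknown node")
        if terminal.startswith("AF"):
            tail, head, vclass = terminal, node_id, "af-branch"
        else:
            tail, head, vclass = node_id, terminal, "dv-branch"
        net.add_vessel(Vessel.from_dimensions(
            f"{vclass}:{terminal}:{node_id}", tail, head, vclass, config))

    net.nidus = nidus
    if not net.is_connected():
        raise TopologyError("network is not connected after nidus attachment")
    return net
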