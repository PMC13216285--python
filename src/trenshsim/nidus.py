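"""Stochastic generation of compartmentalized plexiform nidus architectures.

A nidus is organized into C horizontal compartments (C drawn from a rounded
normal centred on 4.5, sd 1, truncated to [3, 6]) and K columns (centred on
5, sd 1, truncated to [3, 7]).  Columns represent steps of distance from the
arterial feeders (left) to the draining veins (right); end columns carry
30-34 nodes per compartment and interior columns 36-40.  Intracompartmental
vessels guarantee every node at least one incoming vessel from the previous
column and one outgoing vessel to the next; 2*C*K intercompartmental vessels
connect random nodes of different compartments; a single larger-radius
fistula runs from AF2 through one node of each column of the middle
compartment to DV2.  First/last-column nodes attach to the nearest AF/DV
terminal by Euclidean distance in the layout.

Generation is fully deterministic for a given seed: random draws occur in a
fixed documented order (compartments, columns, cell sizes, incoming vessels,
outgoing fixes, intercompartmental vessels, fistula route).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig
from .errors import ParameterError
from .network import Node, Vessel, vessel_resistance

__all__ = [
    "NidusArchitecture",
    "sample_architecture",
    "sample_truncated_normal_integer",
    "generate_intercompartmental_vessels",
    "route_fistula",
    "attach_boundaries",
]


@dataclass
class NidusArchitecture:
    """The stochastic intranidal subgraph."""

    n_compartments: int
    n_columns: int
    nodes: list[Node] = field(default_factory=list)
    vessels: list[Vessel] = field(default_factory=list)
    fistula_path: list[str] = field(default_factory=list)
    #: first/last-column node id -> AF/DV terminal id
    boundary_attachments: dict[str, str] = field(default_factory=dict)
    #: (terminal id, node id) pairs for terminals left otherwise unconnected
    extra_attachments: list[tuple[str, str]] = field(default_factory=list)
    seed: int | None = None

    @property
    def n_vessels(self) -> int:
        """Number of intranidal vessels (plexiform + fistula)."""
        return len(self.vessels)

    def cell_nodes(self) -> dict[tuple[int, int], list[Node]]:
        """Nodes grouped by (compartment, column), in creation order."""
        cells: dict[tuple[int, int], list[Node]] = {}
        for node in self.nodes:
            cells.setdefault((node.compartment, node.column), []).append(node)
        return cells

    def af_coordinates(self) -> dict[str, tuple[float, float]]:
        c = self.n_compartments
        return {f"AF{i}t": (0.0, c * (i - 0.5) / 4.0) for i in range(1, 5)}

    def dv_coordinates(self) -> dict[str, tuple[float, float]]:
        c, k = self.n_compartments, self.n_columns
        return {f"DV{i}t": (float(k + 1), c * (i - 0.5) / 3.0)
                for i in range(1, 4)}


def sample_truncated_normal_integer(rng: np.random.Generator, mean: float,
                                    sd: float, low: int, high: int) -> int:
    """Rounded normal draw restricted to [low, high] by rejection.

    Out-of-range draws are resampled (not clipped), so the result follows a
    rounded normal distribution truncated to the bounds.  ``sd = 0``
    degenerates to ``round(mean)``.
    """
    if low > high:
        raise ParameterError(f"low ({low}) exceeds high ({high})")
    if sd < 0:
        raise ParameterError("sd must be non-negative")
    if sd == 0:
        k = int(math.floor(mean + 0.5))
        if not low <= k <= high:
            raise ParameterError(
                f"degenerate draw {k} outside bounds [{low}, {high}]")
        return k
    for _ in range(100_000):
        k = int(math.floor(rng.normal(mean, sd) + 0.5))
        if low <= k <= high:
            return k
    raise ParameterError(
        f"truncated normal ({mean}, {sd}) never hit [{low}, {high}]")


def _plexiform_proto(config: SimulationConfig):
    length, radius = config.dimensions("plexiform")
    return length, radius, vessel_resistance(length, radius, config.viscosity)


def generate_intercompartmental_vessels(
        rng: np.random.Generator, architecture: NidusArchitecture,
        config: SimulationConfig | None = None) -> list[Vessel]:
    """Generate exactly 2*C*K vessels linking distinct compartments.

    Each vessel starts on a uniformly random node of a random column of a
    random compartment; the end compartment is uniform over the remaining
    compartments, the end column is a rounded normal centred on (but
    excluding) the start column with sd 2 (redrawn until it lands in [1, K]),
    and the end node is uniform within that cell.
    """
    config = config or SimulationConfig()
    c, k = architecture.n_compartments, architecture.n_columns
    sd = config.nidus.intercompartmental_column_sd
    cells = architecture.cell_nodes()
    length, radius, resistance = _plexiform_proto(config)
    vessels = []
    for idx in range(2 * c * k):
        s_c = int(rng.integers(1, c + 1))
        s_j = int(rng.integers(1, k + 1))
        start = cells[(s_c, s_j)][int(rng.integers(len(cells[(s_c, s_j)])))]
        t = int(rng.integers(1, c))  # uniform over the c-1 other compartments
        e_c = t if t < s_c else t + 1
        while True:
            e_j = int(math.floor(rng.normal(s_j, sd) + 0.5))
            if 1 <= e_j <= k and e_j != s_j:
                break
        end = cells[(e_c, e_j)][int(rng.integers(len(cells[(e_c, e_j)])))]
        vessels.append(Vessel(
            id=f"I{idx}", tail=start.id, head=end.id, length=length,
            radius=radius, resistance=resistance,
            category="intranidal-plexiform", vclass="plexiform",
            compartment=s_c, column=s_j))
    return vessels


def route_fistula(rng: np.random.Generator,
                  architecture: NidusArchitecture,
                  config: SimulationConfig | None = None) -> list[Vessel]:
    """Route the intranidal fistula: AF2 -> one node per column of the middle
    compartment -> DV2, on larger-radius vessels (K+1 vessels in total)."""
    config = config or SimulationConfig()
    c, k = architecture.n_compartments, architecture.n_columns
    mid = math.ceil(c / 2)
    cells = architecture.cell_nodes()
    length, radius = config.dimensions("fistula")
    resistance = vessel_resistance(length, radius, config.viscosity)
    path_nodes = [cells[(mid, j)][int(rng.integers(len(cells[(mid, j)])))]
                  for j in range(1, k + 1)]
    hops = (["AF2t"] + [n.id for n in path_nodes] + ["DV2t"])
    vessels = []
    for j in range(k + 1):
        vessels.append(Vessel(
            id=f"F{j}", tail=hops[j], head=hops[j + 1], length=length,
            radius=radius, resistance=resistance,
            category="intranidal-fistula", vclass="fistula",
            compartment=mid, column=min(j + 1, k)))
    return vessels


def attach_boundaries(architecture: NidusArchitecture) -> dict[str, str]:
    """Attach every first-column node to its nearest AF terminal and every
    last-column node to its nearest DV terminal (Euclidean distance on the
    layout; ties break to the lower-index terminal).  A terminal left with no
    attachment — possible only for a peripheral feeder such as AF4 — is
    connected to the nearest intranidal node via ``extra_attachments``.
    """
    k = architecture.n_columns
    attachments: dict[str, str] = {}
    used: dict[str, int] = {}

    for side, coords in (("AF", architecture.af_coordinates()),
                         ("DV", architecture.dv_coordinates())):
        terminals = sorted(coords)  # AF1t..AF4t / DV1t..DV3t
        txy = np.array([coords[t] for t in terminals])
        col = 1 if side == "AF" else k
        for node in architecture.nodes:
            if node.column != col:
                continue
            d2 = (txy[:, 0] - node.x) ** 2 + (txy[:, 1] - node.y) ** 2
            t = terminals[int(np.argmin(d2))]
            attachments[node.id] = t
            used[t] = used.get(t, 0) + 1

    # fistula endpoints keep AF2/DV2 connected even without attachments
    used["AF2t"] = used.get("AF2t", 0) + 1
    used["DV2t"] = used.get("DV2t", 0) + 1

    extra: list[tuple[str, str]] = []
    all_coords = {**architecture.af_coordinates(),
                  **architecture.dv_coordinates()}
    nxy = np.array([(n.x, n.y) for n in architecture.nodes])
    for t, (tx, ty) in all_coords.items():
        if used.get(t, 0) == 0:
            d2 = (nxy[:, 0] - tx) ** 2 + (nxy[:, 1] - ty) ** 2
            extra.append((t, architecture.nodes[int(np.argmin(d2))].id))

    architecture.boundary_attachments = attachments
    architecture.extra_attachments = extra
    return attachments


def sample_architecture(seed: int,
                        config: SimulationConfig | None = None
                        ) -> NidusArchitecture:
    """Generate one nidus architecture, deterministically for a fixed seed."""
    config = config or SimulationConfig()
    p = config.nidus
    rng = np.random.default_rng(seed)

    c = sample_truncated_normal_integer(
        rng, p.compartments_mean, p.compartments_sd, *p.compartments_bounds)
    k = sample_truncated_normal_integer(
        rng, p.columns_mean, p.columns_sd, *p.columns_bounds)
    arch = NidusArchitecture(n_compartments=c, n_columns=k, seed=seed)

    # --- nodes per (compartment, column) cell -----------------------------
    counts = np.zeros((c + 1, k + 1), dtype=int)  # 1-based
    for j in range(1, k + 1):
        lo, hi = (p.end_column_nodes if j in (1, k)
                  else p.interior_column_nodes)
        if p.counts_per_compartment:
            for ci in range(1, c + 1):
                counts[ci, j] = int(rng.integers(lo, hi + 1))
        else:
            total = int(rng.integers(lo, hi + 1))
            base, rem = divmod(total, c)
            counts[1:, j] = base
            bump = rng.permutation(c)[:rem]
            for b in bump:
                counts[b + 1, j] += 1

    cells: dict[tuple[int, int], list[Node]] = {}
    for ci in range(1, c + 1):
        for j in range(1, k + 1):
            n_cj = counts[ci, j]
            cell = []
            for i in range(n_cj):
                node = Node(
                    id=f"N{ci}_{j}_{i}", role="junction",
                    x=float(j), y=(ci - 1) + (i + 0.5) / n_cj,
                    compartment=ci, column=j)
                cell.append(node)
                arch.nodes.append(node)
            cells[(ci, j)] = cell

    # --- intracompartmental vessels ---------------------------------------
    length, radius, resistance = _plexiform_proto(config)
    vid = 0

    def plex(tail: Node, head: Node) -> None:
        nonlocal vid
        arch.vessels.append(Vessel(
            id=f"P{vid}", tail=tail.id, head=head.id, length=length,
            radius=radius, resistance=resistance,
            category="intranidal-plexiform", vclass="plexiform",
            compartment=tail.compartment, column=tail.column))
        vid += 1

    has_out: dict[str, bool] = {}
    # one incoming vessel per node (from the previous column, same compartment)
    for ci in range(1, c + 1):
        for j in range(2, k + 1):
            prev = cells[(ci, j - 1)]
            tails = rng.integers(0, len(prev), size=len(cells[(ci, j)]))
            for t, node in zip(tails, cells[(ci, j)]):
                plex(prev[int(t)], node)
                has_out[prev[int(t)].id] = True
    # one outgoing vessel for any node still lacking one
    for ci in range(1, c + 1):
        for j in range(1, k):
            nxt = cells[(ci, j + 1)]
            for node in cells[(ci, j)]:
                if not has_out.get(node.id):
                    plex(node, nxt[int(rng.integers(len(nxt)))])
                    has_out[node.id] = True

    arch.vessels.extend(
        generate_intercompartmental_vessels(rng, arch, config))
    fistula = route_fistula(rng, arch, config)
    arch.vessels.extend(fistula)
    arch.fistula_path = [v.id for v in fistula]

    attach_boundaries(arch)
    return arch
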