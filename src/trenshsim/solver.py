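"""Steady-state flow solution of a vessel network under one or many pressure
sets.

The solver assembles a sparse nodal-potential (grounded Laplacian) system in
CGS units: the aortic root is pinned to the set's systemic pressure (ESP) and
the vena-cava outlet to its CVP (ECVP, which is also the absolute-pressure
reference); the AF/DV EMFs act as ideal sources in series with their vessels.
One LU factorization is shared by all pressure sets of a topology (sets that
remove the same TBO edge), solved with a blocked right-hand side; topologies
differing by edge removal are factorized separately.

Kirchhoff consistency is verifiable post hoc with
:func:`kirchhoff_residuals`, which evaluates node conservation and the cycle
equation  sum(EMF_i) = sum(R_vj * Q_j)  over a computed cycle basis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .errors import (ConsistencyError, NumericError, ParameterError,
                     SingularSystemError)
from .network import VesselNetwork
from .scenarios import PressureSet
from .units import CM3S_TO_ML_MIN, MMHG

#: |Q| below this (cm^3/s) is treated as zero for direction-dependent logic
ZERO_FLOW = 1e-12


@dataclass
class FlowSolution:
    """Per-vessel signed flow and per-node absolute pressure for one set.

    Flows are in cm^3/s, positive along the vessel's nominal (tail->head)
    orientation; node pressures and pressure drops are in mmHg.  Arrays are
    indexed in the network's compiled vessel/node order.
    """

    network: VesselNetwork
    pressure_set: PressureSet
    q: np.ndarray        # cm^3/s, per vessel
    node_p: np.ndarray   # mmHg, per node

    @property
    def vessel_flow(self) -> dict[str, float]:
        ids = self.network.compiled()["vessel_ids"]
        return dict(zip(ids, self.q))

    @property
    def vessel_dp(self) -> dict[str, float]:
        """Poiseuille pressure drop R_v * Q per vessel, mmHg."""
        c = self.network.compiled()
        return dict(zip(c["vessel_ids"], self.dp_array()))

    def dp_array(self) -> np.ndarray:
        return self.network.compiled()["resistance"] * self.q / MMHG

    def flow(self, vessel_id: str) -> float:
        c = self.network.compiled()
        return float(self.q[c["vessel_index"][vessel_id]])

    def pressure(self, node_id: str) -> float:
        c = self.network.compiled()
        return float(self.node_p[c["node_index"][node_id]])

    def removed_vessels(self) -> frozenset:
        return frozenset([self.pressure_set.tbo]
                         if self.pressure_set.tbo else [])

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-vessel table (flow in mL/min, drop in mmHg)."""
        c = self.network.compiled()
        return pd.DataFrame({
            "vessel_id": c["vessel_ids"],
            "flow_ml_min": self.q * CM3S_TO_ML_MIN,
            "dp_mmHg": self.dp_array(),
        })


def _series_emf_matrix(network: VesselNetwork) -> tuple[np.ndarray, list]:
    """Map the ordered EMF list onto per-edge series sources.

    Returns (edge_index, signed column) pairs for the seven series EMFs
    (EAF1..4, EDV1..3); ESP/ECVP are realized as pinned boundary pressures.
    """
    c = network.compiled()
    entries = []
    for emf in network.emfs.values():
        if emf.id in ("ESP", "ECVP"):
            continue
        entries.append((c["vessel_index"][emf.attached_edge], emf.id,
                        emf.polarity))
    return entries


class _Topology:
    """Assembled system for one (network, removed-edges) topology."""

    def __init__(self, network: VesselNetwork, removed: frozenset):
        c = network.compiled()
        n_nodes = len(c["node_ids"])
        w = len(c["vessel_ids"])
        active = np.ones(w, dtype=bool)
        for vid in removed:
            if vid not in c["vessel_index"]:
                raise ParameterError(f"cannot occlude unknown vessel {vid!r}")
            active[c["vessel_index"][vid]] = False

        # an AF/DV terminal touching only its own feeder/vein is a dead end:
        # the AVM circuit is open until a nidus is attached
        degree: dict[str, int] = {}
        for v in network.vessels.values():
            degree[v.tail] = degree.get(v.tail, 0) + 1
            degree[v.head] = degree.get(v.head, 0) + 1
        dangling = [n.id for n in network.nodes.values()
                    if n.role in ("AF-terminal", "DV-terminal")
                    and degree.get(n.id, 0) < 2]
        if dangling:
            raise SingularSystemError(
                "open circuit: dangling terminals "
                f"{sorted(dangling)} — no nidus attached")

        esp_edge = network.emfs["ESP"].attached_edge
        cvp_edge = network.emfs["ECVP"].attached_edge
        i_esp = c["tail"][c["vessel_index"][esp_edge]]
        i_cvp = c["head"][c["vessel_index"][cvp_edge]]

        tail, head = c["tail"][active], c["head"][active]
        g = 1.0 / c["resistance"][active]

        adj = sp.coo_matrix(
            (np.ones(tail.size), (tail, head)), shape=(n_nodes, n_nodes))
        n_comp, labels = connected_components(adj, directed=False)
        if labels[i_esp] != labels[i_cvp]:
            raise SingularSystemError(
                "open circuit: no path between the systemic (ESP) and venous "
                f"(ECVP) terminals{' after occluding ' + ', '.join(sorted(removed)) if removed else ''}")
        if not np.all(labels == labels[i_esp]):
            raise SingularSystemError(
                "network contains components disconnected from the pressure "
                "sources")

        unknown = np.ones(n_nodes, dtype=bool)
        unknown[[i_esp, i_cvp]] = False
        u_index = np.cumsum(unknown) - 1  # position among unknowns

        rows, cols, vals = [], [], []
        b_esp = np.zeros(n_nodes)
        b_cvp = np.zeros(n_nodes)
        for a, b_ in ((tail, head), (head, tail)):
            # diagonal and off-diagonal Laplacian entries at nodes `a`
            rows.append(a)
            cols.append(a)
            vals.append(g)
            rows.append(a)
            cols.append(b_)
            vals.append(-g)
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        # pinned columns move to the RHS
        pin_esp = cols == i_esp
        pin_cvp = cols == i_cvp
        np.add.at(b_esp, rows[pin_esp], -vals[pin_esp])
        np.add.at(b_cvp, rows[pin_cvp], -vals[pin_cvp])
        keep = unknown[rows] & unknown[cols]
        n_unk = int(unknown.sum())
        lap = sp.coo_matrix(
            (vals[keep], (u_index[rows[keep]], u_index[cols[keep]])),
            shape=(n_unk, n_unk)).tocsc()

        # series-EMF RHS map: b[tail] -= g*E, b[head] += g*E
        emf_entries = _series_emf_matrix(network)
        m_rows, m_cols, m_vals = [], [], []
        emf_ids = []
        for col_idx, (e_idx, emf_id, pol) in enumerate(emf_entries):
            emf_ids.append((emf_id, pol))
            if not active[e_idx]:
                continue
            ge = 1.0 / c["resistance"][e_idx]
            for node, sign in ((c["tail"][e_idx], -ge), (c["head"][e_idx],
                                                         +ge)):
                if unknown[node]:
                    m_rows.append(u_index[node])
                    m_cols.append(col_idx)
                    m_vals.append(sign)
        m_emf = sp.coo_matrix(
            (m_vals, (m_rows, m_cols)), shape=(n_unk, len(emf_entries))
        ).tocsr()

        try:
            self.lu = splu(lap)
        except RuntimeError as exc:  # pragma: no cover - guarded above
            raise SingularSystemError(str(exc)) from exc
        self.network = network
        self.removed = removed
        self.active = active
        self.unknown = unknown
        self.u_index = u_index
        self.i_esp, self.i_cvp = int(i_esp), int(i_cvp)
        self.b_esp = b_esp[unknown]
        self.b_cvp = b_cvp[unknown]
        self.m_emf = m_emf
        self.emf_ids = emf_ids
        self.edge_emf = emf_entries

    def solve_sets(self, sets: Sequence[PressureSet]) -> list[FlowSolution]:
        c = self.network.compiled()
        n_sets = len(sets)
        esp = np.array([s.emf_values["ESP"] for s in sets]) * MMHG
        cvp = np.array([s.emf_values["ECVP"] for s in sets]) * MMHG
        series = np.array([[s.emf_values[emf_id] * pol
                            for emf_id, pol in self.emf_ids]
                           for s in sets]).T * MMHG  # (7, n)
        rhs = (np.outer(self.b_esp, esp) + np.outer(self.b_cvp, cvp)
               + self.m_emf @ series)
        p_unknown = self.lu.solve(rhs)
        if not np.all(np.isfinite(p_unknown)):
            raise NumericError("flow solve produced non-finite pressures")

        n_nodes = self.unknown.size
        p_full = np.empty((n_nodes, n_sets))
        p_full[self.unknown] = p_unknown
        p_full[self.i_esp] = esp
        p_full[self.i_cvp] = cvp

        # per-edge series EMF values (CGS) for each set
        w = len(c["vessel_ids"])
        e_edge = np.zeros((w, n_sets))
        for col_idx, (e_idx, _, _) in enumerate(self.edge_emf):
            e_edge[e_idx] += series[col_idx]

        g = np.where(self.active, 1.0 / c["resistance"], 0.0)
        dp = p_full[c["tail"]] - p_full[c["head"]] + e_edge
        q = g[:, None] * dp

        out = []
        for j, pset in enumerate(sets):
            out.append(FlowSolution(network=self.network, pressure_set=pset,
                                    q=q[:, j], node_p=p_full[:, j] / MMHG))
        return out


def solve(network: VesselNetwork,
          sets: Sequence[PressureSet] | PressureSet) -> list[FlowSolution]:
    """Solve the network for one or many pressure sets.

    Sets sharing a TBO topology share one factorization and are solved with a
    blocked right-hand side; the result order matches the input order.
    """
    if isinstance(sets, PressureSet):
        sets = [sets]
    groups: dict[frozenset, list[int]] = {}
    for i, s in enumerate(sets):
        groups.setdefault(frozenset([s.tbo] if s.tbo else []), []).append(i)
    out: list[Optional[FlowSolution]] = [None] * len(sets)
    for removed, idxs in groups.items():
        topo = _Topology(network, removed)
        for i, sol in zip(idxs, topo.solve_sets([sets[i] for i in idxs])):
            out[i] = sol
    return out  # type: ignore[return-value]


def node_pressures(solution: FlowSolution) -> dict[str, float]:
    """Absolute node pressures (mmHg), anchored at the ECVP terminal."""
    c = solution.network.compiled()
    return dict(zip(c["node_ids"], solution.node_p))


def total_nidal_flow(solution: FlowSolution) -> float:
    """Total volumetric flow entering the nidus across the AF boundary,
    in mL/min.  By conservation this equals the DV-boundary outflow."""
    net = solution.network
    if net.nidus is None:
        raise ConsistencyError("network has no nidus attached")
    idx = net.compiled()["vessel_index"]
    q_in = sum(solution.q[idx[v]] for v in net.boundary_in_vessel_ids())
    return float(q_in * CM3S_TO_ML_MIN)


def boundary_outflow(solution: FlowSolution) -> float:
    """Total DV-boundary outflow in mL/min (conservation counterpart)."""
    net = solution.network
    idx = net.compiled()["vessel_index"]
    q_out = sum(solution.q[idx[v]] for v in net.boundary_out_vessel_ids())
    return float(q_out * CM3S_TO_ML_MIN)


@dataclass
class KirchhoffResiduals:
    """Post-hoc Kirchhoff-consistency report."""

    max_node_residual: float   # cm^3/s, relative to max(|Q|, 1)
    max_cycle_residual: float  # mmHg
    n_cycles: int


def kirchhoff_residuals(solution: FlowSolution) -> KirchhoffResiduals:
    """Verify both Kirchhoff laws on a computed cycle basis.

    Node residual: net flow imbalance at every non-terminal node, scaled by
    max(|Q|, 1).  Cycle residual: | sum(R_v Q - EMF) | accumulated around
    each cycle of a cycle basis of the active graph (parallel edges
    contribute explicit two-edge cycles).
    """
    net = solution.network
    c = net.compiled()
    removed = solution.removed_vessels()
    active = [v for v in net.vessels.values() if v.id not in removed]
    idx = c["vessel_index"]
    qs = solution.q

    # --- node conservation ------------------------------------------------
    balance: dict[str, float] = {nid: 0.0 for nid in net.nodes}
    for v in active:
        balance[v.tail] -= qs[idx[v.id]]
        balance[v.head] += qs[idx[v.id]]
    scale = max(float(np.max(np.abs(qs))), 1.0)
    pinned = {net.vessels[net.emfs["ESP"].attached_edge].tail,
              net.vessels[net.emfs["ECVP"].attached_edge].head}
    node_res = max((abs(b) for nid, b in balance.items()
                    if nid not in pinned), default=0.0) / scale

    # --- cycle law --------------------------------------------------------
    def drop_minus_emf(v) -> float:  # mmHg, tail->head
        e = solution.pressure_set.emf_values
        series = 0.0
        for emf in net.emfs.values():
            if emf.id in ("ESP", "ECVP") or emf.attached_edge != v.id:
                continue
            series += emf.polarity * e[emf.id]
        return v.resistance * qs[idx[v.id]] / MMHG - series

    rep: dict[tuple[str, str], object] = {}
    parallel_pairs = []
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    for v in active:
        key = tuple(sorted((v.tail, v.head)))
        if key in rep:
            parallel_pairs.append((rep[key], v))
        else:
            rep[key] = v
            g.add_edge(*key)

    max_cycle = 0.0
    n_cycles = 0
    for cycle in nx.cycle_basis(g):
        total = 0.0
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            v = rep[tuple(sorted((a, b)))]
            sign = 1.0 if (v.tail, v.head) == (a, b) else -1.0
            total += sign * drop_minus_emf(v)
        max_cycle = max(max_cycle, abs(total))
        n_cycles += 1
    for v1, v2 in parallel_pairs:
        sign = 1.0 if (v1.tail, v1.head) == (v2.tail, v2.head) else -1.0
        total = drop_minus_emf(v2) - sign * drop_minus_emf(v1)
        max_cycle = max(max_cycle, abs(total))
        n_cycles += 1

    return KirchhoffResiduals(max_node_residual=node_res,
                              max_cycle_residual=max_cycle,
                              n_cycles=n_cycles)
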