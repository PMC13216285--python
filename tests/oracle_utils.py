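"""Independent oracles used by the test suite.

These deliberately avoid the package's solver/reachability code paths: the
flow oracle assembles the m x w flow-variable system (one conservation row
per node, one voltage row per basis cycle, plus source-path rows) and solves
it densely by least squares; the filling oracle enumerates directed paths
with networkx on a graph rebuilt from scratch.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

MMHG = 1333.22


def dense_flow_oracle(network, pressure_set):
    """Solve a network with the dense flow-variable (KCL+KVL) formulation.

    Returns a dict vessel id -> flow (cm^3/s).  Only supports networks
    without parallel edges and without TBO removal.
    """
    vessels = list(network.vessels.values())
    vid_index = {v.id: j for j, v in enumerate(vessels)}
    w = len(vessels)

    emf_on = {}
    for emf in network.emfs.values():
        if emf.id in ("ESP", "ECVP"):
            continue
        val = pressure_set.emf_values[emf.id] * emf.polarity * MMHG
        emf_on[emf.attached_edge] = emf_on.get(emf.attached_edge, 0.0) + val

    esp_edge = network.emfs["ESP"].attached_edge
    cvp_edge = network.emfs["ECVP"].attached_edge
    pin_a = network.vessels[esp_edge].tail
    pin_b = network.vessels[cvp_edge].head
    p_a = pressure_set.emf_values["ESP"] * MMHG
    p_b = pressure_set.emf_values["ECVP"] * MMHG

    rows, rhs = [], []
    # KCL at every non-pinned node
    for node in network.nodes.values():
        if node.id in (pin_a, pin_b):
            continue
        row = np.zeros(w)
        for v in vessels:
            if v.tail == node.id:
                row[vid_index[v.id]] -= 1.0
            if v.head == node.id:
                row[vid_index[v.id]] += 1.0
        rows.append(row)
        rhs.append(0.0)

    g = nx.Graph()
    for v in vessels:
        g.add_edge(v.tail, v.head, vid=v.id)

    def edge_between(a, b):
        return network.vessels[g.edges[a, b]["vid"]]

    # KVL around each basis cycle: sum +-(R q - E) = 0
    for cycle in nx.cycle_basis(g):
        row = np.zeros(w)
        total_e = 0.0
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            v = edge_between(a, b)
            sign = 1.0 if (v.tail, v.head) == (a, b) else -1.0
            row[vid_index[v.id]] += sign * v.resistance
            total_e += sign * emf_on.get(v.id, 0.0)
        rows.append(row)
        rhs.append(total_e)

    # source-path row: along one path pin_a -> pin_b,
    # sum +-(R q - E) = P_a - P_b
    path = nx.shortest_path(g, pin_a, pin_b)
    row = np.zeros(w)
    total_e = 0.0
    for a, b in zip(path, path[1:]):
        v = edge_between(a, b)
        sign = 1.0 if (v.tail, v.head) == (a, b) else -1.0
        row[vid_index[v.id]] += sign * v.resistance
        total_e += sign * emf_on.get(v.id, 0.0)
    rows.append(row)
    rhs.append(p_a - p_b + total_e)

    a_mat = np.vstack(rows)
    b_vec = np.asarray(rhs)
    q, *_ = np.linalg.lstsq(a_mat, b_vec, rcond=None)
    return {v.id: q[vid_index[v.id]] for v in vessels}


def _oriented_edges(network, solution, edges, zero=1e-12):
    out = []
    for vid in edges:
        v = network.vessels[vid]
        q = solution.flow(vid)
        if q > zero:
            out.append((v.tail, v.head, vid))
        elif q < -zero:
            out.append((v.head, v.tail, vid))
    return out


def filling_oracle(network, solution, injection_site, zero=1e-12):
    """Exhaustive-path ingress oracle: a vessel is filled iff a directed path
    exists from the injection junction to its flow-origin node, along
    flow-oriented intranidal vessels, the injected DV's branches, and open
    feeder stumps (feeder retrograde or occluded)."""
    terminal = f"{injection_site}t"
    removed = solution.removed_vessels()
    open_afs = set()
    for i in range(1, 5):
        if f"AF{i}" in removed or solution.flow(f"AF{i}") < -zero:
            open_afs.add(f"AF{i}t")
    allowed = []
    for v in network.vessels.values():
        if v.id in removed:
            continue
        if v.is_intranidal:
            allowed.append(v.id)
        elif v.vclass == "dv-branch" and v.head == terminal:
            allowed.append(v.id)
        elif v.vclass == "af-branch" and v.tail in open_afs:
            allowed.append(v.id)
    g = nx.DiGraph()
    g.add_nodes_from(network.nodes)
    g.add_edges_from((a, b) for a, b, _ in
                     _oriented_edges(network, solution, allowed, zero))
    filled = set()
    for v in network.vessels.values():
        if not v.is_intranidal:
            continue
        q = solution.flow(v.id)
        if abs(q) <= zero:
            continue
        origin = v.tail if q > 0 else v.head
        if origin == terminal or nx.has_path(g, terminal, origin):
            filled.add(v.id)
    return filled


def egress_oracle(network, baseline_solution, ingress_ids, zero=1e-12):
    """Brute-force fixed-point iteration of the antegrade closure rule."""
    oriented = {}
    for v in network.vessels.values():
        if not v.is_intranidal or v.id in baseline_solution.removed_vessels():
            continue
        q = baseline_solution.flow(v.id)
        if abs(q) <= zero:
            continue
        origin, dest = (v.tail, v.head) if q > 0 else (v.head, v.tail)
        oriented[v.id] = (origin, dest)
    filled = set(ingress_ids)
    while True:
        heads = {oriented[vid][1] for vid in filled if vid in oriented}
        added = {vid for vid, (origin, _) in oriented.items()
                 if origin in heads} - filled
        if not added:
            return filled
        filled |= added


def rounded_truncated_normal_pmf(mean, sd, low, high):
    """Exact pmf of a rounded normal draw restricted to [low, high]."""
    from scipy.stats import norm
    ks = np.arange(low, high + 1)
    p = norm.cdf(ks + 0.5, mean, sd) - norm.cdf(ks - 0.5, mean, sd)
    return ks, p / p.sum()
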