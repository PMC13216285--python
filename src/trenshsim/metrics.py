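"""Sclerosant-filling algorithm and rupture-risk statistic.

Filling is purely reachability-based, mirroring the unidirectional nature of
steady-state flow.  During retrograde injection (*ingress* phase) every
vessel is oriented by the sign of its computed flow; an intranidal vessel is
"filled" iff a continuous intranidal path exists, along flow-oriented
vessels, from the injection site's nidus-boundary junction to the vessel's
origin node.  After the injection stops (*egress* phase) flow reverts to the
baseline (no-injection) profile and the filled set is closed antegradely: a
vessel joins the set iff its baseline-flow origin node is the head of a
vessel already in the set, iterated to a fixed point.

The rupture risk of a vessel exposed to a hemodynamic pressure P_exp is

    Risk = ln(P_exp / P_min) / ln(P_max / P_min) * 100%

clamped to [0, 100], with P_min = 4 mmHg (the minimum CVP across the
pressure sets) and P_max = 74 mmHg (the maximal feeder pressure expected
during systemic hypertension).  P_exp is the magnitude of the vessel's
Poiseuille pressure difference R_v * Q (configurable to the mean of the
endpoint node pressures instead).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import breadth_first_order

from .config import RiskParams
from .errors import ConsistencyError, ParameterError
from .nidus import NidusArchitecture
from .scenarios import PressureSet, make_pressure_set
from .solver import ZERO_FLOW, FlowSolution, solve
from .units import MMHG

__all__ = [
    "FilledSet", "ingress_filling", "egress_closure", "percent_filling",
    "rupture_risk", "nidus_risk_summary", "animation_frames", "Frame",
]


@dataclass(frozen=True)
class FilledSet:
    """A set of intranidal vessels reached by the sclerosant."""

    vessels: frozenset
    injection_site: str
    phase_tag: str = "ingress"  # ingress | final
    tbo: Optional[str] = None


def _traversal_cache(network, site: str):
    """Edge arrays of the intranidal traversal graph for one injection site:
    intranidal vessels plus the injected DV's boundary branches."""
    key = ("traversal", site)
    if key not in network._cache:
        c = network.compiled()
        terminal = f"{site}t"
        if terminal not in network.nodes:
            raise ParameterError(f"unknown injection site {site!r}")
        vidx = c["vessel_index"]
        edges, af_edges = [], []
        af_term = []
        for v in network.vessels.values():
            # always traversable: intranidal vessels and the injected DV's
            # boundary branches (the sclerosant's way in).  Other DVs'
            # branches are pure outflow and are never traversable.
            if v.is_intranidal or (v.vclass == "dv-branch"
                                   and v.head == terminal):
                edges.append(vidx[v.id])
            # conditionally traversable: AF boundary branches — sclerosant
            # reaching a feeder stump can spill over and re-enter through the
            # stump's other branchlets, but only while the feeder itself is
            # not flushing the stump with antegrade inflow (its net flow is
            # retrograde, or it is balloon-occluded)
            elif v.vclass == "af-branch":
                af_edges.append(vidx[v.id])
                af_term.append(v.tail)
        network._cache[key] = {
            "edges": np.array(edges, dtype=np.int64),
            "af_edges": np.array(af_edges, dtype=np.int64),
            "af_term": af_term,
            "start": c["node_index"][terminal],
            "n_nodes": len(c["node_ids"]),
        }
    return network._cache[key]


def _intranidal_cache(network):
    key = "intranidal_edges"
    if key not in network._cache:
        c = network.compiled()
        edges = np.flatnonzero(c["intranidal"])
        network._cache[key] = {
            "edges": edges,
            "tail": c["tail"][edges],
            "head": c["head"][edges],
            "ids": np.array(c["vessel_ids"], dtype=object)[edges],
            "n_nodes": len(c["node_ids"]),
        }
    return network._cache[key]


def _reach(n_nodes: int, tails: np.ndarray, heads: np.ndarray,
           starts: np.ndarray) -> np.ndarray:
    """Boolean mask of nodes reachable from ``starts`` along directed edges,
    including the start nodes themselves."""
    reached = np.zeros(n_nodes + 1, dtype=bool)
    if tails.size == 0:
        reached[starts] = True
        return reached[:-1]
    # virtual root (index n_nodes) fans out to all start nodes
    rows = np.concatenate([tails, np.full(starts.size, n_nodes)])
    cols = np.concatenate([heads, starts])
    adj = sp.csr_matrix((np.ones(rows.size, dtype=np.int8), (rows, cols)),
                        shape=(n_nodes + 1, n_nodes + 1))
    order = breadth_first_order(adj, n_nodes, directed=True,
                                return_predecessors=False)
    reached[order] = True
    return reached[:-1]


def ingress_filling(injection_solution: FlowSolution,
                    injection_site: str) -> FilledSet:
    """Filled set during retrograde injection.

    Vessels are oriented by the sign of their computed flow (near-zero flows
    are non-traversable); an intranidal vessel is filled iff its flow-origin
    node is reachable from the injection site's nidus-boundary junction
    along flow-oriented intranidal vessels.
    """
    net = injection_solution.network
    cache = _traversal_cache(net, injection_site)
    c = net.compiled()
    removed = injection_solution.removed_vessels()
    # feeder stumps open to transit: net feeder flow retrograde or occluded
    open_terms = set()
    for i in range(1, 5):
        vid = f"AF{i}"
        if vid in removed or injection_solution.flow(vid) < -ZERO_FLOW:
            open_terms.add(f"AF{i}t")
    af_open = np.array([t in open_terms for t in cache["af_term"]],
                       dtype=bool)
    edges = np.concatenate([cache["edges"], cache["af_edges"][af_open]])
    q = injection_solution.q[edges]
    tail, head = c["tail"][edges], c["head"][edges]
    fwd = q > ZERO_FLOW
    rev = q < -ZERO_FLOW
    tails = np.concatenate([tail[fwd], head[rev]])
    heads = np.concatenate([head[fwd], tail[rev]])
    reached = _reach(cache["n_nodes"], tails, heads,
                     np.array([cache["start"]]))

    nid = _intranidal_cache(net)
    qn = injection_solution.q[nid["edges"]]
    origin = np.where(qn >= 0, nid["tail"], nid["head"])
    filled = (np.abs(qn) > ZERO_FLOW) & reached[origin]
    return FilledSet(vessels=frozenset(nid["ids"][filled]),
                     injection_site=injection_site,
                     phase_tag="ingress",
                     tbo=injection_solution.pressure_set.tbo)


def egress_closure(baseline_solution: FlowSolution,
                   ingress: FilledSet) -> FilledSet:
    """Antegrade fixed-point closure of an ingress set.

    Under the baseline (no-injection) flow orientation, a vessel joins the
    set iff its baseline-flow origin node is the head of some vessel already
    in the set; iterated until nothing more joins.  Idempotent.
    """
    if baseline_solution.pressure_set.tbo != ingress.tbo:
        raise ConsistencyError(
            "baseline solution and ingress set have different TBO states "
            f"({baseline_solution.pressure_set.tbo!r} vs {ingress.tbo!r})")
    net = baseline_solution.network
    nid = _intranidal_cache(net)
    q = baseline_solution.q[nid["edges"]]
    moving = np.abs(q) > ZERO_FLOW
    origin = np.where(q >= 0, nid["tail"], nid["head"])
    dest = np.where(q >= 0, nid["head"], nid["tail"])

    in_ingress = np.isin(nid["ids"], list(ingress.vessels))
    seeds = np.unique(dest[in_ingress & moving])
    if seeds.size == 0:
        return FilledSet(vessels=ingress.vessels,
                         injection_site=ingress.injection_site,
                         phase_tag="final", tbo=ingress.tbo)
    reached = _reach(nid["n_nodes"], origin[moving], dest[moving], seeds)
    joined = moving & reached[origin]
    final = frozenset(nid["ids"][joined]) | ingress.vessels
    return FilledSet(vessels=final, injection_site=ingress.injection_site,
                     phase_tag="final", tbo=ingress.tbo)


def percent_filling(final: FilledSet, nidus: NidusArchitecture) -> float:
    """Percentage of intranidal vessels (fistula included) that are filled."""
    total = nidus.n_vessels
    if total == 0:
        raise ParameterError("nidus has no vessels")
    return 100.0 * len(final.vessels) / total


def rupture_risk(pressure: float, params: RiskParams | None = None) -> float:
    """Normalized rupture-risk percentage for one exposure pressure (mmHg)."""
    params = params or RiskParams()
    if pressure <= 0:
        raise ParameterError("exposure pressure must be positive")
    raw = (math.log(pressure / params.p_min)
           / math.log(params.p_max / params.p_min) * 100.0)
    return min(100.0, max(0.0, raw))


def _risk_vector(solution: FlowSolution,
                 params: RiskParams) -> np.ndarray:
    net = solution.network
    nid = _intranidal_cache(net)
    if params.pexp_mode == "drop":
        c = net.compiled()
        pexp = np.abs(c["resistance"][nid["edges"]]
                      * solution.q[nid["edges"]]) / MMHG
    else:  # endpoint-mean
        pexp = 0.5 * (solution.node_p[nid["tail"]]
                      + solution.node_p[nid["head"]])
    with np.errstate(divide="ignore"):
        raw = (np.log(np.maximum(pexp, 1e-300) / params.p_min)
               / math.log(params.p_max / params.p_min) * 100.0)
    return np.clip(raw, 0.0, 100.0)


def nidus_risk_summary(solution: FlowSolution,
                       nidus: NidusArchitecture | None = None,
                       params: RiskParams | None = None
                       ) -> tuple[float, float]:
    """(mean, max) rupture risk over the intranidal vessels of a solution."""
    params = params or solution.network.config.risk
    risks = _risk_vector(solution, params)
    return float(risks.mean()), float(risks.max())


@dataclass(frozen=True)
class Frame:
    """One animation frame: the colored (filled) vessel set."""

    phase: str  # ingress | exit
    injection_mmhg: float
    filled: frozenset = field(default_factory=frozenset)


def animation_frames(network, scenario: PressureSet,
                     target_injection: float) -> list[Frame]:
    """Frame sequence of one simulated treatment.

    Ingress frames recompute flow and reachability at injection pressures
    0, 1, ..., target (1-mmHg increments).  Exit frames then apply the
    antegrade shift rule under the baseline flow: a vessel is colored iff a
    vessel pointing to its entry node was colored in the previous frame,
    until the coloring empties or repeats.
    """
    if target_injection < 0:
        raise ParameterError("target injection pressure must be >= 0")
    if scenario.injection is None:
        raise ParameterError("scenario must specify an injection site")
    site = scenario.injection[0]
    target = int(round(target_injection))

    config = network.config
    sets = [make_pressure_set(config, scenario.hypotension_level,
                              scenario.cvp_level, scenario.tbo,
                              (site, float(p)) if p > 0 else None,
                              scenario.phase)
            for p in range(target + 1)]
    solutions = solve(network, sets)

    frames = [Frame("ingress", float(p),
                    ingress_filling(sol, site).vessels)
              for p, sol in enumerate(solutions)]

    # exit phase under the baseline (p = 0) orientation
    baseline = solutions[0]
    nid = _intranidal_cache(network)
    q = baseline.q[nid["edges"]]
    moving = np.abs(q) > ZERO_FLOW
    origin = np.where(q >= 0, nid["tail"], nid["head"])
    dest = np.where(q >= 0, nid["head"], nid["tail"])

    colored = frames[-1].filled
    seen = {colored}
    while colored:
        mask = np.isin(nid["ids"], list(colored)) & moving
        entry_nodes = np.unique(dest[mask])
        new_mask = moving & np.isin(origin, entry_nodes)
        new = frozenset(nid["ids"][new_mask])
        if new in seen:
            break
        seen.add(new)
        frames.append(Frame("exit", 0.0, new))
        colored = new
    return frames
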