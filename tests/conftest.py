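import math

import pytest

from trenshsim import (SimulationConfig, VesselNetwork, Vessel, Node,
                       EMFSource, attach_nidus, build_extranidal_template,
                       sample_architecture, vessel_resistance)


@pytest.fixture(scope="session")
def config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def template(config):
    return build_extranidal_template(config)


@pytest.fixture(scope="session")
def small_config():
    """Config producing tiny nidi (tens of vessels) for oracle comparisons."""
    cfg = SimulationConfig()
    cfg.nidus.compartments_bounds = (3, 3)
    cfg.nidus.compartments_mean = 3.0
    cfg.nidus.columns_bounds = (3, 3)
    cfg.nidus.columns_mean = 3.0
    cfg.nidus.end_column_nodes = (2, 3)
    cfg.nidus.interior_column_nodes = (2, 3)
    return cfg


@pytest.fixture(scope="session")
def small_network(small_config):
    arch = sample_architecture(12345, small_config)
    return attach_nidus(build_extranidal_template(small_config), arch)


@pytest.fixture(scope="session")
def network(config, template):
    """One full-size model (template + generated nidus)."""
    return attach_nidus(template, sample_architecture(2024, config))


def make_toy_network(edges, resistances, esp_edge, ecvp_edge,
                     series_emfs=(), viscosity=0.035):
    """A hand-built circuit for solver tests.

    ``edges``: list of (vid, tail, head); resistances are imposed directly
    (geometry back-computed).  The tail of ``esp_edge`` and the head of
    ``ecvp_edge`` become the pinned terminals.
    """
    cfg = SimulationConfig()
    net = VesselNetwork(cfg)
    nodes = {n for _, t, h in edges for n in (t, h)}
    pin_a = next(t for vid, t, h in edges if vid == esp_edge)
    pin_b = next(h for vid, t, h in edges if vid == ecvp_edge)
    for n in sorted(nodes):
        role = "source-terminal" if n in (pin_a, pin_b) else "junction"
        net.add_node(Node(n, role))
    for (vid, tail, head), r_val in zip(edges, resistances):
        length = 1.0
        radius = (8 * length * viscosity / (math.pi * r_val)) ** 0.25
        net.add_vessel(Vessel(
            id=vid, tail=tail, head=head, length=length, radius=radius,
            resistance=vessel_resistance(length, radius, viscosity),
            category="extranidal-artery", vclass="aortic-arch"))
    net.emfs["ESP"] = EMFSource("ESP", esp_edge)
    net.emfs["ECVP"] = EMFSource("ECVP", ecvp_edge)
    for emf_id, edge, polarity in series_emfs:
        net.emfs[emf_id] = EMFSource(emf_id, edge, polarity=polarity)
    return net


def toy_pressure_set(esp, ecvp=0.0, **series):
    from trenshsim import PressureSet
    from trenshsim.network import EMF_IDS
    emfs = {e: 0.0 for e in EMF_IDS}
    emfs["ESP"] = esp
    emfs["ECVP"] = ecvp
    emfs.update(series)
    return PressureSet(emf_values=emfs)
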