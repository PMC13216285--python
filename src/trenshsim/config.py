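"""Simulation configuration: viscosity, vessel dimension table, EMF values,
nidus generator parameters, and rupture-risk parameters.

The default vessel-dimension table follows the extranidal architecture of the
classical electrical-network AVM models (aortic arch feeding carotid /
subclavian / vertebral trunks and cerebral arteries, four arterial feeders of
which AF1/AF2 are major low-resistance and AF3/AF4 minor high-resistance,
three draining veins into a dural sinus and vena cava).  Dimensions were
calibrated once so that the baseline state of the stochastic model reproduces
the published physiologic anchors of that model family: a mean nidal entry
pressure near 47 mmHg, exit pressure near 17 mmHg, and a mean total nidal
flow near 367 mL/min at systemic normotension.  Every value can be overridden
via :class:`SimulationConfig` or a YAML config file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

from .errors import ConfigurationError, InvalidGeometryError

#: Vessel classes that the extranidal template requires, in build order.
EXTRANIDAL_CLASSES = (
    "aortic-arch",
    "common-carotid",
    "subclavian",
    "internal-carotid",
    "external-carotid",
    "vertebral",
    "mca",
    "aca",
    "pca",
    "transosseous-feeder",
    "cerebral-runoff",
    "af1",
    "af2",
    "af3",
    "af4",
    "dv1",
    "dv2",
    "dv3",
    "dural-sinus",
    "vena-cava",
)

#: Classes used when attaching a nidus to the template.
NIDAL_CLASSES = ("af-branch", "dv-branch", "plexiform", "fistula")

# (length cm, radius cm) per vessel class.  Trunk vessels use textbook-scale
# dimensions; feeder, draining-vein and intranidal radii are the calibrated
# values discussed in docs/methods.md.
DEFAULT_DIMENSIONS: dict[str, tuple[float, float]] = {
    "aortic-arch": (7.0, 1.0),
    "common-carotid": (15.0, 0.40),
    "subclavian": (10.0, 0.40),
    "internal-carotid": (15.0, 0.30),
    "external-carotid": (12.0, 0.25),
    "vertebral": (20.0, 0.20),
    "mca": (8.0, 0.1485),
    "aca": (8.0, 0.140),
    "pca": (8.0, 0.145),
    "transosseous-feeder": (6.0, 0.120),
    # lumped normal (capillary) runoff of each cerebral arterial territory,
    # returning to the systemic veins; together with the trunk resistances it
    # sets the perfusion-pressure divider at the feeder origins, i.e. the
    # stall pressure a retrograde injection must overcome to reverse a feeder
    "cerebral-runoff": (2.0, 0.087),
    # arterial feeders: AF2 strongest, AF1 second, AF3/AF4 minor
    "af1": (4.0, 0.120),
    "af2": (4.0, 0.135),
    "af3": (5.0, 0.090),
    "af4": (5.0, 0.080),
    # draining veins
    "dv1": (5.0, 0.113),
    "dv2": (5.0, 0.120),
    "dv3": (4.0, 0.094),
    "dural-sinus": (6.0, 0.20),
    "vena-cava": (10.0, 0.40),
    # nidus boundary branches and intranidal vessels; the dv-branch pedicles
    # carry most of the nidus-to-vein pressure drop (intranidal hypertension)
    "af-branch": (0.30, 0.030),
    "dv-branch": (0.30, 0.0130),
    "plexiform": (0.50, 0.032),
    "fistula": (0.50, 0.045),
}

#: Mean systemic arterial pressure (mmHg) per hypotension level.
HYPOTENSION_MMHG: dict[str, float] = {
    "normo": 74.0,
    "mild": 70.0,
    "moderate": 50.0,
    "profound": 25.0,
}

#: Central venous pressure (mmHg) per CVP level.
CVP_MMHG: dict[str, float] = {
    "normal": 6.0,
    "high": 12.0,
}


@dataclass
class RiskParams:
    """Parameters of the normalized rupture-risk statistic.

    ``p_min`` (mmHg) anchors zero risk (the minimum CVP across the pressure
    sets) and ``p_max`` (mmHg) anchors 100% risk (the maximal feeder pressure
    expected during systemic hypertension).  ``pexp_mode`` selects how the
    per-vessel exposure pressure is measured: ``"drop"`` uses the magnitude of
    the hemodynamic pressure difference R_v*Q across the vessel (the default),
    ``"endpoint-mean"`` uses the mean of the two endpoint node pressures.
    """

    p_min: float = 4.0
    p_max: float = 74.0
    pexp_mode: str = "drop"

    def __post_init__(self) -> None:
        if not (0.0 < self.p_min < self.p_max):
            raise ConfigurationError("risk params require 0 < p_min < p_max")
        if self.pexp_mode not in ("drop", "endpoint-mean"):
            raise ConfigurationError(f"unknown pexp_mode {self.pexp_mode!r}")


@dataclass
class NidusParams:
    """Parameters of the stochastic compartment/column nidus generator."""

    compartments_mean: float = 4.5
    compartments_sd: float = 1.0
    compartments_bounds: tuple[int, int] = (3, 6)
    columns_mean: float = 5.0
    columns_sd: float = 1.0
    columns_bounds: tuple[int, int] = (3, 7)
    #: inclusive node-count range for end columns (adjacent to AFs/DVs)
    end_column_nodes: tuple[int, int] = (30, 34)
    #: inclusive node-count range for interior columns
    interior_column_nodes: tuple[int, int] = (36, 40)
    #: standard deviation of the intercompartmental end-column draw
    intercompartmental_column_sd: float = 2.0
    #: draw node counts per (compartment, column) cell; if False, counts are
    #: column totals partitioned across compartments
    counts_per_compartment: bool = True


@dataclass
class ScenarioParams:
    """Pressure-set construction parameters."""

    hypotension_mmhg: dict[str, float] = field(
        default_factory=lambda: dict(HYPOTENSION_MMHG))
    cvp_mmhg: dict[str, float] = field(default_factory=lambda: dict(CVP_MMHG))
    injection_pressures: tuple[float, ...] = (10.0, 20.0, 30.0)
    #: baseline value of the three DV EMFs (venous outflow pressure head);
    #: a retrograde injection adds its pressure on top of this
    venous_emf_mmhg: float = 0.0
    #: fractional arterial EMF offset for the cardiac phases
    #: (diastole = -offset, intermediate = 0, systole = +offset)
    phase_offset_frac: float = 0.10


@dataclass
class SimulationConfig:
    """Complete configuration of the simulator."""

    viscosity: float = 0.035  # poise (3.5 cP)
    vessel_dimensions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DIMENSIONS))
    scenario: ScenarioParams = field(default_factory=ScenarioParams)
    nidus: NidusParams = field(default_factory=NidusParams)
    risk: RiskParams = field(default_factory=RiskParams)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.viscosity <= 0:
            raise InvalidGeometryError("viscosity must be positive")

    def dimensions(self, vclass: str) -> tuple[float, float]:
        """Return (length, radius) for a vessel class, or raise naming it."""
        try:
            length, radius = self.vessel_dimensions[vclass]
        except KeyError:
            raise ConfigurationError(
                f"no vessel dimensions configured for class {vclass!r}"
            ) from None
        if length <= 0 or radius <= 0:
            raise InvalidGeometryError(
                f"vessel class {vclass!r} has non-positive dimensions")
        return float(length), float(radius)

    # -- YAML round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["vessel_dimensions"] = {
            k: list(v) for k, v in self.vessel_dimensions.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "vessel_dimensions" in d:
            d["vessel_dimensions"] = {
                k: tuple(v) for k, v in d["vessel_dimensions"].items()}
        for key, sub in (("scenario", ScenarioParams), ("nidus", NidusParams),
                         ("risk", RiskParams)):
            if key in d and isinstance(d[key], Mapping):
                sub_d = dict(d[key])
                for tup_key in ("compartments_bounds", "columns_bounds",
                                "end_column_nodes", "interior_column_nodes",
                                "injection_pressures"):
                    if tup_key in sub_d:
                        sub_d[tup_key] = tuple(sub_d[tup_key])
                d[key] = sub(**sub_d)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
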