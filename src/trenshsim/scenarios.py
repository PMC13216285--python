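"""Enumeration of pressure-set grids.

A pressure set assigns a value (mmHg) to each of the nine EMFs plus scenario
metadata: systemic hypotension level (normo/mild/moderate/profound at
74/70/50/25 mmHg), CVP level (normal 6 / high 12 mmHg), temporary balloon
occlusion (TBO) of one arterial feeder (pure edge removal, never an EMF
change), a retrograde draining-vein injection (added to that DV's EMF only),
and a cardiac phase (diastole / intermediate / systole, an arterial EMF
offset with intermediate = the mean, i.e. zero offset).

The standard grid holds 320 sets per architecture: 32 without injection
(4 hypotension x 2 CVP x 4 TBO) and 288 with injection (x 3 DV sites x 3
injection pressures of 10/20/30 mmHg).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .config import SimulationConfig
from .errors import ConfigurationError, ParameterError
from .network import EMF_IDS

HYPOTENSION_LEVELS = ("normo", "mild", "moderate", "profound")
CVP_LEVELS = ("normal", "high")
TBO_STATES = (None, "AF1", "AF2", "AF3")
PHASES = ("diastole", "intermediate", "systole")
INJECTION_SITES = ("DV1", "DV2", "DV3")

_PHASE_SIGN = {"diastole": -1.0, "intermediate": 0.0, "systole": +1.0}


@dataclass(frozen=True)
class PressureSet:
    """One scenario: nine EMF values plus metadata."""

    emf_values: dict[str, float]
    hypotension_level: str = "normo"
    cvp_level: str = "normal"
    tbo: Optional[str] = None
    injection: Optional[tuple[str, float]] = None
    phase: str = "intermediate"

    def __post_init__(self):
        missing = set(EMF_IDS) - set(self.emf_values)
        if missing:
            raise ConfigurationError(f"pressure set missing EMFs {missing}")
        if self.tbo is not None and self.tbo not in ("AF1", "AF2", "AF3"):
            raise ParameterError(
                f"TBO must be one of AF1..AF3, got {self.tbo!r}")
        if any(v < 0 for v in self.emf_values.values()):
            raise ParameterError("EMF pressures must be non-negative")

    @property
    def label(self) -> str:
        inj = (f"{self.injection[0]}+{self.injection[1]:g}"
               if self.injection else "none")
        return (f"{self.hypotension_level}/{self.cvp_level}/"
                f"tbo={self.tbo or 'none'}/inj={inj}/{self.phase}")

    def emf_vector(self) -> list[float]:
        return [self.emf_values[e] for e in EMF_IDS]

    def baseline_parent(self) -> "PressureSet":
        """The matching no-injection set (same hypotension/CVP/TBO/phase)."""
        if self.injection is None:
            return self
        site, pressure = self.injection
        emfs = dict(self.emf_values)
        emfs[f"E{site}"] -= pressure
        return replace(self, emf_values=emfs, injection=None)


def make_pressure_set(config: SimulationConfig,
                      hypotension: str = "normo", cvp: str = "normal",
                      tbo: Optional[str] = None,
                      injection: Optional[tuple[str, float]] = None,
                      phase: str = "intermediate") -> PressureSet:
    """Assemble one pressure set from scenario levels.

    ESP carries the systemic mean for the hypotension level, ECVP the CVP
    level; AF and DV EMFs are zero at baseline.  An injection adds its
    pressure to the injected DV's EMF only.  The cardiac phase scales the
    arterial-side EMFs (ESP, EAF1..4) by ``1 +/- phase_offset_frac``.
    """
    sp = config.scenario
    if hypotension not in sp.hypotension_mmhg:
        raise ParameterError(f"unknown hypotension level {hypotension!r}")
    if cvp not in sp.cvp_mmhg:
        raise ParameterError(f"unknown CVP level {cvp!r}")
    if phase not in _PHASE_SIGN:
        raise ConfigurationError(f"unknown cardiac phase {phase!r}")
    factor = 1.0 + _PHASE_SIGN[phase] * sp.phase_offset_frac
    emfs = {e: 0.0 for e in EMF_IDS}
    emfs["ESP"] = sp.hypotension_mmhg[hypotension] * factor
    for i in range(1, 5):
        emfs[f"EAF{i}"] *= factor
    for i in range(1, 4):
        emfs[f"EDV{i}"] = sp.venous_emf_mmhg
    emfs["ECVP"] = sp.cvp_mmhg[cvp]
    if injection is not None:
        site, pressure = injection
        if site not in INJECTION_SITES:
            raise ParameterError(f"unknown injection site {site!r}")
        emfs[f"E{site}"] += float(pressure)
    return PressureSet(emf_values=emfs, hypotension_level=hypotension,
                       cvp_level=cvp, tbo=tbo, injection=injection,
                       phase=phase)


@dataclass
class ScenarioGrid:
    """A cartesian scenario grid definition."""

    hypotension_levels: Sequence[str] = HYPOTENSION_LEVELS
    cvp_levels: Sequence[str] = CVP_LEVELS
    tbo_states: Sequence[Optional[str]] = TBO_STATES
    injection_pressures: Sequence[float] = (10.0, 20.0, 30.0)
    injection_sites: Sequence[str] = INJECTION_SITES
    phases: Sequence[str] = ("intermediate",)
    include_no_injection: bool = True

    def __post_init__(self):
        if "AF4" in self.tbo_states:
            raise ParameterError("AF4 cannot be balloon-occluded")

    def pressure_sets(self, config: SimulationConfig) -> list[PressureSet]:
        sets = []
        for phase in self.phases:
            for hypo in self.hypotension_levels:
                for cvp in self.cvp_levels:
                    for tbo in self.tbo_states:
                        if self.include_no_injection:
                            sets.append(make_pressure_set(
                                config, hypo, cvp, tbo, None, phase))
                        for site in self.injection_sites:
                            for p in self.injection_pressures:
                                sets.append(make_pressure_set(
                                    config, hypo, cvp, tbo, (site, p), phase))
        return sets


def standard_grid(config: SimulationConfig | None = None) -> list[PressureSet]:
    """The 320-set main grid: 32 no-injection + 288 injection sets."""
    config = config or SimulationConfig()
    return ScenarioGrid().pressure_sets(config)


def fine_sweep_grid(low: float, high: float, step: float,
                    config: SimulationConfig | None = None,
                    hypotension_levels: Sequence[str] = ("moderate",
                                                         "profound"),
                    cvp_levels: Sequence[str] = ("normal",),
                    tbo_states: Sequence[Optional[str]] = TBO_STATES,
                    injection_sites: Sequence[str] = INJECTION_SITES,
                    ) -> list[PressureSet]:
    """Fine injection-pressure sweep (e.g. 20..30 mmHg in 1-mmHg steps)."""
    if step <= 0 or low > high:
        raise ParameterError("sweep requires low <= high and step > 0")
    config = config or SimulationConfig()
    pressures = []
    p = low
    while p <= high + 1e-9:
        pressures.append(round(p, 9))
        p += step
    grid = ScenarioGrid(hypotension_levels=hypotension_levels,
                        cvp_levels=cvp_levels, tbo_states=tbo_states,
                        injection_pressures=pressures,
                        injection_sites=injection_sites,
                        include_no_injection=False)
    return grid.pressure_sets(config)


def phase_grid(config: SimulationConfig | None = None,
               hypotension_levels: Sequence[str] = ("mild",),
               cvp: str = "normal", site: str = "DV1",
               injection_pressures: Sequence[float] | None = None,
               ) -> list[PressureSet]:
    """Cardiac-phase study grid: for each phase, injections through one DV.

    The intermediate phase equals the standard (mean) sets exactly; diastole
    and systole shift the arterial EMFs down/up by the configured offset.
    The default injection sweep is 20..30 mmHg in 1-mmHg steps.
    """
    config = config or SimulationConfig()
    if config.scenario.phase_offset_frac is None:
        raise ConfigurationError("phase offsets are not configured")
    if injection_pressures is None:
        injection_pressures = [float(p) for p in range(20, 31)]
    sets = []
    for phase in PHASES:
        for hypo in hypotension_levels:
            for p in injection_pressures:
                sets.append(make_pressure_set(
                    config, hypo, cvp, None, (site, p), phase))
    return sets
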