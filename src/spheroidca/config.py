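"""Simulation configuration: dataclasses, validation, YAML round-trip."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .cells import CycleParameters, GrowthMode
from .drugs import DrugParameters, RemovalPolicy
from .oxygen import OxygenParameters
from .radiation import RadiosensitivityTable
from .cells import Phase

__all__ = ["ScheduleEvent", "TreatmentSchedule", "SimulationConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid configuration; ``fields`` lists the offending entries."""

    def __init__(self, fields: list[str]):
        super().__init__("invalid configuration: " + "; ".join(fields))
        self.fields = fields


@dataclass
class ScheduleEvent:
    """One dose event: time (hours from treatment start), modality and size.

    ``magnitude`` is Gy for IR; for HAP it is the bath concentration
    (in vitro) or the exterior source rate (in vivo), in units of the
    lethal threshold Psi. ``duration`` applies to HAP exposure only.
    """

    time: float
    modality: str  # "HAP" | "IR"
    magnitude: float
    duration: float | None = None


@dataclass
class TreatmentSchedule:
    events: list[ScheduleEvent] = field(default_factory=list)

    def validate(self) -> list[str]:
        errs = []
        times = [e.time for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            errs.append("schedule.events times must be non-decreasing")
        for i, e in enumerate(self.events):
            if e.modality not in ("HAP", "IR"):
                errs.append(f"schedule.events[{i}].modality unknown: {e.modality!r}")
            if e.magnitude < 0:
                errs.append(f"schedule.events[{i}].magnitude must be >= 0")
            if e.modality == "HAP" and (e.duration is None or e.duration <= 0):
                errs.append(f"schedule.events[{i}].duration must be > 0 for HAP")
        return errs


@dataclass
class SimulationConfig:
    """Everything a run needs; presets live in :mod:`spheroidca.reference`.

    The default cell-clock step matches the published automaton (1e-3 h);
    reduced desk-scale presets raise it to 0.1 h, which is still three
    orders of magnitude below the ~40 h cycle timescale (oxygen and drugs
    are integrated on their own, faster clocks).
    """

    dims: tuple[int, int, int] = (100, 100, 100)
    spacing_um: float = 20.0
    dt: float = 1e-3  # h, cell-clock step
    mode: GrowthMode = GrowthMode.IN_VITRO
    nu: int = 3  # maximal division-neighbourhood order
    cycle: CycleParameters = field(default_factory=CycleParameters)
    oxygen: OxygenParameters = field(default_factory=OxygenParameters)
    drugs: DrugParameters = field(default_factory=DrugParameters)
    radio: RadiosensitivityTable = field(default_factory=RadiosensitivityTable)
    schedule: TreatmentSchedule = field(default_factory=TreatmentSchedule)
    oxygen_scale_factor: float = 1.0
    seed: int = 0
    run_count: int = 10
    output_every: float = 1.0  # h between summary rows
    oxygen_refresh_every: float = 5.0  # h between quasi-steady re-solves
    drug_dt: float = 0.05  # h, drug-field macro-step
    solver: str = "implicit"  # drug-diffusion stepper

    def validate(self) -> "SimulationConfig":
        errs = []
        if len(self.dims) != 3 or any(int(d) < 4 for d in self.dims):
            errs.append("dims must be three integers >= 4")
        if self.spacing_um <= 0:
            errs.append("spacing_um must be > 0")
        if self.dt <= 0:
            errs.append("dt must be > 0")
        if self.nu < 1:
            errs.append("nu must be >= 1")
        if not 0 < self.oxygen_scale_factor <= 1:
            errs.append("oxygen_scale_factor must be in (0, 1]")
        if self.run_count < 1:
            errs.append("run_count must be >= 1")
        if self.output_every <= 0:
            errs.append("output_every must be > 0")
        if self.drug_dt <= 0:
            errs.append("drug_dt must be > 0")
        if self.solver not in ("implicit", "explicit"):
            errs.append("solver must be 'implicit' or 'explicit'")
        errs += self.cycle.validate()
        errs += self.oxygen.validate()
        errs += self.drugs.validate()
        errs += self.radio.validate()
        errs += self.schedule.validate()
        if errs:
            raise ConfigError(errs)
        return self


# ---------------------------------------------------------------------------
# YAML round-trip. Enums and the phase-keyed radiosensitivity dicts need a
# little help; everything else is plain dataclass <-> mapping.

def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {(k.name if isinstance(k, Phase) else k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (GrowthMode, RemovalPolicy)):
        return obj.value
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def config_to_yaml(config: SimulationConfig) -> str:
    return yaml.safe_dump(_to_plain(config), sort_keys=False)


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    kwargs = {}
    kwargs["dims"] = tuple(d.pop("dims", (100, 100, 100)))
    if "mode" in d:
        kwargs["mode"] = GrowthMode(d.pop("mode"))
    if "cycle" in d:
        c = dict(d.pop("cycle"))
        if "theta" in c:
            c["theta"] = tuple(c["theta"])
        kwargs["cycle"] = CycleParameters(**c)
    if "oxygen" in d:
        kwargs["oxygen"] = OxygenParameters(**d.pop("oxygen"))
    if "drugs" in d:
        dd = dict(d.pop("drugs"))
        if "removal_policy" in dd:
            dd["removal_policy"] = RemovalPolicy(dd["removal_policy"])
        kwargs["drugs"] = DrugParameters(**dd)
    if "radio" in d:
        r = dict(d.pop("radio"))
        for key in ("alpha", "beta"):
            if key in r:
                r[key] = {Phase[k]: v for k, v in r[key].items()}
        kwargs["radio"] = RadiosensitivityTable(**r)
    if "schedule" in d:
        evs = d.pop("schedule").get("events", [])
        kwargs["schedule"] = TreatmentSchedule([ScheduleEvent(**e) for e in evs])
    kwargs.update(d)
    return SimulationConfig(**kwargs)


def config_from_yaml(text: str) -> SimulationConfig:
    return config_from_dict(yaml.safe_load(text)).validate()
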