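"""Model parameter tables and configuration I/O.

All defaults are the published point estimates used by the cohort model:
annual lesion transition probabilities, colonoscopy sensitivities by lesion
size, stage-specific breakpoint mortality hazards, registry-style stage
prevalences, treatment/colonoscopy costs with one-way sensitivity bounds,
and health-state utilities.  A configuration can be round-tripped through
YAML or JSON; the ``transition_rates`` block of the file uses the clinical
row labels verbatim so a parameter file reads like the source table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path

import yaml

__all__ = [
    "CRCStage",
    "LesionTransitionRates",
    "SensitivityTable",
    "BreakpointHazard",
    "StageMix",
    "Bounded",
    "CostTables",
    "UtilityTable",
    "DiscountSpec",
    "ModelConfig",
    "default_config",
    "load_config",
    "save_config",
]


class CRCStage(IntEnum):
    """Colorectal cancer stage; ``NONE`` means no invasive cancer."""

    NONE = 0
    LOCAL = 1
    REGIONAL = 2
    DISTANT = 3


#: Stage names used in survival fitting; "unknown" never appears in the
#: natural-history state space, only in the prevalence-weighted mixture.
SURVIVAL_STAGES = ("local", "regional", "distant", "unknown")


class ConfigError(ValueError):
    """Raised when a parameter table violates its invariants."""


@dataclass(frozen=True)
class LesionTransitionRates:
    """Annual transition probabilities of the colonic neoplasia model.

    Each value is the probability that a single lesion (or the patient's
    cancer) makes the named transition within one year.  The appearance of
    new diminutive adenomas is age dependent: zero before
    ``appearance_ramp_start_age``, rising linearly to ``appearance_max`` at
    ``appearance_plateau_age`` and constant thereafter.
    """

    appearance_max: float = 0.0971
    appearance_ramp_start_age: float = 20.0
    appearance_plateau_age: float = 70.0
    diminutive_to_none: float = 0.0181
    diminutive_to_medium: float = 0.0163
    medium_to_diminutive: float = 0.0716
    medium_to_large: float = 0.0377
    medium_to_crc: float = 0.0025
    large_to_medium: float = 0.0047
    large_to_crc: float = 0.0028
    local_to_regional: float = 0.22
    regional_to_distant: float = 0.50
    symptoms_local: float = 0.17
    symptoms_regional: float = 0.22
    symptoms_distant: float = 0.50

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if name.startswith("appearance_ramp") or name.startswith("appearance_plateau"):
                continue
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name}={value} outside [0, 1]")
        if not 0.0 <= self.appearance_max < 1.0:
            raise ConfigError("appearance_max must be in [0, 1)")
        if self.appearance_plateau_age <= self.appearance_ramp_start_age:
            raise ConfigError("plateau age must exceed ramp start age")
        # outgoing probability per lesion class must leave a positive
        # self-transition remainder
        out = {
            "diminutive": self.diminutive_to_none + self.diminutive_to_medium,
            "medium": self.medium_to_diminutive + self.medium_to_large + self.medium_to_crc,
            "large": self.large_to_medium + self.large_to_crc,
            "local": self.local_to_regional + self.symptoms_local,
            "regional": self.regional_to_distant + self.symptoms_regional,
            "distant": self.symptoms_distant,
        }
        for cls, total in out.items():
            if total >= 1.0:
                raise ConfigError(f"outgoing yearly probability from {cls} is {total} >= 1")


#: Mapping between the dataclass fields and the clinical row labels used in
#: parameter files.
_RATE_LABELS = {
    "diminutive_to_none": "Diminutive to no adenoma",
    "diminutive_to_medium": "Diminutive to medium adenoma",
    "medium_to_diminutive": "Medium to diminutive adenoma",
    "medium_to_large": "Medium to large adenoma",
    "medium_to_crc": "Medium adenoma to CRC",
    "large_to_medium": "Large to medium adenoma",
    "large_to_crc": "Large adenoma to local CRC",
    "local_to_regional": "Local CRC to regional CRC",
    "regional_to_distant": "Regional CRC to distant CRC",
    "symptoms_local": "Asymptomatic local CRC to symptomatic local CRC",
    "symptoms_regional": "Asymptomatic regional CRC to symptomatic regional CRC",
    "symptoms_distant": "Asymptomatic distant CRC to symptomatic distant CRC",
}


@dataclass(frozen=True)
class SensitivityTable:
    """Per-lesion colonoscopy detection probabilities by lesion size.

    Published values exist for diminutive (0.39) and large (0.958) adenomas.
    The medium-size sensitivity and the sensitivity for an asymptomatic
    cancer are not published; the defaults (0.70 between the two printed
    anchors, and 0.958 matching large lesions) are configurable.
    """

    diminutive: float = 0.39
    medium: float = 0.70
    large: float = 0.958
    crc: float = 0.958

    def __post_init__(self) -> None:
        for name in ("diminutive", "medium", "large", "crc"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"sensitivity {name}={value} outside [0, 1]")
        if not self.diminutive <= self.medium <= self.large:
            raise ConfigError("sensitivity must be non-decreasing in lesion size")


@dataclass(frozen=True)
class BreakpointHazard:
    """Two-piece constant mortality hazard after cancer diagnosis.

    The hazard is ``k1`` per year until ``breakpoint`` years since
    diagnosis and ``k2`` thereafter.
    """

    stage: str
    k1: float
    breakpoint: float
    k2: float

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k2 < 0:
            raise ConfigError("hazard rates must be non-negative")
        if self.breakpoint <= 0:
            raise ConfigError("breakpoint must be positive")

    def rate(self, t: float) -> float:
        """Hazard at ``t`` years since diagnosis."""
        return self.k1 if t < self.breakpoint else self.k2


def default_breakpoint_hazards() -> dict[str, BreakpointHazard]:
    """Fitted stage-specific hazards (per year) with their breakpoints."""
    return {
        "local": BreakpointHazard("local", 0.025, 7.3, 0.018),
        "regional": BreakpointHazard("regional", 0.068, 5.3, 0.025),
        "distant": BreakpointHazard("distant", 0.600, 1.6, 0.085),
        "unknown": BreakpointHazard("unknown", 0.155, 4.8, 2.2e-6),
    }


@dataclass(frozen=True)
class StageMix:
    """Stage-at-diagnosis prevalence weights for the survival mixture."""

    local: float = 0.44
    regional: float = 0.34
    distant: float = 0.18
    unknown: float = 0.05
    normalizer: float = 1.01

    def __post_init__(self) -> None:
        weights = (self.local, self.regional, self.distant, self.unknown)
        if any(w < 0 for w in weights):
            raise ConfigError("stage weights must be non-negative")
        if abs(sum(weights) - self.normalizer) > 1e-12:
            raise ConfigError("stage weights must sum to the normalizer")

    def weight(self, stage: str) -> float:
        return getattr(self, stage)


@dataclass(frozen=True)
class Bounded:
    """A base-case value with low/high one-way sensitivity bounds."""

    base: float
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        if self.base < 0:
            raise ConfigError("costs must be non-negative")
        lo = self.base if self.low is None else self.low
        hi = self.base if self.high is None else self.high
        if not lo <= self.base <= hi:
            raise ConfigError(f"bounds must bracket the base value: {lo}, {self.base}, {hi}")

    def pick(self, which: str) -> float:
        if which == "base":
            return self.base
        if which == "low":
            return self.base if self.low is None else self.low
        if which == "high":
            return self.base if self.high is None else self.high
        raise ConfigError(f"unknown bound {which!r}")


@dataclass(frozen=True)
class CostTables:
    """Colonoscopy and phase-based CRC treatment costs (2010 USD).

    CRC costs follow the initial / surveillance / terminal phase structure:
    the initial cost accrues over the first year after diagnosis, the
    surveillance cost over years 2-5, and the terminal cost once, in the
    year of a CRC death (added to, not replacing, that year's phase cost).
    """

    colonoscopy: Bounded = field(default_factory=lambda: Bounded(1068.59, 303.0, 2627.0))
    adverse_events: Bounded = field(default_factory=lambda: Bounded(92.06))
    initial: dict[str, Bounded] = field(
        default_factory=lambda: {
            "local": Bounded(20247.20, 13848.0, 25527.02),
            "regional": Bounded(26007.50, 15398.0, 37639.27),
            "distant": Bounded(30085.20, 17223.0, 42401.0),
        }
    )
    surveillance: dict[str, Bounded] = field(
        default_factory=lambda: {
            "local": Bounded(1305.04, 425.0, 2353.26),
            "regional": Bounded(2346.72, 1424.0, 4014.69),
            "distant": Bounded(15057.0, 2702.0, 26855.0),
        }
    )
    terminal: Bounded = field(default_factory=lambda: Bounded(23002.35, 11188.0, 50920.0))

    def at(self, colonoscopy: str = "base", cancer: str = "base") -> "CostValues":
        """Resolve the tables at the requested sensitivity bounds."""
        return CostValues(
            colonoscopy=self.colonoscopy.pick(colonoscopy),
            adverse_events=self.adverse_events.pick("base"),
            initial={s: b.pick(cancer) for s, b in self.initial.items()},
            surveillance={s: b.pick(cancer) for s, b in self.surveillance.items()},
            terminal=self.terminal.pick(cancer),
        )


@dataclass(frozen=True)
class CostValues:
    """Cost tables resolved to point values (no sensitivity bounds)."""

    colonoscopy: float
    adverse_events: float
    initial: dict[str, float]
    surveillance: dict[str, float]
    terminal: float

    @property
    def per_colonoscopy(self) -> float:
        return self.colonoscopy + self.adverse_events

    def zeroed(self) -> "CostValues":
        """All-zero costs, useful for bookkeeping checks."""
        zero = {s: 0.0 for s in self.initial}
        return CostValues(0.0, 0.0, zero, dict(zero), 0.0)


@dataclass(frozen=True)
class UtilityTable:
    """Annual QALY weights by health state.

    Alive patients without a cancer diagnosis score the healthy utility
    (adenomas are asymptomatic and undetected); a diagnosed cancer scores
    the utility of its stage at diagnosis; death scores zero.
    """

    healthy: float = 0.91
    dead: float = 0.0
    local: float = 0.74
    regional: float = 0.70
    distant: float = 0.25

    def __post_init__(self) -> None:
        for name in ("healthy", "dead", "local", "regional", "distant"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"utility {name}={value} outside [0, 1]")
        if self.dead != 0.0:
            raise ConfigError("utility of death must be 0")


@dataclass(frozen=True)
class DiscountSpec:
    """Continuous annual discounting anchored at the screening age."""

    rate: float = 0.03
    anchor_age: float = 50.0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ConfigError("discount rate must be non-negative")


@dataclass(frozen=True)
class ModelConfig:
    """Full parameterization of the cohort model and economic evaluation."""

    rates: LesionTransitionRates = field(default_factory=LesionTransitionRates)
    sensitivity: SensitivityTable = field(default_factory=SensitivityTable)
    hazards: dict[str, BreakpointHazard] = field(default_factory=default_breakpoint_hazards)
    stage_mix: StageMix = field(default_factory=StageMix)
    costs: CostTables = field(default_factory=CostTables)
    utilities: UtilityTable = field(default_factory=UtilityTable)
    discount_rate: float = 0.03
    adenoma_cap: int = 3
    horizon_age: float = 100.0
    life_table: object | None = None  # DataFrame (age_lo, age_hi, annual_death_rate)

    def __post_init__(self) -> None:
        if self.adenoma_cap < 1:
            raise ConfigError("adenoma count cap must be >= 1")
        missing = set(SURVIVAL_STAGES) - set(self.hazards)
        if missing:
            raise ConfigError(f"missing breakpoint hazards for stages: {sorted(missing)}")

    def with_(self, **kwargs) -> "ModelConfig":
        return replace(self, **kwargs)


def default_config() -> ModelConfig:
    return ModelConfig()


# ---------------------------------------------------------------------------
# serialization

def _config_to_dict(config: ModelConfig) -> dict:
    rates = config.rates
    d = {
        "transition_rates": {
            "No adenoma to diminutive": {
                "max": rates.appearance_max,
                "ramp_start_age": rates.appearance_ramp_start_age,
                "plateau_age": rates.appearance_plateau_age,
            },
            **{label: getattr(rates, fieldname) for fieldname, label in _RATE_LABELS.items()},
        },
        "sensitivity": {
            "diminutive": config.sensitivity.diminutive,
            "medium": config.sensitivity.medium,
            "large": config.sensitivity.large,
            "crc": config.sensitivity.crc,
        },
        "crc_mortality": {
            stage: {
                "Initial mortality rate (1/year)": h.k1,
                "Breakpoint (years)": h.breakpoint,
                "Second mortality rate (1/year)": h.k2,
            }
            for stage, h in config.hazards.items()
        },
        "stage_prevalence": {
            "local": config.stage_mix.local,
            "regional": config.stage_mix.regional,
            "distant": config.stage_mix.distant,
            "unknown": config.stage_mix.unknown,
            "normalizer": config.stage_mix.normalizer,
        },
        "costs": {
            "Colonoscopy": _bounded_to_list(config.costs.colonoscopy),
            "Adverse effects": _bounded_to_list(config.costs.adverse_events),
            "Initial (year 1)": {s: _bounded_to_list(b) for s, b in config.costs.initial.items()},
            "Surveillance (years 2-5)": {
                s: _bounded_to_list(b) for s, b in config.costs.surveillance.items()
            },
            "Terminal": _bounded_to_list(config.costs.terminal),
        },
        "utilities": {
            "Healthy": config.utilities.healthy,
            "Dead": config.utilities.dead,
            "Local CRC": config.utilities.local,
            "Regional CRC": config.utilities.regional,
            "Distant CRC": config.utilities.distant,
        },
        "discount_rate": config.discount_rate,
        "adenoma_cap": config.adenoma_cap,
        "horizon_age": config.horizon_age,
    }
    return d


def _bounded_to_list(b: Bounded) -> list:
    return [b.base, b.low, b.high]


def _bounded_from(v) -> Bounded:
    if isinstance(v, (int, float)):
        return Bounded(float(v))
    base, low, high = v
    return Bounded(float(base), None if low is None else float(low), None if high is None else float(high))


def _config_from_dict(d: dict) -> ModelConfig:
    tr = d.get("transition_rates", {})
    appearance = tr.get("No adenoma to diminutive", {})
    rate_kwargs = {}
    if appearance:
        rate_kwargs.update(
            appearance_max=float(appearance.get("max", 0.0971)),
            appearance_ramp_start_age=float(appearance.get("ramp_start_age", 20.0)),
            appearance_plateau_age=float(appearance.get("plateau_age", 70.0)),
        )
    for fieldname, label in _RATE_LABELS.items():
        if label in tr:
            rate_kwargs[fieldname] = float(tr[label])
    rates = LesionTransitionRates(**rate_kwargs)

    sens = SensitivityTable(**{k: float(v) for k, v in d.get("sensitivity", {}).items()})

    hazards = default_breakpoint_hazards()
    for stage, row in d.get("crc_mortality", {}).items():
        hazards[stage] = BreakpointHazard(
            stage,
            float(row["Initial mortality rate (1/year)"]),
            float(row["Breakpoint (years)"]),
            float(row["Second mortality rate (1/year)"]),
        )

    mix_d = d.get("stage_prevalence")
    mix = StageMix(**{k: float(v) for k, v in mix_d.items()}) if mix_d else StageMix()

    costs_d = d.get("costs")
    if costs_d:
        costs = CostTables(
            colonoscopy=_bounded_from(costs_d["Colonoscopy"]),
            adverse_events=_bounded_from(costs_d["Adverse effects"]),
            initial={s: _bounded_from(b) for s, b in costs_d["Initial (year 1)"].items()},
            surveillance={s: _bounded_from(b) for s, b in costs_d["Surveillance (years 2-5)"].items()},
            terminal=_bounded_from(costs_d["Terminal"]),
        )
    else:
        costs = CostTables()

    util_d = d.get("utilities")
    if util_d:
        utilities = UtilityTable(
            healthy=float(util_d["Healthy"]),
            dead=float(util_d["Dead"]),
            local=float(util_d["Local CRC"]),
            regional=float(util_d["Regional CRC"]),
            distant=float(util_d["Distant CRC"]),
        )
    else:
        utilities = UtilityTable()

    return ModelConfig(
        rates=rates,
        sensitivity=sens,
        hazards=hazards,
        stage_mix=mix,
        costs=costs,
        utilities=utilities,
        discount_rate=float(d.get("discount_rate", 0.03)),
        adenoma_cap=int(d.get("adenoma_cap", 3)),
        horizon_age=float(d.get("horizon_age", 100.0)),
    )


def save_config(config: ModelConfig, path: str | Path) -> None:
    """Write a configuration as YAML (``.yaml``/``.yml``) or JSON."""
    path = Path(path)
    d = _config_to_dict(config)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


def load_config(path: str | Path) -> ModelConfig:
    """Read a configuration written by :func:`save_config`."""
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return _config_from_dict(d)
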