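"""Parameter schema, validation and (de)serialization.

All model constants are grouped by sub-model, mirroring the structure of the
coupled system: the endocrine core (GnRH / LH / FSH / ovarian transport and
receptor binding / steroid production), the algebraic luteal steroid curves,
stochastic follicle recruitment, follicular growth and competition,
drug pharmacokinetics, and the two stimulation-protocol rule sets.

Every parameter carries a provenance tag in ``ModelParameters.meta``
(``"calibrated"`` for values fitted to reproduce published cycle and
treatment statistics, ``"clinical"`` for values taken directly from the
protocol descriptions, ``"convention"`` for fixed structural choices such as
the 14-day luteal phase).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import yaml

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Raised when a parameter set violates the schema; message lists all
    offending keys."""


# ---------------------------------------------------------------------------
# Sub-model parameter groups
# ---------------------------------------------------------------------------


@dataclass
class HillSpec:
    """A Hill-function feedback term: half-effect threshold, exponent, mode."""

    threshold: float
    exponent: float
    mode: Literal["stimulatory", "inhibitory"] = "stimulatory"

    def validate(self, prefix: str, errors: list[str]) -> None:
        if not self.threshold > 0:
            errors.append(f"{prefix}.threshold must be > 0 (got {self.threshold})")
        if not self.exponent > 0:
            errors.append(f"{prefix}.exponent must be > 0 (got {self.exponent})")
        if self.mode not in ("stimulatory", "inhibitory"):
            errors.append(f"{prefix}.mode must be 'stimulatory' or 'inhibitory'")


@dataclass
class LutealCurveParams:
    """Gaussian-shaped luteal E2/P4 curves with fixed 14-day support.

    The corpus luteum is not a dynamical state: after each ovulation the
    luteal steroids follow fixed Gaussian curves peaking mid-luteal.
    """

    amplitude_p4: float = 13.0   # peak luteal P4 (ng/mL)
    amplitude_e2: float = 110.0  # peak luteal E2 (pg/mL)
    peak_offset: float = 7.0     # days from ovulation to peak (mid-luteal)
    width: float = 1.8           # Gaussian sigma (days)
    luteal_length: float = 14.0  # fixed luteal-phase duration (days)

    def validate(self, errors: list[str]) -> None:
        for k in ("amplitude_p4", "amplitude_e2", "peak_offset", "width"):
            if not getattr(self, k) > 0:
                errors.append(f"luteal.{k} must be > 0 (got {getattr(self, k)})")
        if self.luteal_length != 14.0:
            errors.append("luteal.luteal_length is fixed at 14.0 days")
        if not 0 < self.peak_offset < self.luteal_length:
            errors.append("luteal.peak_offset must lie inside the luteal phase")


@dataclass
class HormoneCoreParams:
    """Constants of the reduced pituitary/ovarian endocrine ODE system.

    Units: time in days; serum LH/FSH in IU/L, pituitary pools in IU;
    E2 in pg/mL; P4 in ng/mL; GnRH frequency/mass dimensionless.
    """

    # GnRH pulse frequency: relaxes toward a P4-inhibited target with a
    # floor (pulsatility slows but does not stop in the luteal phase)
    gnrh_freq_gain: float = 5.0
    gnrh_freq_floor: float = 0.15
    gnrh_freq_p4: HillSpec = field(
        default_factory=lambda: HillSpec(1.5, 2.0, "inhibitory"))
    # GnRH releasable mass: synthesis under biphasic E2 control, 1st-order release
    gnrh_mass_synthesis: float = 2.0
    gnrh_mass_release: float = 2.0
    gnrh_e2_inhibitory: HillSpec = field(
        default_factory=lambda: HillSpec(120.0, 2.0, "inhibitory"))
    gnrh_e2_stimulatory: HillSpec = field(
        default_factory=lambda: HillSpec(200.0, 8.0, "stimulatory"))
    gnrh_e2_inhibitory_weight: float = 1.0
    gnrh_e2_stimulatory_weight: float = 2.0

    # LH: synthesis stimulated by E2 (steep, drives the surge), inhibited by P4
    lh_syn_basal: float = 250.0       # IU/day
    lh_syn_e2_max: float = 4000.0     # IU/day at full E2 stimulation
    lh_e2: HillSpec = field(default_factory=lambda: HillSpec(210.0, 10.0))
    lh_p4: HillSpec = field(
        default_factory=lambda: HillSpec(0.35, 2.0, "inhibitory"))
    lh_release: float = 3.0           # 1/day per unit GnRH activity
    lh_clearance: float = 14.0        # 1/day serum clearance

    # FSH: synthesis inhibited by P4 (replacing inhibin feedback) and by E2
    fsh_syn_basal: float = 145.0      # IU/day
    fsh_p4: HillSpec = field(
        default_factory=lambda: HillSpec(4.0, 2.0, "inhibitory"))
    fsh_e2: HillSpec = field(
        default_factory=lambda: HillSpec(135.0, 5.0, "inhibitory"))
    fsh_release: float = 1.0          # 1/day per unit GnRH activity
    fsh_clearance: float = 5.0        # 1/day serum clearance

    blood_volume: float = 2.5         # lumped distribution factor (L)

    # FSH transport into the ovary and receptor binding
    fsh_transport: float = 4.0        # serum -> ovary (1/day)
    fsh_ovary_clearance: float = 2.0  # ovarian degradation (1/day)
    fsh_binding: float = 2.0          # ovary -> receptor complex (1/day)
    fsh_unbinding: float = 2.0        # complex dissociation (1/day)

    # steroid production
    e2_baseline: float = 20.0         # non-follicular, non-luteal E2 floor (pg/mL)
    e2_per_follicle: float = 0.0075   # pg/mL per mm^e2_size_exponent
    e2_size_exponent: float = 3.5     # granulosa-mass scaling of follicular E2
    p4_baseline: float = 0.3          # non-luteal P4 floor (ng/mL)

    def validate(self, errors: list[str]) -> None:
        positive = [
            "gnrh_freq_gain", "gnrh_mass_synthesis", "gnrh_mass_release",
            "gnrh_e2_inhibitory_weight", "gnrh_e2_stimulatory_weight",
            "lh_syn_basal", "lh_syn_e2_max", "lh_release", "lh_clearance",
            "fsh_syn_basal", "fsh_release", "fsh_clearance", "blood_volume",
            "fsh_transport", "fsh_ovary_clearance", "fsh_binding",
            "fsh_unbinding", "e2_per_follicle", "e2_size_exponent",
        ]
        for k in positive:
            if not getattr(self, k) > 0:
                errors.append(f"hormone_core.{k} must be > 0 (got {getattr(self, k)})")
        for k in ("e2_baseline", "p4_baseline"):
            if getattr(self, k) < 0:
                errors.append(f"hormone_core.{k} must be >= 0")
        if not 0 <= self.gnrh_freq_floor < 1:
            errors.append("hormone_core.gnrh_freq_floor must be in [0, 1)")
        for k in ("gnrh_freq_p4", "gnrh_e2_inhibitory", "gnrh_e2_stimulatory",
                  "lh_e2", "lh_p4", "fsh_p4", "fsh_e2"):
            getattr(self, k).validate(f"hormone_core.{k}", errors)


@dataclass
class RecruitmentParams:
    """Poisson recruitment of antral follicles into the growing pool."""

    base_rate: float = 0.7             # follicles/day
    elevated_rate: float = 4.5         # follicles/day when FSH is high
    fsh_recruit_threshold: float = 6.5  # serum FSH (IU/L) switching the rate
    sens_mean: float = 8.0             # mean FSH-sensitivity threshold (IU/L)
    sens_sd: float = 2.0               # SD of the sensitivity threshold
    seed_size: float = 2.0             # diameter at recruitment (mm)

    def validate(self, errors: list[str]) -> None:
        if not self.base_rate > 0:
            errors.append(f"recruitment.base_rate must be > 0 (got {self.base_rate})")
        if not self.elevated_rate >= self.base_rate:
            errors.append("recruitment.elevated_rate must be >= base_rate")
        if not self.sens_sd > 0:
            errors.append(f"recruitment.sens_sd must be > 0 (got {self.sens_sd})")
        if not self.fsh_recruit_threshold > 0:
            errors.append("recruitment.fsh_recruit_threshold must be > 0")
        if not self.seed_size > 0:
            errors.append("recruitment.seed_size must be > 0")


@dataclass
class GrowthParams:
    """Follicular growth, competition and life-cycle thresholds."""

    growth_rate: float = 0.60          # intrinsic logistic rate (1/day)
    max_size: float = 26.0             # asymptotic follicle diameter (mm)
    competition_strength: float = 0.10  # shared competition coefficient (1/day)
    competition_load_exponent: float = 2.0  # size weighting of the load
    fsh_window_threshold: float = 10.0  # ovarian FSH switching competition off
    fsh_window_exponent: float = 6.0
    gate_exponent: float = 6.0         # steepness of the FSH-sensitivity gate
    atresia_rate: float = 0.25         # regression rate of FSH-deprived
    #                                    follicles (1/day)
    p4_atresia_boost: float = 3.0      # extra regression under luteal P4
    p4_atresia: HillSpec = field(
        default_factory=lambda: HillSpec(4.0, 4.0, "stimulatory"))
    p4_growth_inhibition: HillSpec = field(
        default_factory=lambda: HillSpec(8.5, 2.0, "inhibitory"))
    rec_complex_stimulation: HillSpec = field(
        default_factory=lambda: HillSpec(8.0, 2.0, "stimulatory"))
    ovulation_size_threshold: float = 18.0  # minimal ovulable diameter (mm)
    atresia_floor: float = 1.8         # retirement diameter for shrinkers (mm)
    # dominance: the largest follicle past this size escapes FSH dependence
    # (gonadotropin switch of the selected follicle) and cannot regress
    dominance_size: float = 15.0       # mm
    dominance_floor: float = 0.30      # minimal growth modifier of the leader

    def validate(self, errors: list[str]) -> None:
        for k in ("growth_rate", "fsh_window_threshold", "fsh_window_exponent",
                  "gate_exponent", "competition_load_exponent"):
            if not getattr(self, k) > 0:
                errors.append(f"growth.{k} must be > 0 (got {getattr(self, k)})")
        for k in ("competition_strength", "atresia_rate", "p4_atresia_boost"):
            if getattr(self, k) < 0:
                errors.append(f"growth.{k} must be >= 0")
        self.p4_atresia.validate("growth.p4_atresia", errors)
        if not 0 <= self.dominance_floor <= 1:
            errors.append("growth.dominance_floor must be in [0, 1]")
        if not self.dominance_size > 0:
            errors.append("growth.dominance_size must be > 0")
        if not (self.max_size > self.ovulation_size_threshold
                > self.atresia_floor >= 0):
            errors.append(
                "growth: require max_size > ovulation_size_threshold "
                "> atresia_floor >= 0")
        self.p4_growth_inhibition.validate("growth.p4_growth_inhibition", errors)
        self.rec_complex_stimulation.validate(
            "growth.rec_complex_stimulation", errors)
        if self.p4_growth_inhibition.mode != "inhibitory":
            errors.append("growth.p4_growth_inhibition.mode must be inhibitory")
        if self.rec_complex_stimulation.mode != "stimulatory":
            errors.append("growth.rec_complex_stimulation.mode must be stimulatory")


@dataclass
class PKParams:
    """One-compartment hMG pharmacokinetics: first-order absorption and
    elimination plus a lumped dose-to-concentration scale."""

    absorption_rate: float = 3.0   # ka (1/day)
    elimination_rate: float = 0.35  # ke (1/day)
    scale: float = 0.044           # (IU/L) per IU administered
    lh_activity: bool = False      # hMG modeled as pure FSH activity

    def validate(self, errors: list[str]) -> None:
        for k in ("absorption_rate", "elimination_rate", "scale"):
            if not getattr(self, k) > 0:
                errors.append(f"pk.{k} must be > 0 (got {getattr(self, k)})")


@dataclass
class ProtocolParams:
    """Clinical rule constants of the two variable-start protocols."""

    # shared stopping criterion
    stop_n_follicles: int = 3
    stop_size: float = 18.0            # mm
    # late-follicular start
    lf_trigger_size: float = 14.0      # mm; start when any follicle this big
    lf_initial_dose: float = 150.0     # IU/day
    lf_escalated_dose: float = 225.0   # IU/day
    lf_escalation_day: int = 6         # dose rises on the 7th administration
    # luteal start
    luteal_window: tuple[float, float] = (1.0, 3.0)  # days post-ovulation
    luteal_max_follicle_size: float = 8.0  # mm; need a follicle below this
    luteal_dose: float = 225.0         # IU/day
    dose_hour: float = 8.0 / 24.0      # daily morning check/administration

    def validate(self, errors: list[str]) -> None:
        if self.stop_n_follicles < 1:
            errors.append("protocol.stop_n_follicles must be >= 1")
        for k in ("stop_size", "lf_trigger_size", "lf_initial_dose",
                  "lf_escalated_dose", "luteal_max_follicle_size",
                  "luteal_dose"):
            if not getattr(self, k) > 0:
                errors.append(f"protocol.{k} must be > 0 (got {getattr(self, k)})")
        lo, hi = self.luteal_window
        if not 0 <= lo < hi:
            errors.append("protocol.luteal_window must satisfy 0 <= lo < hi")
        if not 0 <= self.dose_hour < 1:
            errors.append("protocol.dose_hour must be a day fraction in [0, 1)")


@dataclass
class ModelParameters:
    """The complete coupled-model parameter set, grouped by sub-model."""

    hormone_core: HormoneCoreParams = field(default_factory=HormoneCoreParams)
    luteal: LutealCurveParams = field(default_factory=LutealCurveParams)
    recruitment: RecruitmentParams = field(default_factory=RecruitmentParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    pk: PKParams = field(default_factory=PKParams)
    protocol: ProtocolParams = field(default_factory=ProtocolParams)
    meta: dict = field(default_factory=lambda: {
        "schema_version": SCHEMA_VERSION,
        "provenance": {
            "hormone_core": "calibrated",
            "luteal": "calibrated",
            "recruitment": "calibrated",
            "growth": "calibrated",
            "pk": "calibrated",
            "protocol": "clinical",
            "luteal.luteal_length": "convention",
        },
    })

    def validate(self) -> None:
        errors: list[str] = []
        self.hormone_core.validate(errors)
        self.luteal.validate(errors)
        self.recruitment.validate(errors)
        self.growth.validate(errors)
        self.pk.validate(errors)
        self.protocol.validate(errors)
        if errors:
            raise ConfigError(
                "invalid parameter set:\n  " + "\n  ".join(errors))


def default_parameters() -> ModelParameters:
    """The default (calibrated) parameter set."""
    params = ModelParameters()
    params.validate()
    return params


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_GROUP_TYPES = {
    "hormone_core": HormoneCoreParams,
    "luteal": LutealCurveParams,
    "recruitment": RecruitmentParams,
    "growth": GrowthParams,
    "pk": PKParams,
    "protocol": ProtocolParams,
}


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def save_params(params: ModelParameters, path: str | Path) -> None:
    """Write a parameter set to a human-editable YAML file."""
    doc = {name: _to_plain(getattr(params, name)) for name in _GROUP_TYPES}
    doc["meta"] = params.meta
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _build_group(cls, data: dict, group: str, errors: list[str]):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            errors.append(f"{group}.{key}: unknown key")
            continue
        ftype = fields[key].type
        if isinstance(value, dict) and "threshold" in value:
            value = HillSpec(**value)
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:
        errors.append(f"{group}: {exc}")
        return cls()


def load_params(path: str | Path) -> ModelParameters:
    """Load and validate a parameter file; errors name every offending key."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"parameter file not found: {path}")
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: not a mapping")
    meta = doc.get("meta", {})
    if meta.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
        raise ConfigError(
            f"{path}: schema_version {meta.get('schema_version')} "
            f"!= {SCHEMA_VERSION}")
    errors: list[str] = []
    groups = {}
    for name, cls in _GROUP_TYPES.items():
        data = doc.get(name)
        if data is None:
            errors.append(f"missing section: {name}")
            groups[name] = cls()
            continue
        groups[name] = _build_group(cls, data, name, errors)
    for key in doc:
        if key not in _GROUP_TYPES and key != "meta":
            errors.append(f"unknown section: {key}")
    if errors:
        raise ConfigError("invalid parameter file:\n  " + "\n  ".join(errors))
    params = ModelParameters(meta=meta or ModelParameters().meta, **groups)
    params.validate()
    return params
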