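"""Typed, validated model parameters and their config-file plumbing.

Every input of the cost-effectiveness model lives here: per-arm annual
transition probabilities, age-banded background mortality, health-state
utilities, and the run configuration (cohort size, horizon, discount
rates, conventions).  The bundled parameter sets are loaded from the
packaged YAML fixtures, which are the single source of truth for the
published values.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, NamedTuple

import yaml

from .conventions import ModelConventions

__all__ = [
    "ArmParameters",
    "MortalityTable",
    "UtilitySet",
    "ModelConfig",
    "ParameterBundle",
    "ValidationReport",
    "SchemaError",
    "builtin_table1",
    "load_parameters",
    "serialize_parameters",
    "validate_parameters",
]


class SchemaError(ValueError):
    """A config document does not conform to the parameter schema."""


def _check_prob(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise SchemaError(f"{name} must be in [0, 1], got {value}")
    return value


def _check_prob_vector(name: str, values: Iterable[float], length: int) -> tuple:
    vec = tuple(float(v) for v in values)
    if len(vec) != length:
        raise SchemaError(
            f"{name} must have exactly {length} annual values, got {len(vec)}"
        )
    for i, v in enumerate(vec, start=1):
        _check_prob(f"{name}[year {i}]", v)
    return vec


def _check_cost(name: str, value: float) -> float:
    value = float(value)
    if value < 0:
        raise SchemaError(f"{name} must be >= 0, got {value}")
    return value


@dataclass(frozen=True)
class ArmParameters:
    """One treatment arm's transition probabilities and unit costs.

    Time-dependent probabilities are indexed by year since surgery
    (years 1..horizon); metastasis probabilities are annual and fixed.
    Costs are per patient in 2021 USD, except ``cost_annual_maintenance``
    which is per equipment-year (0 where not applicable).
    """

    arm_label: str
    p_local_recurrence: tuple[float, ...]
    p_bc_death: tuple[float, ...]
    p_metastasis_from_disease_free: float
    p_metastasis_from_local_recurrence: float
    cost_treatment: float
    cost_other_direct: float
    cost_annual_maintenance: float = 0.0

    def __post_init__(self) -> None:
        horizon = len(self.p_local_recurrence)
        if len(self.p_bc_death) != horizon:
            raise SchemaError(
                f"p_bc_death has {len(self.p_bc_death)} values but "
                f"p_local_recurrence has {horizon}; vectors must cover the same years"
            )
        object.__setattr__(
            self,
            "p_local_recurrence",
            _check_prob_vector("p_local_recurrence", self.p_local_recurrence, horizon),
        )
        object.__setattr__(
            self,
            "p_bc_death",
            _check_prob_vector("p_bc_death", self.p_bc_death, horizon),
        )
        _check_prob(
            "p_metastasis_from_disease_free", self.p_metastasis_from_disease_free
        )
        _check_prob(
            "p_metastasis_from_local_recurrence",
            self.p_metastasis_from_local_recurrence,
        )
        for name in ("cost_treatment", "cost_other_direct", "cost_annual_maintenance"):
            _check_cost(name, getattr(self, name))

    @property
    def horizon(self) -> int:
        return len(self.p_local_recurrence)

    def with_variant(self, label: str, **overrides) -> "ArmParameters":
        """Copy with the named fields replaced (one-way sensitivity sets)."""
        return replace(self, arm_label=label, **overrides)


@dataclass(frozen=True)
class MortalityTable:
    """Age-banded annual all-cause death probabilities.

    Bands are closed integer-age intervals, contiguous and
    non-overlapping.
    """

    bands: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        bands = tuple(
            (int(lo), int(hi), _check_prob(f"mortality band {lo}-{hi}", p))
            for lo, hi, p in self.bands
        )
        if not bands:
            raise SchemaError("mortality table must have at least one band")
        for lo, hi, _ in bands:
            if hi < lo:
                raise SchemaError(f"mortality band {lo}-{hi} is inverted")
        for (_, hi_prev, _), (lo, _, _) in zip(bands, bands[1:]):
            if lo != hi_prev + 1:
                raise SchemaError(
                    f"mortality bands must be contiguous; gap/overlap at age {lo}"
                )
        object.__setattr__(self, "bands", bands)

    def annual_probability(self, age: float) -> float:
        """All-cause annual death probability for the band containing ``age``."""
        for lo, hi, p in self.bands:
            if lo <= age <= hi:
                return p
        raise KeyError(f"age {age} outside mortality table ({self.bands[0][0]}-{self.bands[-1][1]})")


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utility weights (1 = perfect health, 0 = death)."""

    u_disease_free: float
    u_local_recurrence: float
    u_metastasis: float

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_prob(f.name, getattr(self, f.name))

    def as_vector(self) -> tuple[float, float, float, float]:
        """Utilities in health-state matrix order (death = 0)."""
        return (self.u_disease_free, self.u_local_recurrence, self.u_metastasis, 0.0)


@dataclass(frozen=True)
class ModelConfig:
    """Run configuration: cohort, horizon, discounting and conventions."""

    cohort_size: float = 100
    start_age: int = 60
    horizon: int = 10
    cycle_length: float = 1.0
    discount_rate_benefits: float = 0.03
    discount_rate_costs: float = 0.03
    include_maintenance: bool = True
    conventions: ModelConventions = field(default_factory=ModelConventions)

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise SchemaError(f"horizon must be >= 1, got {self.horizon}")
        if self.cohort_size <= 0:
            raise SchemaError(f"cohort_size must be > 0, got {self.cohort_size}")
        for name in ("discount_rate_benefits", "discount_rate_costs"):
            r = getattr(self, name)
            if not 0.0 <= r < 1.0:
                raise SchemaError(f"{name} must be in [0, 1), got {r}")


class ParameterBundle(NamedTuple):
    """The full bundled parameter tuple: both arms, the one-way
    sensitivity variants of the IORT arm, background mortality,
    utilities, and the run configuration."""

    iort: ArmParameters
    imrt: ArmParameters
    iort_lower_recurrence: ArmParameters
    iort_lower_metastasis: ArmParameters
    mortality: MortalityTable
    utilities: UtilitySet
    config: ModelConfig


# ---------------------------------------------------------------------------
# config document <-> objects

_ARM_KEYS = {
    "p_local_recurrence",
    "p_bc_death",
    "p_metastasis_from_disease_free",
    "p_metastasis_from_local_recurrence",
    "cost_treatment",
    "cost_other_direct",
    "cost_annual_maintenance",
}
_CONFIG_KEYS = {
    "cohort_size",
    "start_age",
    "horizon",
    "cycle_length",
    "discount_rate_benefits",
    "discount_rate_costs",
    "include_maintenance",
}
_VARIANT_KEYS = {"lower_recurrence", "lower_metastasis"}


def _reject_unknown(section: str, mapping: dict, allowed: set) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise SchemaError(f"unknown key(s) in {section}: {sorted(unknown)}")


def _parse_arm(label: str, doc: dict, horizon: int) -> ArmParameters:
    if not isinstance(doc, dict):
        raise SchemaError(f"arm {label!r} must be a mapping")
    _reject_unknown(f"arms.{label}", doc, _ARM_KEYS)
    missing = _ARM_KEYS - set(doc) - {"cost_annual_maintenance"}
    if missing:
        raise SchemaError(f"arms.{label} missing key(s): {sorted(missing)}")
    arm = ArmParameters(arm_label=label, **{k: doc[k] for k in doc})
    if arm.horizon != horizon:
        raise SchemaError(
            f"arms.{label}: probability vectors have length {arm.horizon} "
            f"but config.horizon is {horizon}"
        )
    return arm


def load_parameters(
    source,
    sensitivity_source=None,
    conventions: ModelConventions | None = None,
) -> ParameterBundle:
    """Load and validate a parameter bundle from config documents.

    Parameters
    ----------
    source
        Path to a YAML/JSON document, or an already-parsed mapping, with
        sections ``arms`` (labels ``IORT``/``IMRT``), ``mortality``,
        ``utilities`` and ``config``.
    sensitivity_source
        Optional document with a ``variants`` section carrying the
        ``lower_recurrence`` and ``lower_metastasis`` overrides for the
        IORT arm.  When absent, the variants default to the base arm.
    conventions
        Modelling conventions to embed in the returned ``ModelConfig``
        (defaults to the calibrated convention set).
    """
    doc = _as_document(source)
    _reject_unknown("document", doc, {"arms", "mortality", "utilities", "config"})
    for section in ("arms", "mortality", "utilities", "config"):
        if section not in doc:
            raise SchemaError(f"missing section {section!r}")

    cfg_doc = dict(doc["config"])
    _reject_unknown("config", cfg_doc, _CONFIG_KEYS)
    config = ModelConfig(
        **cfg_doc, conventions=conventions if conventions else ModelConventions()
    )

    arms_doc = doc["arms"]
    _reject_unknown("arms", arms_doc, {"IORT", "IMRT"})
    if set(arms_doc) != {"IORT", "IMRT"}:
        raise SchemaError("arms section must define exactly IORT and IMRT")
    iort = _parse_arm("IORT", arms_doc["IORT"], config.horizon)
    imrt = _parse_arm("IMRT", arms_doc["IMRT"], config.horizon)

    bands = []
    for row in doc["mortality"]:
        _reject_unknown("mortality row", row, {"age_low", "age_high", "p"})
        bands.append((row["age_low"], row["age_high"], row["p"]))
    mortality = MortalityTable(bands=tuple(bands))

    util_doc = doc["utilities"]
    _reject_unknown("utilities", util_doc, {"disease_free", "local_recurrence", "metastasis"})
    utilities = UtilitySet(
        u_disease_free=util_doc["disease_free"],
        u_local_recurrence=util_doc["local_recurrence"],
        u_metastasis=util_doc["metastasis"],
    )

    lower_rec, lower_met = iort, iort
    if sensitivity_source is not None:
        sdoc = _as_document(sensitivity_source)
        _reject_unknown("sensitivity document", sdoc, {"variants"})
        variants = sdoc.get("variants", {})
        _reject_unknown("variants", variants, _VARIANT_KEYS)
        if "lower_recurrence" in variants:
            v = variants["lower_recurrence"]
            _reject_unknown("variants.lower_recurrence", v, _ARM_KEYS)
            lower_rec = iort.with_variant("IORT-lower-recurrence", **v)
        if "lower_metastasis" in variants:
            v = variants["lower_metastasis"]
            _reject_unknown("variants.lower_metastasis", v, _ARM_KEYS)
            lower_met = iort.with_variant("IORT-lower-metastasis", **v)

    return ParameterBundle(
        iort=iort,
        imrt=imrt,
        iort_lower_recurrence=lower_rec,
        iort_lower_metastasis=lower_met,
        mortality=mortality,
        utilities=utilities,
        config=config,
    )


def _as_document(source) -> dict:
    if isinstance(source, dict):
        return source
    with open(source, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise SchemaError(f"config document {source} is not a mapping")
    return doc


def serialize_parameters(bundle: ParameterBundle) -> dict:
    """Inverse of ``load_parameters`` for the base document
    (``load_parameters(serialize_parameters(b))`` reproduces the base
    arms, mortality, utilities and config of ``b``)."""

    def arm_doc(arm: ArmParameters) -> dict:
        return {
            "p_local_recurrence": list(arm.p_local_recurrence),
            "p_bc_death": list(arm.p_bc_death),
            "p_metastasis_from_disease_free": arm.p_metastasis_from_disease_free,
            "p_metastasis_from_local_recurrence": arm.p_metastasis_from_local_recurrence,
            "cost_treatment": arm.cost_treatment,
            "cost_other_direct": arm.cost_other_direct,
            "cost_annual_maintenance": arm.cost_annual_maintenance,
        }

    cfg = bundle.config
    return {
        "arms": {"IORT": arm_doc(bundle.iort), "IMRT": arm_doc(bundle.imrt)},
        "mortality": [
            {"age_low": lo, "age_high": hi, "p": p} for lo, hi, p in bundle.mortality.bands
        ],
        "utilities": {
            "disease_free": bundle.utilities.u_disease_free,
            "local_recurrence": bundle.utilities.u_local_recurrence,
            "metastasis": bundle.utilities.u_metastasis,
        },
        "config": {
            "cohort_size": cfg.cohort_size,
            "start_age": cfg.start_age,
            "horizon": cfg.horizon,
            "cycle_length": cfg.cycle_length,
            "discount_rate_benefits": cfg.discount_rate_benefits,
            "discount_rate_costs": cfg.discount_rate_costs,
            "include_maintenance": cfg.include_maintenance,
        },
    }


def builtin_table1(conventions: ModelConventions | None = None) -> ParameterBundle:
    """The bundled published parameter sets (base case plus the two
    one-way sensitivity variants of the IORT arm)."""
    data = importlib.resources.files("apbi_cea") / "data"
    return load_parameters(
        data / "table1_base.yaml",
        sensitivity_source=data / "table1_sensitivity.yaml",
        conventions=conventions,
    )


# ---------------------------------------------------------------------------
# validation report

@dataclass
class ValidationReport:
    """Collected parameter violations; empty means valid."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __iter__(self):
        return iter(self.violations)

    def __len__(self) -> int:
        return len(self.violations)


def validate_parameters(
    bundle_or_arm,
    config: ModelConfig | None = None,
    mortality: MortalityTable | None = None,
) -> ValidationReport:
    """Check model feasibility beyond per-field bounds.

    Flags, for every cycle and alive state, an outgoing-probability sum
    above 1 under the conventions in ``config``; also vector-length
    mismatches against the horizon and negative costs.  Reports rather
    than raises.
    """
    report = ValidationReport()
    if isinstance(bundle_or_arm, ParameterBundle):
        bundle = bundle_or_arm
        config = config or bundle.config
        mortality = mortality or bundle.mortality
        arms = [bundle.iort, bundle.imrt, bundle.iort_lower_recurrence,
                bundle.iort_lower_metastasis]
    else:
        arms = [bundle_or_arm]
        if config is None or mortality is None:
            raise TypeError("config and mortality are required for a single arm")

    from .conventions import ADDITIVE, HealthState  # local to avoid cycle at import

    conv = config.conventions
    for arm in arms:
        if arm.horizon != config.horizon:
            report.violations.append(
                f"{arm.arm_label}: probability vectors of length {arm.horizon} "
                f"!= horizon {config.horizon}"
            )
            continue
        for name in ("cost_treatment", "cost_other_direct", "cost_annual_maintenance"):
            if getattr(arm, name) < 0:
                report.violations.append(f"{arm.arm_label}: {name} negative")
        for cycle in range(1, config.horizon + 1):
            age = config.start_age + cycle - 1
            try:
                p_ac = mortality.annual_probability(age)
            except KeyError:
                report.violations.append(
                    f"{arm.arm_label}: no mortality band for age {age} (cycle {cycle})"
                )
                continue
            p_bc = arm.p_bc_death[cycle - 1]

            def p_death(state: HealthState) -> float:
                bc = p_bc if state in conv.bc_death_source_states else 0.0
                if conv.death_combination == ADDITIVE:
                    return bc + p_ac
                return 1.0 - (1.0 - bc) * (1.0 - p_ac)

            rows = {
                HealthState.DISEASE_FREE: (
                    arm.p_local_recurrence[cycle - 1]
                    + arm.p_metastasis_from_disease_free
                    + p_death(HealthState.DISEASE_FREE)
                ),
                HealthState.LOCAL_RECURRENCE: (
                    arm.p_metastasis_from_local_recurrence
                    + p_death(HealthState.LOCAL_RECURRENCE)
                ),
                HealthState.METASTASIS: p_death(HealthState.METASTASIS),
            }
            for state, total in rows.items():
                if total > 1.0:
                    report.violations.append(
                        f"{arm.arm_label}: outgoing probabilities from "
                        f"{state.name} sum to {total:.4f} > 1 at cycle {cycle}"
                    )
    return report
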