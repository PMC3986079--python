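"""Parameter definitions, validation, and I/O for the screening cost-utility model.

The default parameter set describes pre-prescription HLA-B*5801 genotyping for
Thai patients about to start allopurinol, from a societal perspective:

* epidemiology of allopurinol-induced SJS/TEN (marginal incidence, allele
  prevalence, case fatality, probability of chronic dry eye syndrome among
  survivors),
* the strength of the gene-disease association with its 95% CI,
* characteristics of the genotyping assay,
* one-time and annual costs in 2013 Thai baht (direct medical and direct
  non-medical), and
* utilities, life expectancy, discounting, cohort size and the national
  willingness-to-pay threshold.

Every quantity that is varied in sensitivity analysis carries a (min, max)
plausible range alongside its point value.  Parameters are exchanged as a
flat key-value document with dotted namespaces (``epidemiology.*``,
``costs.*``, ``utilities.*``, ``run.*``, ...), which maps one-to-one onto the
input table of the analysis and diffs cleanly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Dict, Mapping, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "ModelParameters",
    "default_parameters",
    "load_parameters",
    "parse_override",
    "THB_PER_USD",
    "DEFAULT_RANGES",
    "SEMANTIC_CLASS",
]

#: Fixed display conversion; USD is derived output only, never an input.
THB_PER_USD = 31.0

#: Plausible (min, max) range for every parameter varied in sensitivity
#: analysis.  For the association parameter the range is its 95% CI.
DEFAULT_RANGES: Dict[str, Tuple[float, float]] = {
    "incidence_sjs_ten": (0.00079, 0.00241),
    "prevalence_hla": (0.12, 0.18),
    "case_fatality": (0.0503, 0.1765),
    "prob_des": (0.2882, 0.4704),
    "odds_ratio": (19.15, 6336.88),
    "cost_sjs_management": (339.40, 129492.25),
    "cost_test": (800.0, 1200.0),
    "cost_drug_index_annual": (137.33, 823.99),
    "cost_drug_alt_annual": (1277.50, 2555.00),
    "cost_gout_annual": (149.0, 474254.0),
    "cost_des_annual": (3235.12, 4852.68),
    "cost_sjs_patient_transport": (121.54, 182.32),
    "cost_sjs_relative_transport": (824.07, 1236.10),
    "cost_sjs_relative_food": (303.55, 455.33),
    "cost_gout_transport_annual": (1004.09, 1385.16),
    "cost_gout_food_annual": (385.03, 495.08),
    "cost_des_transport_annual": (486.18, 729.26),
    "cost_des_food_annual": (179.09, 268.63),
    "utility_gout": (0.638, 0.736),
    "utility_gout_des": (0.40, 0.56),
    "discount_rate": (0.0, 0.06),
}

#: Semantic class of each uncertain quantity, used by the sensitivity module
#: to pick a sampling distribution (beta / gamma / lognormal).
SEMANTIC_CLASS: Dict[str, str] = {
    "incidence_sjs_ten": "probability",
    "prevalence_hla": "probability",
    "case_fatality": "probability",
    "prob_des": "probability",
    "sensitivity": "probability",
    "specificity": "probability",
    "odds_ratio": "association",
    "utility_gout": "utility",
    "utility_gout_des": "utility",
    "cost_sjs_management": "cost",
    "cost_test": "cost",
    "cost_drug_index_annual": "cost",
    "cost_drug_alt_annual": "cost",
    "cost_gout_annual": "cost",
    "cost_des_annual": "cost",
    "cost_sjs_patient_transport": "cost",
    "cost_sjs_relative_transport": "cost",
    "cost_sjs_relative_food": "cost",
    "cost_gout_transport_annual": "cost",
    "cost_gout_food_annual": "cost",
    "cost_des_transport_annual": "cost",
    "cost_des_food_annual": "cost",
}

_PROBABILITY_FIELDS = (
    "incidence_sjs_ten",
    "prevalence_hla",
    "case_fatality",
    "prob_des",
    "sensitivity",
    "specificity",
    "utility_gout",
    "utility_gout_des",
)

#: dotted config key -> model field
NAMESPACE_MAP: Dict[str, str] = {
    "epidemiology.incidence_sjs_ten": "incidence_sjs_ten",
    "epidemiology.prevalence_hla": "prevalence_hla",
    "epidemiology.case_fatality": "case_fatality",
    "epidemiology.prob_des": "prob_des",
    "association.odds_ratio": "odds_ratio",
    "association.or_ci_low": "or_ci_low",
    "association.or_ci_high": "or_ci_high",
    "test.sensitivity": "sensitivity",
    "test.specificity": "specificity",
    "costs.test": "cost_test",
    "costs.drug_index_annual": "cost_drug_index_annual",
    "costs.drug_alt_annual": "cost_drug_alt_annual",
    "costs.sjs_management": "cost_sjs_management",
    "costs.gout_annual": "cost_gout_annual",
    "costs.des_annual": "cost_des_annual",
    "costs.sjs_patient_transport": "cost_sjs_patient_transport",
    "costs.sjs_relative_transport": "cost_sjs_relative_transport",
    "costs.sjs_relative_food": "cost_sjs_relative_food",
    "costs.gout_transport_annual": "cost_gout_transport_annual",
    "costs.gout_food_annual": "cost_gout_food_annual",
    "costs.des_transport_annual": "cost_des_transport_annual",
    "costs.des_food_annual": "cost_des_food_annual",
    "utilities.gout": "utility_gout",
    "utilities.gout_des": "utility_gout_des",
    "outcomes.life_expectancy": "life_expectancy",
    "run.discount_rate": "discount_rate",
    "run.cohort_size": "cohort_size",
    "run.start_age": "start_age",
    "run.wtp_threshold": "wtp_threshold",
    "run.drug_cost_mode": "drug_cost_mode",
    "run.discounting": "discounting",
    "run.association_form": "association_form",
}

_FIELD_TO_KEY = {v: k for k, v in NAMESPACE_MAP.items()}


class ModelParameters(BaseModel):
    """Complete, validated input set for one model run.

    All probabilities and utilities live in [0, 1], all costs are
    non-negative 2013 THB, and every parameter that carries a range
    satisfies ``min <= point <= max``.  Unknown fields are rejected.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    # epidemiology
    incidence_sjs_ten: float = 0.0016
    prevalence_hla: float = 0.15
    case_fatality: float = 0.1134
    prob_des: float = 0.3760

    # gene-disease association (point estimate with 95% CI)
    odds_ratio: float = 348.33
    or_ci_low: float = 19.15
    or_ci_high: float = 6336.88

    # test characteristics
    sensitivity: float = 1.0
    specificity: float = 1.0

    # direct medical costs (THB, 2013)
    cost_test: float = 1000.0
    cost_drug_index_annual: float = 411.99
    cost_drug_alt_annual: float = 1277.50
    cost_sjs_management: float = 15440.275
    cost_gout_annual: float = 7512.0
    cost_des_annual: float = 4043.90

    # direct non-medical costs (THB, 2013)
    cost_sjs_patient_transport: float = 151.93
    cost_sjs_relative_transport: float = 1030.09
    cost_sjs_relative_food: float = 379.44
    cost_gout_transport_annual: float = 1194.63
    cost_gout_food_annual: float = 440.06
    cost_des_transport_annual: float = 607.72
    cost_des_food_annual: float = 223.86

    # outcomes
    utility_gout: float = 0.71
    utility_gout_des: float = 0.48
    life_expectancy: float = 42.7

    # run settings
    discount_rate: float = 0.03
    cohort_size: int = 1000
    start_age: float = 30.0
    wtp_threshold: float = 160000.0
    drug_cost_mode: str = "replicate_paper"
    discounting: str = "calibrated"
    association_form: str = "risk_ratio"

    #: per-field (min, max) used by sensitivity analysis; missing key = fixed
    ranges: Dict[str, Tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )

    @model_validator(mode="after")
    def _check_invariants(self) -> "ModelParameters":
        for name in _PROBABILITY_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        for name in type(self).model_fields:
            if name.startswith("cost_") and getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)!r}")
        if self.odds_ratio <= 0:
            raise ValueError(f"odds_ratio must be > 0, got {self.odds_ratio!r}")
        if not self.or_ci_low <= self.odds_ratio <= self.or_ci_high:
            raise ValueError(
                "odds_ratio CI must bracket the point estimate: "
                f"{self.or_ci_low!r} <= {self.odds_ratio!r} <= {self.or_ci_high!r}"
            )
        if not 0.0 <= self.discount_rate <= 0.10:
            raise ValueError(f"discount_rate must lie in [0, 0.10], got {self.discount_rate!r}")
        if self.life_expectancy <= 0:
            raise ValueError(f"life_expectancy must be > 0, got {self.life_expectancy!r}")
        if self.cohort_size < 1:
            raise ValueError(f"cohort_size must be >= 1, got {self.cohort_size!r}")
        if self.drug_cost_mode not in ("replicate_paper", "truthful"):
            raise ValueError(f"unknown drug_cost_mode {self.drug_cost_mode!r}")
        if self.discounting not in ("calibrated", "end_of_year", "beginning_of_year", "midyear"):
            raise ValueError(f"unknown discounting convention {self.discounting!r}")
        if self.association_form not in ("risk_ratio", "odds_ratio"):
            raise ValueError(f"unknown association_form {self.association_form!r}")
        for name, rng in self.ranges.items():
            if name == "odds_ratio":
                point = self.odds_ratio
            elif name not in type(self).model_fields or name == "ranges":
                raise ValueError(f"range given for unknown parameter {name!r}")
            else:
                point = getattr(self, name)
            lo, hi = rng
            if not lo <= point <= hi:
                raise ValueError(
                    f"range for {name!r} must bracket its point value: "
                    f"{lo!r} <= {point!r} <= {hi!r}"
                )
        return self

    # ------------------------------------------------------------------ I/O

    def to_flat_dict(self) -> Dict[str, Any]:
        """Dotted-key representation mirroring the config file layout."""
        out: Dict[str, Any] = {}
        for key, field in NAMESPACE_MAP.items():
            out[key] = getattr(self, field)
        out["ranges"] = {k: list(v) for k, v in sorted(self.ranges.items())}
        return out

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_flat_dict(), sort_keys=True)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_flat_dict(), indent=indent, sort_keys=True)

    def replace(self, **updates: Any) -> "ModelParameters":
        """Return a re-validated copy with ``updates`` applied."""
        data = self.model_dump()
        data.update(updates)
        return ModelParameters(**data)


def default_parameters() -> ModelParameters:
    """The base-case parameter set (every field at its tabulated value)."""
    return ModelParameters()


def _flatten(mapping: Mapping[str, Any], prefix: str = "") -> Dict[str, Any]:
    flat: Dict[str, Any] = {}
    for key, value in mapping.items():
        dotted = f"{prefix}{key}"
        if isinstance(value, Mapping) and dotted != "ranges":
            flat.update(_flatten(value, prefix=f"{dotted}."))
        else:
            flat[dotted] = value
    return flat


def load_parameters(source: Any = None, overrides: Optional[Mapping[str, Any]] = None) -> ModelParameters:
    """Load a parameter set from a config document.

    ``source`` may be ``None`` (pure defaults), a :class:`~pathlib.Path` to a
    YAML file, a YAML string, or an already-parsed mapping.  Keys use dotted
    namespaces (``epidemiology.prevalence_hla: 0.12``) or equivalent nesting;
    unknown keys raise ``ValueError``.  Any omitted field keeps its base-case
    default.  ``overrides`` (dotted key -> value) are applied last.
    """
    if source is None:
        raw: Dict[str, Any] = {}
    elif isinstance(source, Path):
        raw = yaml.safe_load(source.read_text()) or {}
    elif isinstance(source, str):
        parsed = yaml.safe_load(source)
        raw = parsed or {}
    elif isinstance(source, Mapping):
        raw = dict(source)
    else:
        raise TypeError(f"cannot load parameters from {type(source).__name__}")
    if not isinstance(raw, Mapping):
        raise ValueError("parameter document must be a key-value mapping")

    flat = _flatten(raw)
    if overrides:
        flat.update(overrides)

    kwargs: Dict[str, Any] = {}
    for dotted, value in flat.items():
        if dotted == "ranges":
            if not isinstance(value, Mapping):
                raise ValueError("'ranges' must map parameter names to [min, max]")
            kwargs["ranges"] = {k: tuple(v) for k, v in value.items()}
        elif dotted in NAMESPACE_MAP:
            kwargs[NAMESPACE_MAP[dotted]] = value
        elif dotted in ModelParameters.model_fields and dotted != "ranges":
            # bare field names are accepted as a convenience
            kwargs[dotted] = value
        else:
            raise ValueError(f"unknown parameter key {dotted!r}")

    # an explicit point override wins over the stored sensitivity range:
    # widen the range (and the association CI) to keep bracketing invariants
    ranges = dict(kwargs.get("ranges", DEFAULT_RANGES))
    for name, value in kwargs.items():
        if name in ranges and isinstance(value, (int, float)):
            lo, hi = ranges[name]
            ranges[name] = (min(lo, value), max(hi, value))
    if "odds_ratio" in kwargs and isinstance(kwargs["odds_ratio"], (int, float)):
        point = kwargs["odds_ratio"]
        kwargs.setdefault("or_ci_low", min(19.15, point))
        kwargs.setdefault("or_ci_high", max(6336.88, point))
    kwargs["ranges"] = ranges
    return ModelParameters(**kwargs)


def parse_override(text: str) -> Tuple[str, Any]:
    """Parse one ``key=value`` CLI override into a (dotted key, value) pair."""
    if "=" not in text:
        raise ValueError(f"override must have the form key=value, got {text!r}")
    key, _, raw = text.partition("=")
    key = key.strip()
    raw = raw.strip()
    try:
        value: Any = int(raw)
    except ValueError:
        try:
            value = float(raw)
        except ValueError:
            value = raw
    return key, value
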