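"""One-way, scenario, and probabilistic sensitivity analysis.

One-way analysis re-runs the full deterministic pipeline at the low and
high end of a parameter's plausible range and reports both ICERs; sweeping
every ranged parameter yields the tornado table.

The probabilistic sensitivity analysis (PSA) is a second-order Monte Carlo:
each uncertain parameter receives a distribution fitted to its point value
and range, all parameters are drawn independently each iteration, the full
two-strategy pipeline is run, and the incremental cost/QALY pair is
recorded.  Distribution families follow standard health-economic practice:

* beta for probabilities and utilities (bounded in [0, 1]),
* gamma for costs (non-negative),
* lognormal for the gene-disease association parameter, and
* a degenerate ``fixed`` family when no range is given.

Ranges are read as central 95% intervals, so the implied standard deviation
is ``(max - min) / (2 * 1.96)``; beta and gamma are moment-matched to the
point value and that SD, and the lognormal takes the point as its log-scale
location (median) with ``sigma = ln(max/min) / (2 * 1.96)``.

Net monetary benefit ``NMB = lambda * dQALY - dCost`` is evaluated on a
willingness-to-pay grid; the cost-effectiveness acceptability curve (CEAC)
at each threshold is the fraction of iterations with strictly positive NMB.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohort import CEResult, compare_strategies, expected_events, run_cohort
from .parameters import DEFAULT_RANGES, SEMANTIC_CLASS, ModelParameters

__all__ = [
    "TornadoEntry",
    "DistributionSpec",
    "PSAResult",
    "one_way",
    "tornado",
    "scenario",
    "assign_distribution",
    "parameter_distributions",
    "run_psa",
    "DEFAULT_LAMBDA_GRID",
]

logger = logging.getLogger(__name__)

#: WTP grid for the CEAC: 0 to 500,000 THB/QALY in 5,000 THB steps.
DEFAULT_LAMBDA_GRID = np.arange(0.0, 500001.0, 5000.0)

#: Parameters that a one-way analysis may vary (anything with a range);
#: structural run settings are excluded.
_NOT_ONE_WAY = {"cohort_size", "start_age", "wtp_threshold", "life_expectancy"}

#: Parameters held fixed in the PSA even though ranged: the discount rate is
#: a policy convention, not a sampling uncertainty.
_PSA_FIXED = {"discount_rate"}


@dataclass(frozen=True)
class TornadoEntry:
    parameter_name: str
    low_value: float
    high_value: float
    icer_at_low: Optional[float]
    icer_at_high: Optional[float]

    @property
    def bar_width(self) -> float:
        if self.icer_at_low is None or self.icer_at_high is None:
            return math.inf
        return abs(self.icer_at_high - self.icer_at_low)


def _pipeline_ce(params: ModelParameters) -> CEResult:
    usual = run_cohort(params, expected_events(params, "usual_care"), build_trace=False)
    testing = run_cohort(
        params, expected_events(params, "genetic_testing"), build_trace=False
    )
    return compare_strategies(testing, usual, params.wtp_threshold)


def one_way(
    params: ModelParameters,
    parameter_name: str,
    low: Optional[float] = None,
    high: Optional[float] = None,
) -> TornadoEntry:
    """Recompute the full pipeline at the low and high value of one parameter.

    ``low``/``high`` default to the parameter's stored range.  Structural
    settings (cohort size, starting age, threshold, horizon) are not
    one-way-variable and raise ``ValueError``.
    """
    if parameter_name in _NOT_ONE_WAY or parameter_name not in ModelParameters.model_fields:
        raise ValueError(f"{parameter_name!r} is not a one-way-variable parameter")
    if low is None or high is None:
        rng = params.ranges.get(parameter_name)
        if rng is None:
            raise ValueError(f"{parameter_name!r} has no stored range and none was given")
        low = rng[0] if low is None else low
        high = rng[1] if high is None else high
    if low > high:
        raise ValueError(f"low {low!r} exceeds high {high!r}")
    ce_low = _pipeline_ce(_with_value(params, parameter_name, low))
    ce_high = _pipeline_ce(_with_value(params, parameter_name, high))
    return TornadoEntry(
        parameter_name=parameter_name,
        low_value=low,
        high_value=high,
        icer_at_low=ce_low.icer,
        icer_at_high=ce_high.icer,
    )


def _with_value(params: ModelParameters, name: str, value: float) -> ModelParameters:
    ranges = dict(params.ranges)
    if name in ranges:
        lo, hi = ranges[name]
        ranges[name] = (min(lo, value), max(hi, value))
    return params.replace(**{name: value, "ranges": ranges})


def tornado(
    params: ModelParameters, parameters: Optional[Iterable[str]] = None
) -> pd.DataFrame:
    """One-way sweep over every ranged parameter, sorted by bar width."""
    names = list(parameters) if parameters is not None else sorted(params.ranges)
    entries = [one_way(params, name) for name in names]
    df = pd.DataFrame(
        {
            "parameter": [e.parameter_name for e in entries],
            "low_value": [e.low_value for e in entries],
            "high_value": [e.high_value for e in entries],
            "icer_at_low": [e.icer_at_low for e in entries],
            "icer_at_high": [e.icer_at_high for e in entries],
            "bar_width": [e.bar_width for e in entries],
        }
    )
    return df.sort_values("bar_width", ascending=False, ignore_index=True)


def scenario(params: ModelParameters, overrides: Mapping[str, float]) -> CEResult:
    """Full pipeline under overridden parameters.

    Overriding ``start_age`` requires an accompanying ``life_expectancy``
    override, since remaining life expectancy at other ages is an external
    input the model cannot infer.
    """
    if "start_age" in overrides and "life_expectancy" not in overrides:
        raise ValueError(
            "overriding start_age requires a matching life_expectancy override"
        )
    new = params
    for name, value in overrides.items():
        new = _with_value(new, name, value)
    return _pipeline_ce(new)


# --------------------------------------------------------------------- PSA


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution fitted to a point value and plausible range."""

    family: str  # beta | gamma | lognormal | fixed
    params: Tuple[float, ...]
    source_point: float
    source_range: Tuple[float, float]

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "fixed":
            return np.full(size, self.source_point)
        if self.family == "beta":
            a, b = self.params
            return rng.beta(a, b, size)
        if self.family == "gamma":
            shape, scale = self.params
            return rng.gamma(shape, scale, size)
        if self.family == "lognormal":
            mu, sigma = self.params
            return rng.lognormal(mu, sigma, size)
        raise ValueError(f"unknown family {self.family!r}")

    def mean(self) -> float:
        if self.family == "beta":
            a, b = self.params
            return a / (a + b)
        if self.family == "gamma":
            shape, scale = self.params
            return shape * scale
        if self.family == "lognormal":
            mu, sigma = self.params
            return math.exp(mu + sigma**2 / 2.0)
        return self.source_point


def assign_distribution(
    point: float, low: float, high: float, semantic_class: str
) -> DistributionSpec:
    """Fit the class-appropriate distribution to a point and 95% range.

    Beta (probability/utility) and gamma (cost) are moment-matched so the
    fitted mean equals ``point`` with SD ``(high - low)/3.92``; the
    association parameter is lognormal with median ``point``.  A degenerate
    range returns the ``fixed`` family.  An infeasible beta SD (larger than
    the maximum a beta with that mean supports) is clipped with a warning.
    """
    if not low <= point <= high:
        raise ValueError(f"need low <= point <= high, got {low!r}, {point!r}, {high!r}")
    rng = (low, high)
    if low == high:
        return DistributionSpec("fixed", (), point, rng)
    sd = (high - low) / (2.0 * 1.96)
    if semantic_class in ("probability", "utility"):
        var = sd**2
        max_var = point * (1.0 - point)
        if var >= max_var:
            logger.warning(
                "beta fit for point %g: implied SD %g infeasible, clipping variance",
                point,
                sd,
            )
            var = 0.999 * max_var
        nu = point * (1.0 - point) / var - 1.0
        return DistributionSpec("beta", (point * nu, (1.0 - point) * nu), point, rng)
    if semantic_class == "cost":
        return DistributionSpec("gamma", ((point / sd) ** 2, sd**2 / point), point, rng)
    if semantic_class == "association":
        sigma = math.log(high / low) / (2.0 * 1.96)
        return DistributionSpec("lognormal", (math.log(point), sigma), point, rng)
    raise ValueError(f"unknown semantic class {semantic_class!r}")


def parameter_distributions(params: ModelParameters) -> Dict[str, DistributionSpec]:
    """Distributions for every PSA-variable parameter, keyed by field name."""
    specs: Dict[str, DistributionSpec] = {}
    for name in sorted(params.ranges):
        if name in _PSA_FIXED:
            continue
        low, high = params.ranges[name]
        point = getattr(params, name)
        specs[name] = assign_distribution(point, low, high, SEMANTIC_CLASS[name])
    return specs


@dataclass
class PSAResult:
    """Draws, incremental pairs, CEAC and summary of one PSA run."""

    draws: pd.DataFrame
    ce_points: pd.DataFrame  # columns delta_cost, delta_qaly, nmb_at_threshold
    ceac: pd.DataFrame  # columns wtp, prob_cost_effective
    prob_ce_at_threshold: float
    wtp_threshold: float
    seed: int
    n_iterations: int
    n_rejected: int


def _draw_valid(params: ModelParameters, row: Dict[str, float]) -> bool:
    """Cheap feasibility check for one PSA draw (no pydantic round trip)."""
    for name in ("incidence_sjs_ten", "prevalence_hla", "case_fatality", "prob_des"):
        if not 0.0 < row.get(name, getattr(params, name)) < 1.0:
            return False
    for name in ("utility_gout", "utility_gout_des"):
        if not 0.0 <= row.get(name, getattr(params, name)) <= 1.0:
            return False
    if row.get("odds_ratio", params.odds_ratio) <= 0.0:
        return False
    ia = row.get("incidence_sjs_ten", params.incidence_sjs_ten)
    p = row.get("prevalence_hla", params.prevalence_hla)
    assoc = row.get("odds_ratio", params.odds_ratio)
    if params.association_form == "risk_ratio":
        if assoc * ia / ((1.0 - p) + p * assoc) > 1.0:
            return False
    return True


def run_psa(
    params: ModelParameters,
    n_iterations: int = 10000,
    seed: int = 20140414,
    lambda_grid: Optional[Sequence[float]] = None,
    distributions: Optional[Mapping[str, DistributionSpec]] = None,
) -> PSAResult:
    """Second-order Monte Carlo over all uncertain parameters.

    Each iteration samples every uncertain parameter independently from its
    :class:`DistributionSpec`, runs both strategies, and records the
    incremental cost/QALY pair.  Pathological draws (e.g. an infeasible
    incidence/prevalence/association triple) are rejected and resampled,
    with the count reported.  Identical seeds give identical output.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    grid = np.asarray(lambda_grid if lambda_grid is not None else DEFAULT_LAMBDA_GRID, dtype=float)
    specs = dict(distributions) if distributions is not None else parameter_distributions(params)
    names = sorted(specs)
    rng = np.random.default_rng(seed)

    # one vectorised draw per parameter, in sorted-name order
    samples = {name: specs[name].sample(rng, n_iterations) for name in names}

    # odds_ratio draws must stay inside a CI bracketing them; keep validation
    # happy by widening the CI to the sampled support when needed.
    or_low, or_high = params.or_ci_low, params.or_ci_high

    delta_cost = np.empty(n_iterations)
    delta_qaly = np.empty(n_iterations)
    n_rejected = 0
    for i in range(n_iterations):
        row = {name: float(samples[name][i]) for name in names}
        while not _draw_valid(params, row):
            n_rejected += 1
            row = {name: float(specs[name].sample(rng, 1)[0]) for name in names}
        update: Dict[str, object] = dict(row)
        if "odds_ratio" in row:
            update["or_ci_low"] = min(or_low, row["odds_ratio"])
            update["or_ci_high"] = max(or_high, row["odds_ratio"])
        drawn = params.model_copy(update=update)
        ce = _pipeline_ce(drawn)
        delta_cost[i] = ce.delta_cost
        delta_qaly[i] = ce.delta_qaly
        samples_i = row
        for name in names:
            samples[name][i] = samples_i[name]
    if n_rejected:
        logger.info("PSA rejected and resampled %d pathological draws", n_rejected)

    nmb_threshold = params.wtp_threshold * delta_qaly - delta_cost
    ceac_probs = [
        float(np.mean(lam * delta_qaly - delta_cost > 0.0)) for lam in grid
    ]
    draws = pd.DataFrame({name: samples[name] for name in names})
    draws.insert(0, "iteration", np.arange(1, n_iterations + 1))
    ce_points = pd.DataFrame(
        {
            "iteration": np.arange(1, n_iterations + 1),
            "delta_cost": delta_cost,
            "delta_qaly": delta_qaly,
            "nmb_at_threshold": nmb_threshold,
        }
    )
    ceac = pd.DataFrame({"wtp": grid, "prob_cost_effective": ceac_probs})
    return PSAResult(
        draws=draws,
        ce_points=ce_points,
        ceac=ceac,
        prob_ce_at_threshold=float(np.mean(nmb_threshold > 0.0)),
        wtp_threshold=params.wtp_threshold,
        seed=seed,
        n_iterations=n_iterations,
        n_rejected=n_rejected,
    )
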