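"""Patient-level microsimulation oracle and synthetic parameter-set generator.

The cohort model is an expectation; this module realises the same decision
tree stochastically, one Bernoulli patient at a time, using identical
costing/discounting conventions.  By the law of large numbers its mean
outcomes must converge to the cohort model's closed-form values, which makes
it the package's principal independent verification oracle.  It also
generates randomised but internally consistent parameter sets for
property-based testing of every pipeline stage.

Draw order per run (single seeded stream, vectorised): genotype, test
result, SJS/TEN event, death, DES.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np

from .cohort import cycle_weights
from .parameters import ModelParameters
from .risk import incidence_split

__all__ = [
    "MicrosimSummary",
    "SyntheticParameterSet",
    "simulate_patients",
    "generate_parameter_sets",
]


@dataclass
class MicrosimSummary:
    """Monte Carlo means, standard errors and event rates for one strategy."""

    strategy: str
    n: int
    seed: int
    mean_cost: float
    se_cost: float
    mean_qaly: float
    se_qaly: float
    cost_category_means: Dict[str, float]
    cost_category_ses: Dict[str, float]
    sjs_rate: float
    death_rate: float
    des_rate: float
    frac_on_alt_drug: float

    def to_dict(self) -> Dict[str, object]:
        return {
            "strategy": self.strategy,
            "n": self.n,
            "seed": self.seed,
            "mean_cost": self.mean_cost,
            "se_cost": self.se_cost,
            "mean_qaly": self.mean_qaly,
            "se_qaly": self.se_qaly,
            "cost_category_means": self.cost_category_means,
            "cost_category_ses": self.cost_category_ses,
            "sjs_rate": self.sjs_rate,
            "death_rate": self.death_rate,
            "des_rate": self.des_rate,
            "frac_on_alt_drug": self.frac_on_alt_drug,
        }


def simulate_patients(
    params: ModelParameters, strategy: str, n: int, seed: int
) -> MicrosimSummary:
    """Simulate ``n`` independent patients under one strategy.

    Per patient: genotype ~ Bernoulli(P); test result via (S, Sp) if the
    strategy tests; drug assignment by the strategy rule (positives get the
    alternative drug, which carries zero SJS/TEN risk); SJS/TEN ~
    Bernoulli(i1, i0 or 0); death ~ Bernoulli(case fatality) among cases;
    DES ~ Bernoulli(prob_des) among survivors.  Discounted costs and QALYs
    accrue per patient with the same conventions (and the same drug-cost
    mode) as the cohort model.  Identical seeds give identical summaries.
    """
    if strategy not in ("usual_care", "genetic_testing"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    split = incidence_split(
        params.incidence_sjs_ten,
        params.prevalence_hla,
        params.odds_ratio,
        form=params.association_form,
    )

    carrier = rng.random(n) < params.prevalence_hla
    test_draw = rng.random(n)
    if strategy == "genetic_testing":
        positive = np.where(
            carrier, test_draw < params.sensitivity, test_draw >= params.specificity
        )
        on_alt = positive
    else:
        on_alt = np.zeros(n, dtype=bool)

    p_sjs = np.where(on_alt, 0.0, np.where(carrier, split.i1, split.i0))
    sjs = rng.random(n) < p_sjs
    died = sjs & (rng.random(n) < params.case_fatality)
    des = sjs & ~died & (rng.random(n) < params.prob_des)

    weights = cycle_weights(params.discount_rate, params.life_expectancy, params.discounting)
    A = float(weights.sum())
    A_from_2 = A - float(weights[0])
    alive = ~died

    u_g, u_gd = params.utility_gout, params.utility_gout_des
    qaly = np.where(alive, np.where(des, u_gd, u_g) * A, 0.0)

    testing = strategy == "genetic_testing"
    c_idx, c_alt = params.cost_drug_index_annual, params.cost_drug_alt_annual
    costs: Dict[str, np.ndarray] = {}
    costs["test"] = np.full(n, params.cost_test) if testing else np.zeros(n)
    if params.drug_cost_mode == "truthful":
        base_annual = np.where(on_alt, c_alt, c_idx)
    else:  # replicate_paper: every patient priced at the index drug
        base_annual = np.full(n, c_idx)
    drug = np.where(alive, base_annual * A, 0.0)
    # SJS/TEN survivors move to the alternative drug from cycle 2
    drug = drug + np.where(sjs & alive, (c_alt - c_idx) * A_from_2, 0.0)
    costs["drug"] = drug
    costs["sjs_management"] = np.where(sjs, params.cost_sjs_management, 0.0)
    costs["gout_management"] = np.where(alive, params.cost_gout_annual * A, 0.0)
    costs["des_management"] = np.where(des, params.cost_des_annual * A, 0.0)
    costs["sjs_nonmedical"] = np.where(
        sjs,
        params.cost_sjs_patient_transport
        + params.cost_sjs_relative_transport
        + params.cost_sjs_relative_food,
        0.0,
    )
    costs["gout_nonmedical"] = np.where(
        alive,
        (params.cost_gout_transport_annual + params.cost_gout_food_annual) * A,
        0.0,
    )
    costs["des_nonmedical"] = np.where(
        des,
        (params.cost_des_transport_annual + params.cost_des_food_annual) * A,
        0.0,
    )
    total = sum(costs.values())

    def _se(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")

    return MicrosimSummary(
        strategy=strategy,
        n=n,
        seed=seed,
        mean_cost=float(total.mean()),
        se_cost=_se(total),
        mean_qaly=float(qaly.mean()),
        se_qaly=_se(qaly),
        cost_category_means={k: float(v.mean()) for k, v in costs.items()},
        cost_category_ses={k: _se(v) for k, v in costs.items()},
        sjs_rate=float(sjs.mean()),
        death_rate=float(died.mean()),
        des_rate=float(des.mean()),
        frac_on_alt_drug=float(on_alt.mean()),
    )


@dataclass
class SyntheticParameterSet:
    """A randomised, internally consistent parameter set and its provenance."""

    params: ModelParameters
    seed: int
    index: int
    perturbation_scale: float


def generate_parameter_sets(
    n: int, seed: int, perturbation_scale: float = 1.0
) -> List[SyntheticParameterSet]:
    """Draw ``n`` valid parameter sets around the base case.

    Each ranged parameter moves uniformly within ``perturbation_scale``
    times the distance from its point value to its range ends, so every set
    respects ``min <= point <= max`` and all domain invariants by
    construction.  ``perturbation_scale = 0`` returns exact base cases.
    Regenerable from ``(n, seed, perturbation_scale)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= perturbation_scale <= 1.0:
        raise ValueError("perturbation_scale must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    base = ModelParameters()
    out: List[SyntheticParameterSet] = []
    for i in range(n):
        updates: Dict[str, float] = {}
        for name in sorted(base.ranges):
            low, high = base.ranges[name]
            point = getattr(base, name)
            u = rng.uniform(-1.0, 1.0)
            if u >= 0.0:
                value = point + perturbation_scale * u * (high - point)
            else:
                value = point + perturbation_scale * u * (point - low)
            updates[name] = value
        params = base.replace(**updates)
        out.append(
            SyntheticParameterSet(
                params=params, seed=seed, index=i, perturbation_scale=perturbation_scale
            )
        )
    return out
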