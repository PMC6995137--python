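"""Sensitivity of the analysis to bias in the observational relative risk.

The relative risk of re-graft comes from a non-randomised before/after
comparison, so it may be systematically biased.  Each scenario places a
multiplicative lognormal bias term on the relative risk, specified — like the
relative risk itself — by a median and 95% interval.  Per iteration the model
uses ``RR_used = RR_base x bias``; the bias term is sampled as a parameter in
its own right so its value of information is estimable, and the EVPPI
reported for "RR" under a scenario refers to the bias-adjusted relative risk
actually driving the decision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import voi as _voi
from .model import DecisionTreeModel
from .parameters import ParameterDraws, ParameterSpec, ParameterSpecSet, lognormal_from_median_ci
from .tree import ModelConfig

__all__ = ["BiasScenario", "DEFAULT_SCENARIOS", "bias_spec", "adjusted_rr", "BiasScenarioAnalysis", "run_scenarios"]

#: EVPPI columns of the headline scenario table (the full per-parameter set is
#: also computed; these four are the headline columns).
HEADLINE_EVPPI = ("bias", "rr", "p_regraft_lf", "c_regraft")


@dataclass(frozen=True)
class BiasScenario:
    """A multiplicative lognormal bias on the relative risk.

    ``bias_median`` and ``bias_ci`` give the median and equal-tailed 95%
    interval of the bias factor; medians below 1 shift the adjusted relative
    risk in favour of low-friction bedding.  The face-value case is the
    degenerate (1, (1, 1)) scenario.
    """

    label: str
    bias_median: float
    bias_ci: tuple[float, float]
    note: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.bias_ci
        if not (0 < lo <= self.bias_median <= hi):
            raise ValueError(
                f"scenario {self.label!r}: require 0 < lo <= median <= hi, "
                f"got median={self.bias_median}, ci={self.bias_ci}"
            )


#: The seven standard scenarios: no/downward/upward median bias crossed with
#: high and low uncertainty, plus the face-value base case.
DEFAULT_SCENARIOS = (
    BiasScenario("face_value", 1.00, (1.00, 1.00), "base case, evidence at face value"),
    BiasScenario("no_bias_high_uncertainty", 1.00, (0.47, 1.88)),
    BiasScenario("favour_lf_high_uncertainty", 0.80, (0.29, 1.76)),
    BiasScenario("against_lf_high_uncertainty", 1.20, (0.65, 2.03)),
    BiasScenario("no_bias_low_uncertainty", 1.00, (0.74, 1.31)),
    BiasScenario("favour_lf_low_uncertainty", 0.80, (0.55, 1.13)),
    BiasScenario("against_lf_low_uncertainty", 1.20, (0.94, 1.51)),
)


def bias_spec(scenario: BiasScenario) -> ParameterSpec:
    """Lognormal spec of the scenario's bias factor (point mass at 1 when the
    interval is degenerate)."""
    lo, hi = scenario.bias_ci
    if lo == hi == scenario.bias_median:
        return ParameterSpec(name="bias", family="point", value=scenario.bias_median, units="ratio")
    spec = lognormal_from_median_ci(scenario.bias_median, lo, hi, name="bias", units="ratio")
    return spec


def adjusted_rr(rr_spec: ParameterSpec, bias: ParameterSpec) -> ParameterSpec:
    """Distribution of the product of an independent lognormal relative risk
    and lognormal bias: meanlogs add, variances add on the log scale.

    Point masses are treated as lognormals with sdlog 0.
    """
    def _as_lognormal(spec: ParameterSpec) -> tuple[float, float]:
        if spec.family == "lognormal":
            return spec.shape_a, spec.shape_b
        if spec.family == "point":
            if spec.value <= 0:
                raise ValueError(f"point mass {spec.name!r} must be positive for a log product")
            return math.log(spec.value), 0.0
        raise TypeError(f"{spec.name!r}: expected lognormal or point, got {spec.family!r}")

    mu1, s1 = _as_lognormal(rr_spec)
    mu2, s2 = _as_lognormal(bias)
    return ParameterSpec(
        name=rr_spec.name or "rr",
        family="lognormal",
        shape_a=mu1 + mu2,
        shape_b=math.hypot(s1, s2),
        units=rr_spec.units,
    )


class BiasScenarioAnalysis:
    """Run the PSA and value-of-information analysis under each bias scenario.

    Per scenario: the bias term is added to the sampled parameters, the
    per-iteration relative risk is multiplied by the bias draw, and the model
    is re-fit with a scenario-specific seed (``base seed + scenario index``)
    so each row of the scenario table is individually reproducible.
    """

    def __init__(
        self,
        spec_set: ParameterSpecSet,
        scenarios=DEFAULT_SCENARIOS,
        config: ModelConfig | None = None,
        pop_config: _voi.PopulationConfig | None = None,
    ):
        self.spec_set = spec_set
        self.scenarios = tuple(scenarios)
        if not self.scenarios:
            raise ValueError("need at least one scenario")
        self.config = config or ModelConfig()
        self.pop_config = pop_config or _voi.PopulationConfig()

    def run_one(
        self,
        scenario: BiasScenario,
        n_iter: int = 50_000,
        seed: int = 1,
        basis_df: int = 6,
        evppi_samples: int = 10_000,
    ) -> dict:
        b_spec = bias_spec(scenario)
        specs = self.spec_set.add(b_spec)
        model = DecisionTreeModel(specs, self.config)
        draws = specs.sample(n_iter, seed)
        values = draws.values.copy()
        values["rr"] = values["rr"] * values["bias"]
        results = model.evaluate(ParameterDraws(values=values, seed=seed))

        s = results.summary()
        rr_adj = adjusted_rr(self.spec_set["rr"], b_spec)
        rr_lo, rr_hi = np.atleast_1d(rr_adj.quantile([0.025, 0.975]))
        pop = _voi.discounted_population(self.pop_config)
        evppi = results.evppi_all(basis_df=basis_df, n_samples=evppi_samples)
        evpi_pp = results.evpi()

        row = {
            "scenario": scenario.label,
            "bias_median": scenario.bias_median,
            "bias_lo": scenario.bias_ci[0],
            "bias_hi": scenario.bias_ci[1],
            "rr_median": rr_adj.median(),
            "rr_lo": float(rr_lo),
            "rr_hi": float(rr_hi),
            "inb_mean": s["inb"]["mean"],
            "inb_lo": s["inb"]["ci_lo"],
            "inb_hi": s["inb"]["ci_hi"],
            "prob_cost_effective": s.prob_cost_effective,
            "evpi": evpi_pp,
            "evpi_population": _voi.population_voi(evpi_pp, pop),
            "evppi_rr_population": _voi.population_voi(evppi.get("rr", 0.0), pop),
            "seed": seed,
        }
        for name, value in evppi.sort_index().items():
            row[f"evppi_{name}"] = value
        return row

    def run(
        self,
        n_iter: int = 50_000,
        seed: int = 1,
        basis_df: int = 6,
        evppi_samples: int = 10_000,
    ) -> pd.DataFrame:
        rows = [
            self.run_one(sc, n_iter=n_iter, seed=seed + i, basis_df=basis_df,
                         evppi_samples=evppi_samples)
            for i, sc in enumerate(self.scenarios)
        ]
        front = [
            "scenario", "bias_median", "bias_lo", "bias_hi", "rr_median", "rr_lo", "rr_hi",
            "inb_mean", "inb_lo", "inb_hi", "prob_cost_effective", "evpi",
        ] + [f"evppi_{p}" for p in HEADLINE_EVPPI] + ["evpi_population", "evppi_rr_population"]
        df = pd.DataFrame(rows)
        rest = [c for c in df.columns if c not in front]
        return df[front + rest].set_index("scenario")


def run_scenarios(
    spec_set: ParameterSpecSet,
    scenarios=DEFAULT_SCENARIOS,
    config: ModelConfig | None = None,
    pop_config: _voi.PopulationConfig | None = None,
    n_iter: int = 50_000,
    seed: int = 1,
    **kwargs,
) -> pd.DataFrame:
    """Functional wrapper around :class:`BiasScenarioAnalysis`."""
    return BiasScenarioAnalysis(spec_set, scenarios, config, pop_config).run(
        n_iter=n_iter, seed=seed, **kwargs
    )
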