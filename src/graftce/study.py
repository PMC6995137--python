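"""Synthetic patient-level before/after study data and parameter estimation.

The model's inputs derive from a two-period feasibility study: a
retrospective "before" period on standard bedding and a prospective "after"
period on low-friction bedding.  This module generates patient records with
that statistical structure — Bernoulli re-graft indicators by period,
lognormal inpatient costs stratified by re-graft status, and beta-distributed
EQ-5D utilities at baseline and day 28 (day-28 stratified by re-graft status,
observed only for the subset of after-period patients who complete
questionnaires) — and estimates a full parameter spec set back from the
records.  Generating at known truth and re-estimating is the package's
parameter-recovery test surface, and :func:`end_to_end` chains
generate -> estimate -> PSA -> VOI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import voi as _voi
from .model import DecisionTreeModel, PSAResults
from .parameters import ParameterSpec, ParameterSpecSet
from .tree import ModelConfig

__all__ = [
    "StudyConfig",
    "generate_study",
    "estimate_regraft_beta",
    "estimate_rr_lognormal",
    "estimate_cost_lognormal",
    "estimate_utility_beta",
    "estimate_spec_set",
    "end_to_end",
]

#: CSV column dictionary for generated records.
RECORD_COLUMNS = {
    "id": "patient identifier",
    "period": "'before' (standard bedding) or 'after' (low-friction)",
    "regraft": "1 if the patient required re-grafting within 28 days",
    "inpatient_cost": "total inpatient cost, GBP",
    "u_baseline": "EQ-5D utility shortly after surgery (missing unless completed)",
    "u_day28": "EQ-5D utility at day 28 (missing unless completed)",
}


@dataclass(frozen=True)
class StudyConfig:
    """Generating truth for the synthetic before/after study.

    Defaults mirror the feasibility study the model draws on: 131 patients in
    the retrospective standard-bedding period, 90 in the prospective
    low-friction period, re-graft rates implied by the base-case re-graft
    probability (0.0382 on low-friction) and relative risk (0.574), lognormal
    costs by re-graft status, beta utilities, and questionnaire completion of
    roughly 40/90 in the prospective period only.
    """

    n_before: int = 131
    n_after: int = 90
    p_regraft_before: float = 0.038154 / 0.574
    p_regraft_after: float = 0.038154
    cost_logmean_regraft: float = 9.81
    cost_logsd_regraft: float = 0.35
    cost_logmean_no: float = 9.20
    cost_logsd_no: float = 0.09
    utility_baseline_ab: tuple[float, float] = (0.77, 1.41)
    utility_no_ab: tuple[float, float] = (2.26, 2.19)
    utility_re_ab: tuple[float, float] = (179.95, 106.82)
    utility_completion_rate: float = 40 / 90
    c_intervention: float = 115.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p, label in [
            (self.p_regraft_before, "p_regraft_before"),
            (self.p_regraft_after, "p_regraft_after"),
            (self.utility_completion_rate, "utility_completion_rate"),
        ]:
            if not 0 <= p <= 1:
                raise ValueError(f"{label} must lie in [0, 1], got {p}")
        if self.n_before < 1 or self.n_after < 1:
            raise ValueError("period sizes must be >= 1")
        for a, b in (self.utility_baseline_ab, self.utility_no_ab, self.utility_re_ab):
            if a <= 0 or b <= 0:
                raise ValueError("beta parameters must be positive")
        if min(self.cost_logsd_regraft, self.cost_logsd_no) < 0:
            raise ValueError("cost log-SDs must be >= 0")


def generate_study(config: StudyConfig | None = None) -> pd.DataFrame:
    """Generate one synthetic study as a patient-record DataFrame.

    Reproducible from ``config.seed``.  Utilities are missing completely at
    random outside the completing subset, and are only collected in the
    prospective (after) period.
    """
    config = config or StudyConfig()
    rng = np.random.default_rng(config.seed)
    frames = []
    for period, n, p in [
        ("before", config.n_before, config.p_regraft_before),
        ("after", config.n_after, config.p_regraft_after),
    ]:
        regraft = rng.random(n) < p
        cost = np.where(
            regraft,
            rng.lognormal(config.cost_logmean_regraft, config.cost_logsd_regraft, n),
            rng.lognormal(config.cost_logmean_no, config.cost_logsd_no, n),
        )
        u_base = np.full(n, np.nan)
        u_d28 = np.full(n, np.nan)
        if period == "after":
            completes = rng.random(n) < config.utility_completion_rate
            u_base[completes] = rng.beta(*config.utility_baseline_ab, completes.sum())
            d28 = np.where(
                regraft,
                rng.beta(*config.utility_re_ab, n),
                rng.beta(*config.utility_no_ab, n),
            )
            u_d28[completes] = d28[completes]
        frames.append(
            pd.DataFrame(
                {
                    "period": period,
                    "regraft": regraft.astype(int),
                    "inpatient_cost": cost,
                    "u_baseline": u_base,
                    "u_day28": u_d28,
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    records.insert(0, "id", np.arange(1, len(records) + 1))
    return records


# ---------------------------------------------------------------------------
# Estimators: records -> ParameterSpec
# ---------------------------------------------------------------------------

def estimate_regraft_beta(
    records: pd.DataFrame, period: str = "after", prior: tuple[float, float] = (0.5, 0.5)
) -> ParameterSpec:
    """Conjugate beta posterior of the re-graft probability in one period.

    Jeffreys prior (0.5, 0.5) by default, so zero observed events still give
    a proper, non-degenerate distribution.
    """
    sub = records.loc[records["period"] == period, "regraft"]
    if len(sub) == 0:
        raise ValueError(f"no records in period {period!r}")
    events = int(sub.sum())
    return ParameterSpec(
        name="p_regraft_lf" if period == "after" else "p_regraft_before",
        family="beta",
        shape_a=events + prior[0],
        shape_b=len(sub) - events + prior[1],
        units="probability",
    )


def estimate_rr_lognormal(records: pd.DataFrame) -> ParameterSpec:
    """Relative risk of re-graft, after vs before, as a lognormal.

    ``meanlog = ln(rate_after / rate_before)`` with the standard delta-method
    log-RR standard error ``sqrt(1/a - 1/n_a + 1/b - 1/n_b)`` for event
    counts a, b.
    """
    counts = {}
    for period in ("before", "after"):
        sub = records.loc[records["period"] == period, "regraft"]
        if len(sub) == 0:
            raise ValueError(f"no records in period {period!r}")
        counts[period] = (int(sub.sum()), len(sub))
    (b, n_b), (a, n_a) = counts["before"], counts["after"]
    if a == 0 or b == 0:
        raise ValueError(
            "zero re-graft events in one period; the log relative risk is undefined "
            "— consider a continuity correction (add 0.5 to all cells) and flag it"
        )
    meanlog = float(np.log((a / n_a) / (b / n_b)))
    sdlog = float(np.sqrt(1 / a - 1 / n_a + 1 / b - 1 / n_b))
    return ParameterSpec(name="rr", family="lognormal", shape_a=meanlog, shape_b=sdlog, units="ratio")


def estimate_cost_lognormal(records: pd.DataFrame, stratum: str) -> ParameterSpec:
    """Lognormal inpatient-cost fit by log-moments in a re-graft stratum,
    pooling both periods (cost structure is assumed common to the arms)."""
    if stratum not in ("regraft", "no_regraft"):
        raise ValueError(f"stratum must be 'regraft' or 'no_regraft', got {stratum!r}")
    mask = records["regraft"] == (1 if stratum == "regraft" else 0)
    costs = records.loc[mask, "inpatient_cost"].to_numpy()
    if len(costs) < 2:
        raise ValueError(f"need >= 2 records in stratum {stratum!r}, got {len(costs)}")
    logs = np.log(costs)
    return ParameterSpec(
        name="c_regraft" if stratum == "regraft" else "c_no_regraft",
        family="lognormal",
        shape_a=float(logs.mean()),
        shape_b=float(logs.std(ddof=1)),
        units="GBP",
    )


_UTILITY_STRATA = {
    "baseline": "u_baseline",
    "no_regraft_d28": "u_day28",
    "regraft_d28": "u_day28",
}
_UTILITY_NAMES = {
    "baseline": "u_baseline",
    "no_regraft_d28": "u_no_regraft",
    "regraft_d28": "u_regraft",
}


def estimate_utility_beta(records: pd.DataFrame, stratum: str) -> ParameterSpec:
    """Method-of-moments beta fit to observed utilities in a stratum.

    ``alpha = m (m(1-m)/v - 1)``, ``beta = (1-m) (m(1-m)/v - 1)`` for sample
    mean m and variance v.  Utilities at exactly 0 or 1 are nudged inward by
    1e-6 (with a warning); a variance at or above m(1-m) is infeasible for a
    beta distribution and raises.
    """
    if stratum not in _UTILITY_STRATA:
        raise ValueError(f"stratum must be one of {sorted(_UTILITY_STRATA)}, got {stratum!r}")
    col = _UTILITY_STRATA[stratum]
    mask = records[col].notna()
    if stratum == "no_regraft_d28":
        mask &= records["regraft"] == 0
    elif stratum == "regraft_d28":
        mask &= records["regraft"] == 1
    u = records.loc[mask, col].to_numpy(dtype=float)
    if len(u) < 2:
        raise ValueError(f"need >= 2 non-missing utilities in stratum {stratum!r}, got {len(u)}")
    if np.any((u == 0) | (u == 1)):
        warnings.warn("utilities at exactly 0/1 nudged inward by 1e-6", stacklevel=2)
        u = np.clip(u, 1e-6, 1 - 1e-6)
    m = float(u.mean())
    v = float(u.var(ddof=1))
    if v <= 0 or v >= m * (1 - m):
        raise ValueError(
            f"sample variance {v:.3g} infeasible for a beta with mean {m:.3g} "
            f"(need 0 < v < {m * (1 - m):.3g})"
        )
    scale = m * (1 - m) / v - 1.0
    return ParameterSpec(
        name=_UTILITY_NAMES[stratum],
        family="beta",
        shape_a=m * scale,
        shape_b=(1 - m) * scale,
        units="utility",
    )


def estimate_spec_set(records: pd.DataFrame, c_intervention: float = 115.0) -> ParameterSpecSet:
    """Assemble a full model spec set from study records.

    The intervention cost is not estimable from the records (it is a priced
    input) and enters as a point mass.
    """
    n_after = int((records["period"] == "after").sum())
    if n_after < 30:
        warnings.warn(
            f"only {n_after} after-period records; estimated distributions are unstable",
            stacklevel=2,
        )
    return ParameterSpecSet(
        [
            estimate_rr_lognormal(records),
            estimate_regraft_beta(records, "after"),
            ParameterSpec(name="c_intervention", family="point", value=c_intervention, units="GBP"),
            estimate_cost_lognormal(records, "regraft"),
            estimate_cost_lognormal(records, "no_regraft"),
            estimate_utility_beta(records, "baseline"),
            estimate_utility_beta(records, "no_regraft_d28"),
            estimate_utility_beta(records, "regraft_d28"),
        ]
    )


def end_to_end(
    study_config: StudyConfig | None = None,
    model_config: ModelConfig | None = None,
    pop_config: _voi.PopulationConfig | None = None,
    n_iter: int = 50_000,
    seed: int = 1,
) -> dict:
    """Full pipeline on synthetic data: generate -> estimate -> PSA -> VOI.

    Returns a dict with the generated records, the estimated spec set, the
    :class:`PSAResults`, its summary, and the VOI table.
    """
    study_config = study_config or StudyConfig()
    records = generate_study(study_config)
    specs = estimate_spec_set(records, c_intervention=study_config.c_intervention)
    model = DecisionTreeModel(specs, model_config)
    results: PSAResults = model.fit(n_iter=n_iter, seed=seed)
    return {
        "records": records,
        "spec_set": specs,
        "results": results,
        "summary": results.summary(),
        "voi": results.voi(pop_config),
    }
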