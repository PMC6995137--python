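"""Decision-tree arithmetic for one joint parameter draw.

Patients recovering from skin-graft surgery are nursed on either standard or
low-friction bedding; with some probability the graft fails and they are
re-grafted.  Each arm is a two-branch chance node: expected cost and QALYs are
the re-graft-probability-weighted mixture of the re-graft and no-re-graft
pathways.  All functions are vectorised over draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .parameters import REQUIRED_PARAMETERS

__all__ = [
    "ModelConfig",
    "ArmOutcome",
    "pathway_qaly",
    "standard_regraft_prob",
    "arm_outcome",
    "net_benefit",
]

STANDARD = "standard"
LOW_FRICTION = "low_friction"


@dataclass(frozen=True)
class ModelConfig:
    """Structural settings of the 28-day decision tree.

    horizon_days
        Model time horizon; costs and utilities accrue over this window only
        (no discounting is applied within it).
    days_per_year
        Divisor converting utility-days into QALYs (365.25 by default).
    wtp
        Willingness-to-pay threshold lambda, GBP per QALY.
    """

    horizon_days: float = 28.0
    days_per_year: float = 365.25
    wtp: float = 20_000.0
    arms: tuple[str, str] = (STANDARD, LOW_FRICTION)

    def __post_init__(self) -> None:
        if self.horizon_days <= 0 or self.horizon_days > self.days_per_year:
            raise ValueError(
                f"horizon_days must lie in (0, {self.days_per_year}], got {self.horizon_days}"
            )
        if self.wtp < 0:
            raise ValueError(f"wtp must be >= 0, got {self.wtp}")


@dataclass(frozen=True)
class ArmOutcome:
    """Expected cost (GBP) and QALYs for one arm under one parameter draw."""

    arm: str
    cost: float | np.ndarray
    qaly: float | np.ndarray


def pathway_qaly(u_start, u_end, horizon_days: float = 28.0, days_per_year: float = 365.25):
    """QALYs accrued between two utility measurements, trapezoid rule.

    Linear interpolation between the utility at surgery (``u_start``) and at
    the end of the horizon (``u_end``): area = mean utility x horizon length,
    expressed in years.
    """
    u_start = np.asarray(u_start, dtype=float)
    u_end = np.asarray(u_end, dtype=float)
    if np.any((u_start < 0) | (u_start > 1)) or np.any((u_end < 0) | (u_end > 1)):
        raise ValueError("utilities must lie in [0, 1]")
    out = 0.5 * (u_start + u_end) * horizon_days / days_per_year
    return out if out.ndim else float(out)


def standard_regraft_prob(p_lf, rr):
    """Re-graft probability on standard bedding implied by the low-friction
    probability and the relative risk (low-friction vs standard).

    ``p_std = min(1, p_lf / RR)``, capped because the division can exceed 1
    for strongly protective RR draws.
    """
    p_lf = np.asarray(p_lf, dtype=float)
    rr = np.asarray(rr, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("relative risk must be strictly positive")
    if np.any((p_lf < 0) | (p_lf > 1)):
        raise ValueError("p_lf must lie in [0, 1]")
    out = np.minimum(1.0, p_lf / rr)
    return out if out.ndim else float(out)


def arm_outcome(draw_row: Mapping, arm: str, config: ModelConfig | None = None) -> ArmOutcome:
    """Evaluate one arm of the decision tree for one (or a vector of) draws.

    ``draw_row`` maps the eight canonical parameter names to scalars or
    aligned arrays.  The low-friction arm uses the sampled re-graft
    probability directly and carries the intervention cost; the standard arm
    derives its probability through the relative risk and costs nothing extra.
    """
    config = config or ModelConfig()
    missing = [p for p in REQUIRED_PARAMETERS if p not in draw_row]
    if missing:
        raise KeyError(f"draw is missing parameters: {missing}")
    if arm not in config.arms:
        raise ValueError(f"unknown arm {arm!r}; expected one of {config.arms}")

    if arm == LOW_FRICTION:
        p = np.asarray(draw_row["p_regraft_lf"], dtype=float)
        extra_cost = np.asarray(draw_row["c_intervention"], dtype=float)
    else:
        p = standard_regraft_prob(draw_row["p_regraft_lf"], draw_row["rr"])
        p = np.asarray(p, dtype=float)
        extra_cost = 0.0

    cost = extra_cost + p * np.asarray(draw_row["c_regraft"], float) + (1.0 - p) * np.asarray(
        draw_row["c_no_regraft"], float
    )
    q_re = pathway_qaly(
        draw_row["u_baseline"], draw_row["u_regraft"], config.horizon_days, config.days_per_year
    )
    q_no = pathway_qaly(
        draw_row["u_baseline"], draw_row["u_no_regraft"], config.horizon_days, config.days_per_year
    )
    qaly = p * q_re + (1.0 - p) * q_no
    if np.ndim(cost) == 0:
        return ArmOutcome(arm=arm, cost=float(cost), qaly=float(qaly))
    return ArmOutcome(arm=arm, cost=cost, qaly=qaly)


def net_benefit(outcome_or_cost, qaly=None, wtp: float = 20_000.0):
    """Net monetary benefit ``wtp * QALY - cost``.

    Accepts either an :class:`ArmOutcome` or explicit cost/qaly values.
    """
    if isinstance(outcome_or_cost, ArmOutcome):
        cost, qaly_ = outcome_or_cost.cost, outcome_or_cost.qaly
    else:
        if qaly is None:
            raise TypeError("net_benefit requires an ArmOutcome or (cost, qaly)")
        cost, qaly_ = outcome_or_cost, qaly
    out = wtp * np.asarray(qaly_, float) - np.asarray(cost, float)
    return out if out.ndim else float(out)
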