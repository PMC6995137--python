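"""Value-of-information estimators.

Per-person EVPI is the exact Monte-Carlo identity
``E[max_arm NB] - max_arm E[NB]``.  Single-parameter EVPPI uses the
Strong-Oakley regression shortcut: the conditional expectation of incremental
net benefit given one parameter is estimated by a flexible univariate
smoother (cubic B-spline basis at quantile knots, ordinary least squares),
and ``EVPPI = E[max(g, 0)] - max(E[g], 0)`` with g the fitted values.
Population values scale per-person values by the discounted number of
patients expected to face the decision over the technology's lifetime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PopulationConfig",
    "evpi",
    "evppi_regression",
    "discounted_population",
    "population_voi",
]


@dataclass(frozen=True)
class PopulationConfig:
    """Eligible population for scaling per-person value of information.

    annual_patients
        Patients per year facing the bedding decision (skin grafts per annum).
    horizon_years
        Technology relevance horizon in years.
    discount_rate
        Annual discount rate applied to future cohorts.
    first_year_discounted
        If False (default), the first cohort is undiscounted (annuity-due).
    """

    annual_patients: float = 1000.0
    horizon_years: int = 10
    discount_rate: float = 0.035
    first_year_discounted: bool = False

    def __post_init__(self) -> None:
        if self.annual_patients < 0 or self.discount_rate < 0:
            raise ValueError("annual_patients and discount_rate must be non-negative")
        if self.horizon_years < 1:
            raise ValueError(f"horizon_years must be >= 1, got {self.horizon_years}")


def evpi(nb: np.ndarray) -> float:
    """Per-person expected value of perfect information.

    ``nb`` is an (n_iter, n_arms) matrix of net benefits.  EVPI is the mean
    of the per-iteration best arm minus the best arm on average; it is
    non-negative by Jensen's inequality and zero exactly when one arm
    dominates in every draw.
    """
    nb = np.asarray(nb, dtype=float)
    if nb.ndim != 2 or nb.shape[0] < 1 or nb.shape[1] < 2:
        raise ValueError(f"nb must be (n_iter, n_arms>=2), got shape {nb.shape}")
    value = float(np.mean(nb.max(axis=1)) - nb.mean(axis=0).max())
    # exact identity can land a hair below 0 in floating point
    return max(value, 0.0)


def _spline_basis(x: np.ndarray, basis_df: int) -> np.ndarray:
    from sklearn.preprocessing import SplineTransformer

    n_knots = max(int(basis_df) - 2, 2)
    st = SplineTransformer(n_knots=n_knots, degree=3, knots="quantile", include_bias=False)
    return st.fit_transform(x.reshape(-1, 1))


def evppi_regression(inb: np.ndarray, x: np.ndarray, basis_df: int = 6) -> float:
    """Single-parameter EVPPI by spline regression of INB on the parameter.

    Fits ``INB ~ spline(x)`` by least squares; the fitted values estimate the
    conditional mean INB given the parameter, and
    ``EVPPI = mean(max(fitted, 0)) - max(mean(fitted), 0)``, floored at 0.

    A constant ``x`` (point-mass parameter) carries no information: the
    result is 0, with a warning.

    Parameters
    ----------
    inb : array
        Per-iteration incremental net benefit.
    x : array
        The parameter's draws, aligned with ``inb``.
    basis_df : int
        Approximate degrees of freedom of the cubic spline basis
        (number of basis columns, intercept excluded).
    """
    inb = np.asarray(inb, dtype=float)
    x = np.asarray(x, dtype=float)
    if inb.shape != x.shape or inb.ndim != 1:
        raise ValueError("inb and x must be 1-d arrays of equal length")
    if len(inb) < 100:
        raise ValueError(f"need >= 100 iterations for regression EVPPI, got {len(inb)}")
    if np.ptp(x) == 0:
        warnings.warn("parameter has zero variance; EVPPI is 0", stacklevel=2)
        return 0.0
    basis = np.column_stack([np.ones_like(x), _spline_basis(x, basis_df)])
    coef, *_ = np.linalg.lstsq(basis, inb, rcond=None)
    fitted = basis @ coef
    value = float(np.mean(np.maximum(fitted, 0.0)) - max(float(fitted.mean()), 0.0))
    return max(value, 0.0)


def discounted_population(config: PopulationConfig | None = None) -> float:
    """Discounted number of patients over the technology's lifetime.

    Sums annual cohorts ``annual_patients / (1 + r)^t``; with
    ``first_year_discounted=False`` the first cohort enters undiscounted
    (t = 0 .. horizon-1), i.e. annuity-due discounting.
    """
    config = config or PopulationConfig()
    offset = 1 if config.first_year_discounted else 0
    t = np.arange(config.horizon_years) + offset
    return float(np.sum(config.annual_patients / (1.0 + config.discount_rate) ** t))


def population_voi(per_person: float, population: float) -> float:
    """Scale a per-person value of information to the eligible population."""
    if per_person < 0 or population < 0:
        raise ValueError("per_person and population must be >= 0")
    return float(per_person * population)
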