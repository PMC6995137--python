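"""Uncertain model inputs as named parametric distributions.

The decision model is driven by eight uncertain inputs: the relative risk of
re-graft on low-friction versus standard bedding, the absolute re-graft
probability on low-friction bedding, the intervention cost, inpatient costs
stratified by re-graft status, and EQ-5D utilities (post-surgery baseline and
day-28 values stratified by re-graft status).  Each is represented by a
:class:`ParameterSpec` — a beta, lognormal, or degenerate (point-mass)
distribution — and a :class:`ParameterSpecSet` samples them jointly and
independently for probabilistic sensitivity analysis.

Relative risks are typically published as a median with a 95% interval rather
than as distribution parameters; :func:`lognormal_from_median_ci` inverts that
summary into a lognormal spec.
"""

from __future__ import annotations

import hashlib
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Z975",
    "REQUIRED_PARAMETERS",
    "ParameterSpec",
    "ParameterSpecSet",
    "ParameterDraws",
    "lognormal_from_median_ci",
    "summarize",
]

#: z-score of the 97.5th percentile of the standard normal, used to invert
#: equal-tailed 95% intervals on the log scale.
Z975 = 1.959964

#: Canonical names of the eight model inputs, in evaluation order.
REQUIRED_PARAMETERS = (
    "rr",              # relative risk of re-graft, low-friction vs standard
    "p_regraft_lf",    # P(re-graft) on low-friction bedding
    "c_intervention",  # cost of providing low-friction bedding (GBP)
    "c_regraft",       # inpatient cost given re-graft (GBP)
    "c_no_regraft",    # inpatient cost given no re-graft (GBP)
    "u_baseline",      # EQ-5D utility shortly after graft surgery
    "u_no_regraft",    # day-28 utility, graft intact
    "u_regraft",       # day-28 utility, graft lost
)

_FAMILIES = ("beta", "lognormal", "point")


@dataclass(frozen=True)
class ParameterSpec:
    """One uncertain model input as a named parametric distribution.

    Parameters
    ----------
    name : str
        Identifier; unique within a spec set.
    family : {"beta", "lognormal", "point"}
        Distribution family.
    shape_a, shape_b : float, optional
        Beta (alpha, beta) or lognormal (meanlog, sdlog).  Unused for
        point masses.
    value : float, optional
        The fixed value of a point mass.
    units : str
        Free-text units (GBP, probability, utility, ratio).
    """

    name: str
    family: str
    shape_a: float | None = None
    shape_b: float | None = None
    value: float | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"parameter {self.name!r}: unknown family {self.family!r}; "
                f"expected one of {_FAMILIES}"
            )
        if self.family == "beta":
            if self.shape_a is None or self.shape_b is None:
                raise ValueError(f"parameter {self.name!r}: beta requires shape_a and shape_b")
            if self.shape_a <= 0 or self.shape_b <= 0:
                raise ValueError(
                    f"parameter {self.name!r}: beta shapes must be positive, "
                    f"got ({self.shape_a}, {self.shape_b})"
                )
        elif self.family == "lognormal":
            if self.shape_a is None or self.shape_b is None:
                raise ValueError(
                    f"parameter {self.name!r}: lognormal requires meanlog (shape_a) "
                    "and sdlog (shape_b)"
                )
            if self.shape_b < 0:
                raise ValueError(f"parameter {self.name!r}: sdlog must be >= 0, got {self.shape_b}")
        else:  # point
            if self.value is None:
                raise ValueError(f"parameter {self.name!r}: point mass requires a value")

    # -- analytic summaries ------------------------------------------------

    def mean(self) -> float:
        if self.family == "beta":
            return self.shape_a / (self.shape_a + self.shape_b)
        if self.family == "lognormal":
            return float(np.exp(self.shape_a + 0.5 * self.shape_b**2))
        return float(self.value)

    def median(self) -> float:
        if self.family == "beta":
            return float(stats.beta(self.shape_a, self.shape_b).median())
        if self.family == "lognormal":
            return float(np.exp(self.shape_a))
        return float(self.value)

    def quantile(self, q) -> np.ndarray | float:
        if self.family == "beta":
            return stats.beta(self.shape_a, self.shape_b).ppf(q)
        if self.family == "lognormal":
            if self.shape_b == 0:
                return np.full_like(np.asarray(q, dtype=float), np.exp(self.shape_a))
            return stats.lognorm(s=self.shape_b, scale=np.exp(self.shape_a)).ppf(q)
        return np.full_like(np.asarray(q, dtype=float), self.value)

    def summarize(self) -> tuple[float, float, float]:
        """Analytic mean and equal-tailed 95% interval (2.5/97.5 percentiles)."""
        lo, hi = np.atleast_1d(self.quantile([0.025, 0.975]))
        return self.mean(), float(lo), float(hi)

    def is_point(self) -> bool:
        """True when every sample is the same value (point mass or sdlog 0)."""
        return self.family == "point" or (self.family == "lognormal" and self.shape_b == 0)

    # -- sampling ----------------------------------------------------------

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n < 1:
            raise ValueError(f"n must be >= 1, got {n}")
        if self.family == "beta":
            return rng.beta(self.shape_a, self.shape_b, size=n)
        if self.family == "lognormal":
            if self.shape_b == 0:
                return np.full(n, np.exp(self.shape_a))
            return rng.lognormal(mean=self.shape_a, sigma=self.shape_b, size=n)
        return np.full(n, float(self.value))


def lognormal_from_median_ci(
    median: float, lo: float, hi: float, name: str = "", units: str = ""
) -> ParameterSpec:
    """Build a lognormal spec from a printed median and 95% interval.

    The interval is symmetrised on the log scale: ``meanlog = ln(median)`` and
    ``sdlog = (ln hi - ln lo) / (2 * 1.959964)``.  A degenerate interval
    (lo == median == hi) yields sdlog 0, i.e. a point mass.

    Raises
    ------
    ValueError
        If any input is non-positive or the ordering ``lo <= median <= hi``
        is violated.
    """
    if min(median, lo, hi) <= 0:
        raise ValueError(f"median/CI must be positive, got ({median}, {lo}, {hi})")
    if not (lo <= median <= hi):
        raise ValueError(f"require lo <= median <= hi, got ({median}, {lo}, {hi})")
    meanlog = float(np.log(median))
    sdlog = float((np.log(hi) - np.log(lo)) / (2.0 * Z975))
    return ParameterSpec(name=name, family="lognormal", shape_a=meanlog, shape_b=sdlog, units=units)


def summarize(spec: ParameterSpec) -> tuple[float, float, float]:
    """Analytic (mean, 2.5th pct, 97.5th pct) of a parameter spec."""
    return spec.summarize()


def _substream(seed: int, name: str) -> np.random.Generator:
    # Per-parameter stream keyed by a stable hash of the name, so adding or
    # reordering parameters never perturbs another parameter's draws.
    digest = hashlib.blake2b(name.encode("utf-8"), digest_size=8).digest()
    key = int.from_bytes(digest, "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


@dataclass(frozen=True)
class ParameterDraws:
    """A seeded rectangle of joint Monte-Carlo samples (one column per parameter)."""

    values: pd.DataFrame
    seed: int | None = None

    @property
    def n_iter(self) -> int:
        return len(self.values)

    @property
    def names(self) -> list[str]:
        return list(self.values.columns)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[name].to_numpy()


class ParameterSpecSet(Mapping):
    """Ordered, name-keyed collection of parameter specs.

    With ``require_complete=True`` (the default) the set must contain all
    eight canonical model inputs (:data:`REQUIRED_PARAMETERS`); extra
    parameters — e.g. a bias term in sensitivity analyses — are allowed.
    """

    def __init__(self, specs: Iterable[ParameterSpec], require_complete: bool = True):
        self._specs: dict[str, ParameterSpec] = {}
        for spec in specs:
            if spec.name in self._specs:
                raise ValueError(f"duplicate parameter name {spec.name!r}")
            if not spec.name:
                raise ValueError("parameter specs in a set must be named")
            self._specs[spec.name] = spec
        if require_complete:
            missing = [p for p in REQUIRED_PARAMETERS if p not in self._specs]
            if missing:
                raise ValueError(f"missing required parameters: {missing}")
        self.require_complete = require_complete

    def __getitem__(self, name: str) -> ParameterSpec:
        return self._specs[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    @property
    def names(self) -> list[str]:
        return list(self._specs)

    def replace(self, spec: ParameterSpec) -> "ParameterSpecSet":
        """Return a new set with the same-named parameter swapped out."""
        if spec.name not in self._specs:
            raise KeyError(spec.name)
        specs = [spec if s.name == spec.name else s for s in self._specs.values()]
        return ParameterSpecSet(specs, require_complete=self.require_complete)

    def add(self, spec: ParameterSpec) -> "ParameterSpecSet":
        if spec.name in self._specs:
            raise ValueError(f"parameter {spec.name!r} already present")
        return ParameterSpecSet(
            list(self._specs.values()) + [spec], require_complete=self.require_complete
        )

    def summary_table(self) -> pd.DataFrame:
        """Audit table: analytic mean and 95% interval per parameter."""
        rows = []
        for spec in self._specs.values():
            mean, lo, hi = spec.summarize()
            rows.append(
                {
                    "name": spec.name,
                    "mean": mean,
                    "ci_lo": lo,
                    "ci_hi": hi,
                    "family": spec.family,
                    "shape_a": spec.shape_a,
                    "shape_b": spec.shape_b,
                    "value": spec.value,
                    "units": spec.units,
                }
            )
        return pd.DataFrame(rows).set_index("name")

    def sample(self, n_iter: int, seed: int) -> ParameterDraws:
        """Jointly sample all parameters, mutually independently.

        Each parameter draws from its own deterministic sub-stream of the
        global seed, so the same seed reproduces draws bit-identically and
        adding a parameter leaves the others' columns unchanged.
        """
        if n_iter < 1:
            raise ValueError(f"n_iter must be >= 1, got {n_iter}")
        cols = {
            name: spec.sample(n_iter, _substream(seed, name))
            for name, spec in self._specs.items()
        }
        return ParameterDraws(values=pd.DataFrame(cols), seed=seed)
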