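"""Probabilistic decision model: Model / Results objects.

:class:`DecisionTreeModel` binds a parameter spec set to the decision-tree
structure; ``fit(n_iter, seed)`` runs the probabilistic sensitivity analysis
(joint Monte-Carlo sampling propagated through the tree) and returns a
:class:`PSAResults` carrying the per-iteration arm outcomes, from which
summaries, the cost-effectiveness acceptability curve, and value-of-
information quantities are derived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import voi as _voi
from .parameters import ParameterDraws, ParameterSpecSet
from .tree import LOW_FRICTION, STANDARD, ModelConfig, arm_outcome

__all__ = ["DecisionTreeModel", "PSAResults", "PSASummary"]


class DecisionTreeModel:
    """Two-arm decision tree for bedding after skin-graft surgery.

    Parameters
    ----------
    spec_set : ParameterSpecSet
        The eight uncertain inputs (relative risk, re-graft probability,
        costs, utilities).
    config : ModelConfig, optional
        Horizon, QALY conversion, willingness-to-pay and arm labels.
    """

    def __init__(self, spec_set: ParameterSpecSet, config: ModelConfig | None = None):
        self.spec_set = spec_set
        self.config = config or ModelConfig()

    @classmethod
    def from_config(cls, path=None) -> "DecisionTreeModel":
        """Build from a YAML configuration file (packaged defaults if None)."""
        from .config import load_config

        cfg = load_config(path)
        return cls(cfg.parameters, cfg.model)

    def evaluate(self, draws: ParameterDraws) -> "PSAResults":
        """Evaluate both arms on an existing draw matrix."""
        row = {name: draws[name] for name in draws.names}
        std = arm_outcome(row, STANDARD, self.config)
        lf = arm_outcome(row, LOW_FRICTION, self.config)
        table = pd.DataFrame(
            {
                "cost_std": np.atleast_1d(std.cost),
                "qaly_std": np.atleast_1d(std.qaly),
                "cost_lf": np.atleast_1d(lf.cost),
                "qaly_lf": np.atleast_1d(lf.qaly),
            }
        )
        return PSAResults(model=self, draws=draws, table=table)

    def fit(self, n_iter: int = 50_000, seed: int = 1) -> "PSAResults":
        """Run the probabilistic sensitivity analysis.

        Samples all parameters jointly (independently, per-parameter
        sub-streams of ``seed``) and evaluates the tree per draw.
        Deterministic given ``seed``.
        """
        if n_iter < 1_000:
            warnings.warn(
                f"n_iter={n_iter} is low; value-of-information estimates are "
                "unstable below 1,000 iterations",
                stacklevel=2,
            )
        draws = self.spec_set.sample(n_iter, seed)
        return self.evaluate(draws)


@dataclass
class PSASummary:
    """Arm-level and incremental summaries of a PSA (means with 95% CrI)."""

    table: pd.DataFrame
    prob_cost_effective: float
    wtp: float
    n_iter: int

    def __str__(self) -> str:
        lines = [
            "Probabilistic sensitivity analysis summary",
            f"  iterations: {self.n_iter}    willingness-to-pay: £{self.wtp:,.0f}/QALY",
            "",
            self.table.to_string(float_format=lambda v: f"{v:,.5g}"),
            "",
            f"  P(low-friction cost-effective at £{self.wtp:,.0f}) = "
            f"{self.prob_cost_effective:.3f}",
        ]
        return "\n".join(lines)

    def __getitem__(self, key):
        return self.table.loc[key]


class PSAResults:
    """Results of a probabilistic sensitivity analysis.

    Attributes
    ----------
    draws : ParameterDraws
        The joint parameter samples used.
    table : DataFrame
        Per-iteration arm outcomes: cost_std, qaly_std, cost_lf, qaly_lf.
    """

    def __init__(self, model: DecisionTreeModel, draws: ParameterDraws, table: pd.DataFrame):
        self.model = model
        self.draws = draws
        self.table = table

    # -- basic quantities --------------------------------------------------

    @property
    def n_iter(self) -> int:
        return len(self.table)

    @property
    def wtp(self) -> float:
        return self.model.config.wtp

    @property
    def seed(self) -> int | None:
        return self.draws.seed

    def nb(self, wtp: float | None = None) -> np.ndarray:
        """(n_iter, 2) net-benefit matrix, columns (standard, low-friction)."""
        wtp = self.wtp if wtp is None else wtp
        t = self.table
        return np.column_stack(
            [
                wtp * t["qaly_std"].to_numpy() - t["cost_std"].to_numpy(),
                wtp * t["qaly_lf"].to_numpy() - t["cost_lf"].to_numpy(),
            ]
        )

    def inb(self, wtp: float | None = None) -> np.ndarray:
        """Per-iteration incremental net benefit, low-friction minus standard."""
        nb = self.nb(wtp)
        return nb[:, 1] - nb[:, 0]

    def ce_plane(self) -> pd.DataFrame:
        """Per-iteration (incremental QALYs, incremental cost) pairs."""
        t = self.table
        return pd.DataFrame(
            {
                "delta_qaly": t["qaly_lf"] - t["qaly_std"],
                "delta_cost": t["cost_lf"] - t["cost_std"],
            }
        )

    # -- summaries ---------------------------------------------------------

    @staticmethod
    def _mean_ci(x: np.ndarray) -> tuple[float, float, float]:
        lo, hi = np.percentile(x, [2.5, 97.5])
        return float(np.mean(x)), float(lo), float(hi)

    def summary(self, wtp: float | None = None) -> PSASummary:
        """Means and equal-tailed 95% credible intervals of arm and
        incremental quantities, plus the probability the low-friction arm is
        cost-effective (fraction of iterations with INB > 0)."""
        wtp = self.wtp if wtp is None else wtp
        t = self.table
        nb = self.nb(wtp)
        inb = nb[:, 1] - nb[:, 0]
        rows = {
            "qaly_standard": self._mean_ci(t["qaly_std"].to_numpy()),
            "qaly_low_friction": self._mean_ci(t["qaly_lf"].to_numpy()),
            "qaly_incremental": self._mean_ci((t["qaly_lf"] - t["qaly_std"]).to_numpy()),
            "cost_standard": self._mean_ci(t["cost_std"].to_numpy()),
            "cost_low_friction": self._mean_ci(t["cost_lf"].to_numpy()),
            "cost_incremental": self._mean_ci((t["cost_lf"] - t["cost_std"]).to_numpy()),
            "nb_standard": self._mean_ci(nb[:, 0]),
            "nb_low_friction": self._mean_ci(nb[:, 1]),
            "inb": self._mean_ci(inb),
        }
        table = pd.DataFrame(rows, index=["mean", "ci_lo", "ci_hi"]).T
        return PSASummary(
            table=table,
            prob_cost_effective=float(np.mean(inb > 0)),
            wtp=wtp,
            n_iter=self.n_iter,
        )

    def prob_cost_effective(self, wtp: float | None = None) -> float:
        """P(INB > 0) at the given willingness-to-pay (ties count as not
        cost-effective)."""
        return float(np.mean(self.inb(wtp) > 0))

    def ceac(self, wtp_grid=None) -> pd.DataFrame:
        """Cost-effectiveness acceptability curve over a threshold grid."""
        if wtp_grid is None:
            wtp_grid = np.arange(0.0, 50_001.0, 1_000.0)
        wtp_grid = np.asarray(wtp_grid, dtype=float)
        if wtp_grid.size == 0:
            raise ValueError("wtp_grid must be non-empty")
        plane = self.ce_plane()
        dq = plane["delta_qaly"].to_numpy()
        dc = plane["delta_cost"].to_numpy()
        probs = [float(np.mean(l * dq - dc > 0)) for l in wtp_grid]
        return pd.DataFrame({"wtp": wtp_grid, "prob_cost_effective": probs})

    # -- value of information ----------------------------------------------

    def evpi(self, wtp: float | None = None) -> float:
        """Per-person expected value of perfect information (GBP)."""
        return _voi.evpi(self.nb(wtp))

    def evppi(
        self,
        param: str,
        wtp: float | None = None,
        basis_df: int = 6,
        n_samples: int = 10_000,
    ) -> float:
        """Per-person EVPPI for one parameter by spline regression.

        Uses the first ``n_samples`` PSA iterations (regression on the full
        50,000 is unnecessary and the estimate is stable by 10,000).
        """
        if param not in self.draws.names:
            raise KeyError(f"unknown parameter {param!r}")
        n = min(n_samples, self.n_iter)
        spec = self.model.spec_set.get(param)
        if spec is not None and spec.is_point():
            warnings.warn(f"parameter {param!r} is a point mass; EVPPI is 0", stacklevel=2)
            return 0.0
        return _voi.evppi_regression(self.inb(wtp)[:n], self.draws[param][:n], basis_df=basis_df)

    def evppi_all(
        self, wtp: float | None = None, basis_df: int = 6, n_samples: int = 10_000
    ) -> pd.Series:
        """EVPPI for every sampled (non-degenerate) parameter, descending."""
        values = {}
        for name in self.draws.names:
            x = self.draws[name]
            if np.ptp(x[: min(n_samples, self.n_iter)]) == 0:
                values[name] = 0.0
            else:
                values[name] = self.evppi(name, wtp=wtp, basis_df=basis_df, n_samples=n_samples)
        return pd.Series(values, name="evppi").sort_values(ascending=False)

    def voi(
        self,
        pop_config: _voi.PopulationConfig | None = None,
        wtp: float | None = None,
        basis_df: int = 6,
        n_samples: int = 10_000,
    ) -> pd.DataFrame:
        """Per-person and population EVPI/EVPPI table.

        One row per parameter (plus an ``evpi`` row), with per-person values
        and values scaled to the discounted eligible population.
        """
        pop_config = pop_config or _voi.PopulationConfig()
        pop = _voi.discounted_population(pop_config)
        evppi = self.evppi_all(wtp=wtp, basis_df=basis_df, n_samples=n_samples)
        rows = [("evpi", self.evpi(wtp))] + list(evppi.items())
        out = pd.DataFrame(rows, columns=["quantity", "per_person"]).set_index("quantity")
        out["population"] = out["per_person"] * pop
        out.attrs["discounted_population"] = pop
        return out
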