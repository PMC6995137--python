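"""CSV report writers, run manifest, and the end-to-end pipeline driver.

CSV conventions: currency to the pound, probabilities to 3 decimals, QALYs to
5 decimals (full precision is retained in memory; rounding is applied only on
write).  Every ``run_all`` output directory contains exactly one manifest
recording the config digest, seeds, iteration counts and file inventory, so a
run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .config import Config, load_config
from .model import DecisionTreeModel, PSAResults
from .scenarios import BiasScenarioAnalysis
from .voi import discounted_population

__all__ = [
    "RunManifest",
    "write_summary_csv",
    "write_ceac_csv",
    "write_ce_plane_csv",
    "write_voi_csv",
    "write_scenarios_csv",
    "write_parameters_csv",
    "run_all",
]

log = logging.getLogger("graftce")

_CURRENCY = ("cost", "nb", "inb", "evpi", "evppi", "per_person", "population")
_PROB = ("prob", "p_regraft")
_QALY = ("qaly",)


def _round_for_report(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind != "f":
            continue
        name = col.lower()
        if any(k in name for k in _QALY):
            out[col] = out[col].round(5)
        elif any(k in name for k in _PROB):
            out[col] = out[col].round(3)
        elif any(k in name for k in _CURRENCY):
            out[col] = out[col].round(0)
    return out


def _write(df: pd.DataFrame, path: Path, index: bool) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    _round_for_report(df).to_csv(path, index=index)
    return path


def write_parameters_csv(config: Config, path: Path) -> Path:
    """Audit table of the parameter distributions (analytic summaries)."""
    return _write(config.parameters.summary_table().reset_index(), path, index=False)


def write_summary_csv(results: PSAResults, path: Path) -> Path:
    """Arm-level and incremental PSA summary (means with 95% CrI)."""
    s = results.summary()
    df = s.table.reset_index(names="quantity")
    # ensure currency/QALY rounding keys match row-wise layout
    df = df.rename(columns={"mean": "mean", "ci_lo": "ci_lo", "ci_hi": "ci_hi"})
    qaly = df["quantity"].str.startswith("qaly")
    for col in ("mean", "ci_lo", "ci_hi"):
        df[col] = df[col].where(~qaly, df[col].round(5)).where(qaly, df[col].round(0))
    extra = pd.DataFrame(
        [{"quantity": "prob_cost_effective", "mean": round(s.prob_cost_effective, 3)}]
    )
    out = pd.concat([df, extra], ignore_index=True)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)
    return path


def write_ceac_csv(results: PSAResults, path: Path, wtp_grid=None) -> Path:
    return _write(results.ceac(wtp_grid), path, index=False)


def write_ce_plane_csv(results: PSAResults, path: Path) -> Path:
    """Per-iteration (incremental QALY, incremental cost) scatter data."""
    return _write(results.ce_plane(), path, index=False)


def write_voi_csv(results: PSAResults, path: Path, pop_config=None, **kwargs) -> Path:
    return _write(results.voi(pop_config, **kwargs).reset_index(), path, index=False)


def write_scenarios_csv(table: pd.DataFrame, path: Path) -> Path:
    return _write(table.reset_index(), path, index=False)


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config_digest: str
    seed: int
    n_iter: int
    version: str
    timestamp: str
    outputs: list[str] = field(default_factory=list)
    stage_seconds: dict = field(default_factory=dict)

    def write(self, path: Path) -> Path:
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.__dict__, sort_keys=False))
        return path

    @classmethod
    def read(cls, path: Path) -> "RunManifest":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _config_digest(path) -> str:
    if path is None:
        from .config import default_config_path

        path = default_config_path()
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_all(
    config_path=None,
    out_dir: str | Path = "outputs",
    n_iter: int = 50_000,
    seed: int = 1,
    evppi_samples: int = 10_000,
    basis_df: int = 6,
) -> RunManifest:
    """Execute the full pipeline: PSA -> CEAC -> VOI -> bias scenarios.

    Writes parameter, summary, CEAC, CE-plane, VOI and scenario CSVs plus a
    manifest into ``out_dir``.  Rerunning with the same config, seed and
    n_iter reproduces all numerical outputs exactly.
    """
    out_dir = Path(out_dir)
    cfg = load_config(config_path)
    log.info("parameters:\n%s", cfg.parameters.summary_table())
    manifest = RunManifest(
        config_digest=_config_digest(config_path),
        seed=seed,
        n_iter=n_iter,
        version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    stages: list[tuple[str, Path]] = []
    t0 = time.perf_counter()
    model = DecisionTreeModel(cfg.parameters, cfg.model)
    results = model.fit(n_iter=n_iter, seed=seed)
    manifest.stage_seconds["psa"] = round(time.perf_counter() - t0, 3)

    stages.append(("parameters", write_parameters_csv(cfg, out_dir / "parameters.csv")))
    stages.append(("summary", write_summary_csv(results, out_dir / "psa_summary.csv")))
    stages.append(("ceac", write_ceac_csv(results, out_dir / "ceac.csv")))
    stages.append(("ce_plane", write_ce_plane_csv(results, out_dir / "ce_plane.csv")))

    t0 = time.perf_counter()
    stages.append(
        (
            "voi",
            write_voi_csv(
                results, out_dir / "voi.csv", cfg.population,
                basis_df=basis_df, n_samples=evppi_samples,
            ),
        )
    )
    manifest.stage_seconds["voi"] = round(time.perf_counter() - t0, 3)
    log.info("discounted population: %.1f", discounted_population(cfg.population))

    t0 = time.perf_counter()
    analysis = BiasScenarioAnalysis(cfg.parameters, cfg.scenarios, cfg.model, cfg.population)
    table = analysis.run(n_iter=n_iter, seed=seed, basis_df=basis_df, evppi_samples=evppi_samples)
    stages.append(("scenarios", write_scenarios_csv(table, out_dir / "scenarios.csv")))
    manifest.stage_seconds["scenarios"] = round(time.perf_counter() - t0, 3)

    manifest.outputs = [p.name for _, p in stages]
    manifest.write(out_dir / "manifest.yaml")
    for stage, p in stages:
        log.info("wrote %s (%s)", p, stage)
    return manifest
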