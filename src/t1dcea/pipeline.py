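"""Pipeline configuration and end-to-end driver.

A single YAML (or JSON) file configures the whole analysis; every omitted key
falls back to the packaged defaults (IMSS cohort marginals, published cost
and utility tables, synthetic disease parameters, 5%/5% discounting, 70-year
horizon).  All randomness flows from the three seeds recorded in the config —
there is no hidden entropy — so re-running a config reproduces every output
byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import yaml

from . import __version__
from .cohort import (
    CohortSpec, default_imss_spec, generate_cohort, summarize_cohort,
    write_cohort_csv,
)
from .costing import CostTable, DisabilityDurations, SalaryTable
from .disease import DiseaseParams, default_disease_params
from .economics import DiscountSpec, default_wtp_grid
from .model import CEAModel
from .scenarios import RunSettings, default_suite, run_suite, suite_report
from .utility import UtilityTable

__all__ = ["PipelineConfig", "ConfigError", "PipelineError", "load_config", "run_pipeline"]


class ConfigError(ValueError):
    """Configuration violates the schema; message names field and constraint."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; message is stage-tagged."""


@dataclass
class CEACConfig:
    run: bool = True
    n_outer: int = 1000
    n_inner: int = 1000
    cost_cv: float = 0.2
    wtp_step: float = 10_000.0
    wtp_max: float = 600_000.0


@dataclass
class PipelineConfig:
    n_patients: int = 192
    horizon: int = 70
    seed_cohort: int = 1
    seed_simulation: int = 2
    seed_psa: int = 3
    discount_costs: float = 0.05
    discount_effects: float = 0.05
    include_indirect: bool = False
    cohort: Dict = field(default_factory=dict)  # CohortSpec field overrides
    disease_params_path: Optional[str] = None
    cost_table_path: Optional[str] = None
    utility_table_path: Optional[str] = None
    disability_path: Optional[str] = None
    run_scenarios: bool = True
    ceac: CEACConfig = field(default_factory=CEACConfig)
    output_dir: str = "t1dcea_output"

    def validate(self) -> None:
        if not 1 <= self.horizon <= 70:
            raise ConfigError(f"horizon must be in [1, 70], got {self.horizon}")
        if self.n_patients < 1:
            raise ConfigError(f"n_patients must be >= 1, got {self.n_patients}")
        if self.discount_costs < 0 or self.discount_effects < 0:
            raise ConfigError("discount rates must be >= 0")
        if self.ceac.n_outer < 1 or self.ceac.n_inner < 1:
            raise ConfigError("ceac.n_outer and ceac.n_inner must be >= 1")
        for attr in ("disease_params_path", "cost_table_path",
                     "utility_table_path", "disability_path"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{attr}: file not found: {p}")
        # cohort overrides validated by building the spec
        self.cohort_spec()

    def cohort_spec(self) -> CohortSpec:
        spec = default_imss_spec(n=self.n_patients, seed=self.seed_cohort)
        valid = set(spec.__dict__)
        for k, v in self.cohort.items():
            if k not in valid:
                raise ConfigError(f"cohort.{k}: unknown CohortSpec field")
            setattr(spec, k, v)
        spec.n = self.n_patients
        spec.seed = self.seed_cohort
        spec.validate()
        return spec

    def to_yaml(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def load_config(path: Optional[str] = None) -> PipelineConfig:
    """Load and validate a config file (YAML; JSON is valid YAML).

    ``None`` or an empty file yields the all-defaults configuration.
    """
    data: Dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    ceac_data = data.pop("ceac", {})
    if not isinstance(ceac_data, dict):
        raise ConfigError("ceac must be a mapping")
    unknown = set(ceac_data) - set(CEACConfig.__dataclass_fields__)
    if unknown:
        raise ConfigError(f"unknown ceac keys: {sorted(unknown)}")
    cfg = PipelineConfig(**data, ceac=CEACConfig(**ceac_data))
    cfg.validate()
    return cfg


def _load_inputs(config: PipelineConfig):
    params = (
        DiseaseParams.from_yaml(config.disease_params_path)
        if config.disease_params_path
        else default_disease_params()
    )
    cost_table = (
        CostTable.from_yaml(config.cost_table_path)
        if config.cost_table_path
        else CostTable.default()
    )
    utility_table = (
        UtilityTable.from_yaml(config.utility_table_path)
        if config.utility_table_path
        else UtilityTable.default()
    )
    disability = (
        DisabilityDurations.from_yaml(config.disability_path)
        if config.disability_path
        else DisabilityDurations()
    )
    return params, cost_table, utility_table, disability


def run_pipeline(config: PipelineConfig, output_dir: Optional[str] = None) -> Dict[str, Path]:
    """Run the full analysis and write all artifacts.

    Writes: cohort CSV + summary, per-arm trajectory tables, base-case
    results (JSON + CSV), the scenario report (CSV + Markdown), the CEAC
    (CSV + PNG figure) and a log of seeds and versions.  Returns the mapping
    of artifact name -> path.
    """
    config.validate()
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    log_lines = [
        f"t1dcea {__version__}",
        f"numpy {np.__version__}",
        f"seeds: cohort={config.seed_cohort} simulation={config.seed_simulation} "
        f"psa={config.seed_psa}",
        f"n_patients={config.n_patients} horizon={config.horizon}",
    ]

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - re-tagged
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return deco

    params, cost_table, utility_table, disability = stage("load-inputs")(
        lambda: _load_inputs(config)
    )

    def _cohort():
        spec = config.cohort_spec()
        cohort = generate_cohort(spec)
        write_cohort_csv(cohort, out / "cohort.csv")
        summarize_cohort(cohort).to_csv(out / "cohort_summary.csv")
        spec.to_yaml(out / "cohort_spec.yaml")
        paths["cohort"] = out / "cohort.csv"
        paths["cohort_summary"] = out / "cohort_summary.csv"
        return cohort

    cohort = stage("cohort")(_cohort)

    settings = RunSettings(
        cost_table=cost_table, utility_table=utility_table,
        discount=DiscountSpec(config.discount_costs, config.discount_effects),
        horizon=config.horizon, sim_seed=config.seed_simulation,
        disability=disability,
    )

    def _base():
        model = CEAModel(
            cohort, disease_params=params, cost_table=cost_table,
            utility_table=utility_table, discount=settings.discount,
            horizon=config.horizon, include_indirect=config.include_indirect,
            disability=disability,
        )
        res = model.fit(seed=config.seed_simulation)
        with open(out / "base_case.json", "w") as fh:
            json.dump(res.to_dict(), fh, indent=2)
        res.summary().to_csv(out / "base_case.csv")
        for arm, run in res.runs.items():
            run.to_frame().to_csv(out / f"trajectories_{arm.lower()}.csv", index=False)
            paths[f"trajectories_{arm.lower()}"] = out / f"trajectories_{arm.lower()}.csv"
        paths["base_case_json"] = out / "base_case.json"
        paths["base_case_csv"] = out / "base_case.csv"
        return model, res

    model, base_res = stage("base-case")(_base)
    log_lines.append(f"base case: {base_res!r}")

    if config.run_scenarios:
        def _scen():
            results = run_suite(default_suite(), cohort, params, settings)
            report = suite_report(results)
            report.to_csv(out / "scenarios.csv")
            with open(out / "scenarios.md", "w") as fh:
                fh.write("# Scenario analyses\n\n")
                fh.write(report.to_markdown(floatfmt=",.3f"))
                fh.write("\n")
            paths["scenarios_csv"] = out / "scenarios.csv"
            paths["scenarios_md"] = out / "scenarios.md"
            return report

        stage("scenarios")(_scen)

    if config.ceac.run:
        def _ceac():
            grid = default_wtp_grid(step=config.ceac.wtp_step, top=config.ceac.wtp_max)
            curve = model.ceac(
                n_outer=config.ceac.n_outer, n_inner=config.ceac.n_inner,
                cohort_spec=config.cohort_spec(), cost_cv=config.ceac.cost_cv,
                wtp_grid=grid, seed=config.seed_psa,
            )
            curve.to_frame().to_csv(out / "ceac.csv", index=False)
            curve.plot(path=out / "ceac.png")
            paths["ceac_csv"] = out / "ceac.csv"
            paths["ceac_png"] = out / "ceac.png"
            return curve

        stage("ceac")(_ceac)

    log_path = out / "log.txt"
    log_path.write_text("\n".join(log_lines) + "\n")
    paths["log"] = log_path
    return paths
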