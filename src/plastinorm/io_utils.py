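"""CSV interchange, schema validation, configuration and pipeline orchestration.

Canonical long-format growth-rate CSV columns:
``genotype, mechanism, env_param, setting, replicate, rate_mm_per_hr,
missing_flag``; race-tube CSV columns: ``assay_id, time_hr, position_mm``.
A column-mapping block in the config can adapt external layouts to these
names.  Malformed rows are collected into an error report, never silently
dropped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synthetic_data import (
    CONTROL_GENOTYPE,
    DEFAULT_GENOTYPES,
    SETTING_GRIDS,
    RaceTubeSeries,
    ValidationError,
    default_simulation_config,
    enumerate_design,
    simulate_growth_rates,
)
from . import bayes_contrasts, growth_rates, mixed_anova, reaction_norms

__all__ = [
    "RATE_COLUMNS",
    "PipelineConfig",
    "read_phenotype_table",
    "read_race_tubes",
    "write_growth_table",
    "write_race_tubes",
    "run_pipeline",
]

log = logging.getLogger(__name__)

RATE_COLUMNS = ["genotype", "mechanism", "env_param", "setting", "replicate",
                "rate_mm_per_hr", "missing_flag"]
RACETUBE_COLUMNS = ["assay_id", "time_hr", "position_mm"]


# ---------------------------------------------------------------------------
# reading and validation
# ---------------------------------------------------------------------------

def read_phenotype_table(
    path: str | Path,
    schema: str = "rates",
    column_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame | list[RaceTubeSeries], list[dict]]:
    """Read and validate a phenotype CSV.

    Returns ``(data, errors)``: for ``schema='rates'`` a typed DataFrame of
    the valid rows plus a list of row-level error records; for
    ``schema='racetube'`` a list of :class:`RaceTubeSeries`.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    raw = pd.read_csv(path, dtype=str)
    if column_map:
        raw = raw.rename(columns=column_map)
    if schema == "rates":
        return _validate_rates(raw)
    if schema == "racetube":
        return _validate_racetubes(raw)
    raise ValidationError(f"unknown schema {schema!r}")


def _require_columns(df: pd.DataFrame, needed: list[str]) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")


def _validate_rates(raw: pd.DataFrame) -> tuple[pd.DataFrame, list[dict]]:
    needed = ["genotype", "env_param", "setting", "replicate", "rate_mm_per_hr"]
    _require_columns(raw, needed)
    errors: list[dict] = []
    rows = []
    known_grids = {p: set(g) for p, g in SETTING_GRIDS.items()}
    off_grid: set[tuple[str, float]] = set()
    for i, row in raw.iterrows():
        try:
            setting = float(row["setting"])
            replicate = int(row["replicate"])
            missing = int(row.get("missing_flag", 0) or 0)
            rate_str = row["rate_mm_per_hr"]
            if missing or (isinstance(rate_str, float) and np.isnan(rate_str)) or rate_str in ("", "NA", None):
                rate = np.nan
                missing = 1
            else:
                rate = float(rate_str)
                if rate < 0:
                    raise ValueError("negative growth rate")
        except (TypeError, ValueError) as exc:
            errors.append({"row": int(i), "error": str(exc)})
            continue
        param = row["env_param"]
        if param in known_grids and not missing and setting not in known_grids[param]:
            off_grid.add((param, setting))
        rows.append({
            "genotype": row["genotype"],
            "mechanism": row.get("mechanism", ""),
            "env_param": param,
            "setting": setting,
            "replicate": replicate,
            "rate_mm_per_hr": rate,
            "missing_flag": missing,
        })
    if off_grid:
        log.warning("settings outside the published grids: %s", sorted(off_grid))
    return pd.DataFrame(rows, columns=RATE_COLUMNS), errors


def _validate_racetubes(raw: pd.DataFrame) -> tuple[list[RaceTubeSeries], list[dict]]:
    _require_columns(raw, RACETUBE_COLUMNS)
    errors: list[dict] = []
    series = []
    for aid, grp in raw.groupby("assay_id", sort=True):
        try:
            t = grp["time_hr"].astype(float).to_numpy()
            p = grp["position_mm"].astype(float).to_numpy()
            order = np.argsort(t)
            t, p = t[order], p[order]
            visible = np.nonzero(p > 1.0)[0]
            series.append(RaceTubeSeries(str(aid), t, p, int(visible[0]) if visible.size else -1))
        except (TypeError, ValueError, ValidationError) as exc:
            errors.append({"assay_id": str(aid), "error": str(exc)})
    return series, errors


def write_growth_table(table: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in RATE_COLUMNS if c in table.columns]
    table[cols].to_csv(path, index=False)


def write_race_tubes(series_list: list[RaceTubeSeries], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"assay_id": s.assay_id, "time_hr": s.mark_times, "position_mm": s.positions})
        for s in series_list
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    out_dir: Path = Path("pipeline_out")
    input_table: Path | None = None      # None = simulate the demo dataset
    column_map: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    control: str = CONTROL_GENOTYPE
    spline_df: int = 4
    alpha: float = 0.05
    run_norms: bool = True
    run_anova: bool = True
    run_contrasts: bool = True
    contrast_cells: list[tuple[str, float]] = field(
        default_factory=lambda: [("salt", 0.8)]
    )
    mcmc: dict = field(default_factory=lambda: {
        "n_chains": 2, "burn_in": 2000, "n_saved": 1000, "thin": 2,
    })

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        self.out_dir = Path(self.out_dir)
        if self.input_table is not None:
            self.input_table = Path(self.input_table)
            if not self.input_table.exists():
                raise ValidationError(f"input table not found: {self.input_table}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "contrast_cells" in raw:
            raw["contrast_cells"] = [
                (str(p), float(s)) for p, s in raw["contrast_cells"]
            ]
        return cls(**raw)

    def digest(self) -> str:
        # output location does not affect results; keep reports comparable
        payload = {k: str(v) for k, v in self.__dict__.items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate -> rates -> norms -> anova -> contrasts and report.

    Any stage failure aborts with the stage name; outputs of completed
    stages stay on disk.  Identical config and seed give an identical
    report body.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "config_hash": config.digest(),
            "seed": config.seed,
            "version": __version__,
        }
    }
    stage = "input"
    try:
        if config.input_table is None:
            stage = "simulate"
            design = enumerate_design(DEFAULT_GENOTYPES, SETTING_GRIDS, 5)
            sim_cfg = default_simulation_config(DEFAULT_GENOTYPES, seed=config.seed)
            table = simulate_growth_rates(sim_cfg, design)
            write_growth_table(table, out / "growth_rates.csv")
        else:
            table, errors = read_phenotype_table(
                config.input_table, "rates", config.column_map or None
            )
            if errors:
                pd.DataFrame(errors).to_csv(out / "input_errors.csv", index=False)
        report["input"] = {
            "n_rows": int(len(table)),
            "n_missing": int(table["missing_flag"].sum()),
        }

        stage = "rates_qc"
        report["qc"] = {
            k: v for k, v in growth_rates.qc_summary(table).items()
        }

        if config.run_norms:
            stage = "norms"
            opt_rows = []
            for genotype in sorted(table["genotype"].unique()):
                for param in sorted(table["env_param"].unique()):
                    norm = reaction_norms.build_norm(table, genotype, param)
                    fit = reaction_norms.fit_natural_spline(norm, df=config.spline_df)
                    opt = reaction_norms.estimate_optimum(fit)
                    opt_rows.append({
                        "genotype": genotype, "env_param": param,
                        "optimum_setting": opt.optimum_setting,
                        "optimum_rate": opt.optimum_rate,
                        "at_boundary": opt.at_boundary,
                    })
            optima = pd.DataFrame(opt_rows)
            optima.to_csv(out / "optima.csv", index=False)
            ctrl = optima[optima["genotype"] == config.control]
            report["optima"] = {
                "n_genotypes": int(optima["genotype"].nunique()),
                "control": {
                    r["env_param"]: round(float(r["optimum_setting"]), 3)
                    for _, r in ctrl.iterrows()
                },
            }

        if config.run_anova:
            stage = "anova"
            anova_summary = {}
            pairwise_frames = []
            for param in sorted(table["env_param"].unique()):
                sub = table[table["env_param"] == param]
                fit = mixed_anova.fit_mixed_model(sub, mixed_anova.per_param_spec())
                res = mixed_anova.anova_table(fit)
                res.fixed.to_csv(out / f"anova_fixed_{param}.csv", index=False)
                if res.random is not None:
                    res.random.to_csv(out / f"anova_random_{param}.csv", index=False)
                pw = mixed_anova.pairwise_control_tests(
                    table, config.control, param, alpha=config.alpha
                )
                pw.insert(0, "env_param", param)
                pairwise_frames.append(pw)
                anova_summary[param] = {
                    "interaction_p": float(
                        res.fixed.set_index("term").loc["mechanism:setting", "p_value"]
                    ),
                    "n_significant_pairwise": int(pw["significant"].sum()),
                }
            pd.concat(pairwise_frames, ignore_index=True).to_csv(
                out / "pairwise_tests.csv", index=False
            )
            report["anova"] = anova_summary

        if config.run_contrasts:
            stage = "contrasts"
            rows = []
            for param, setting in config.contrast_cells:
                cell = table[
                    (table["env_param"] == param) & (table["setting"] == setting)
                ]
                draws = bayes_contrasts.sample_posterior(
                    cell,
                    cfg=bayes_contrasts.McmcConfig(seed=config.seed, **config.mcmc),
                )
                for mutant in draws.genotypes:
                    if mutant == config.control:
                        continue
                    c = bayes_contrasts.compute_contrast(draws, mutant, config.control)
                    rows.append({
                        "env_param": param, "setting": setting, "mutant": mutant,
                        "control": config.control, "mean_diff": c.mean_diff,
                        "hpd_low": c.hpd_low, "hpd_high": c.hpd_high,
                        "significant": c.significant,
                    })
            contrasts = pd.DataFrame(rows)
            contrasts.to_csv(out / "contrasts.csv", index=False)
            report["contrasts"] = {
                "n_cells": len(config.contrast_cells),
                "n_significant": int(contrasts["significant"].sum()),
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
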