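"""End-to-end pipeline: synthesise data, fit physiology, simulate climate,
report risk. Writes every intermediate table plus a machine-readable
summary and a run log; identical config + seed gives identical outputs."""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict
from pathlib import Path

from . import __version__
from .config import RunConfig, config_hash
from .development import anova_sequential, fit_emergence_lm
from .io import write_microclimate, write_table
from .leaf_energy import leaf_series
from .microclimate import generate_microclimate
from .preference import preference_summary
from .risk import scenario_report
from .synthetic import (
    EmergenceDesign,
    GradientDesign,
    HeatShockDesign,
    simulate_emergence,
    simulate_gradient_trials,
    simulate_heat_shock,
)
from .thermal_limits import compare_lt50, fit_logistic_survival

__all__ = ["run_pipeline", "PipelineError"]

logger = logging.getLogger("aspentherm")

# generator truths mirror the published point estimates so the synthetic
# pipeline exercises the same parameter regime as the field study
HOST_TRUTH = {"true_lt50": 42.1, "true_slope": -0.86}
PARASITOID_TRUTH = {"true_lt50": 37.4, "true_slope": -0.25}


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained on disk."""


def run_pipeline(config: RunConfig, heat_shock_n: int = 200) -> Path:
    """Run synth -> fits -> microclimate -> leaf -> risk and write outputs.

    ``heat_shock_n`` is the per-temperature sample size for the synthetic
    heat-shock trials (larger than the field study's ~8 so the pinned
    truths are recovered stably in a single run).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config_sha256": config_hash(config),
    }
    stage = "synthetic data"
    try:
        host_design = HeatShockDesign(
            species="host", seed=config.seed, n_per_temperature=heat_shock_n, **HOST_TRUTH
        )
        para_design = HeatShockDesign(
            species="parasitoid", seed=config.seed + 1, n_per_temperature=heat_shock_n,
            **PARASITOID_TRUTH,
        )
        host_records = simulate_heat_shock(host_design)
        para_records = simulate_heat_shock(para_design)
        write_table(host_records + para_records, "heat_shock", out / "heat_shock.csv")

        trials = simulate_gradient_trials(GradientDesign(seed=config.seed + 2))
        write_table(trials, "gradient", out / "gradient.csv")

        emergence = simulate_emergence(EmergenceDesign(seed=config.seed + 3))
        write_table(emergence, "emergence", out / "emergence.csv")

        stage = "thermal limits"
        fit_host = fit_logistic_survival(host_records, link=config.analysis.link)
        fit_para = fit_logistic_survival(para_records, link=config.analysis.link)
        diff, diff_se, z = compare_lt50(fit_host, fit_para)
        summary["lt50"] = {
            "host": fit_host.lt50,
            "host_se": fit_host.lt50_se,
            "parasitoid": fit_para.lt50,
            "parasitoid_se": fit_para.lt50_se,
            "difference": diff,
            "difference_se": diff_se,
            "z": z,
        }

        stage = "thermal preference"
        pref = preference_summary(trials, levene_center=config.analysis.levene_center)
        summary["preference"] = {
            "n": pref.n,
            "tpref_mean": pref.tpref_mean,
            "tpref_sd": pref.tpref_sd,
            "ci95": list(pref.ci95),
            "levene_F": pref.levene_F,
            "levene_p": pref.levene_p,
            "paired_t": pref.paired_t,
            "paired_p": pref.paired_p,
            "rearing_anova_F": pref.rearing_anova_F,
            "rearing_anova_p": pref.rearing_anova_p,
        }

        stage = "development"
        fit = fit_emergence_lm(emergence)
        table = anova_sequential(fit)
        summary["emergence_anova"] = [
            asdict(row) for row in list(table.rows) + [table.residual]
        ]

        stage = "microclimate and risk"
        reports = []
        for scenario in config.scenarios:
            for month in (5, 6, 7):
                micro = generate_microclimate(config.site, month, scenario)
                write_microclimate(micro, out / f"microclimate_{scenario.name}_m{month:02d}.csv")
                leaf = leaf_series(micro, config.leaf, elevation=config.site.elevation)
                leaf.to_dataframe().to_csv(
                    out / f"leaf_{scenario.name}_m{month:02d}.csv",
                    index=False, float_format="%.6g",
                )
            report = scenario_report(
                config.site, scenario, config.leaf,
                lt50_host=fit_host.lt50, lt50_parasitoid=fit_para.lt50,
                tpref_mean=pref.tpref_mean, tpref_sd=pref.tpref_sd,
            )
            reports.append(report)
            logger.info("scenario %s: window %.2f h/day, risks %.1f/%.1f h",
                        report.scenario, report.opportunity_window,
                        report.host_thermal_risk, report.parasitoid_thermal_risk)
        summary["risk"] = [asdict(r) for r in reports]
        risk_rows = [asdict(r) for r in reports]
        _write_risk_csv(risk_rows, out / "risk_report.csv")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\n{exc}\n")
        raise PipelineError(f"pipeline failed during stage {stage!r}: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str) + "\n")
    logger.info("pipeline complete: %s", out)
    return out


def _write_risk_csv(rows: list[dict], path: Path) -> None:
    import csv

    columns = [
        "scenario", "host_thermal_risk", "parasitoid_thermal_risk",
        "opportunity_window", "host_safety_margin", "parasitoid_safety_margin",
        "max_leaf_temperature", "max_air_temperature",
    ]
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(columns)
        for r in rows:
            writer.writerow([
                r["scenario"],
                *[f"{r[c]:.6g}" for c in columns[1:]],
            ])
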