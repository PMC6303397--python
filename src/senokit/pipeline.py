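"""Configuration, orchestration and serialization for end-to-end runs.

A run is described by a YAML config (simulator settings, analysis
parameters, stage toggles, one seed).  The master seed fans out to fixed
per-stage child seeds via ``numpy.random.SeedSequence`` spawn keys, so
disabling one stage never shifts another's random stream.  Every artifact
carries the config hash; the serialized report contains no wall-clock
values, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, StageError
from .expression import write_counts
from .gating import GatingConfig, default_gating_config, senescent_fraction
from .rejuvenation import rejuvenation_report, serialize_report
from .simulate import (
    CellSimConfig,
    ExpressionSimConfig,
    SurvivalSimConfig,
    simulate_cell_features,
    simulate_counts,
    simulate_survival,
)
from .survival import gehan_breslow_wilcoxon, km_estimate, pairwise_gbw

log = logging.getLogger("senokit")

# Fixed spawn keys: stage streams are independent of which stages are enabled.
STAGE_SPAWN_KEYS = {"expression": 0, "survival": 1, "gating": 2}


@dataclass
class AnalysisParams:
    alpha: float = 0.05
    lfc_min: float = 0.0
    detection_threshold: float = 1.0
    pseudocount: float = 1.0
    conf_level: float = 0.95

    def validate(self) -> list[str]:
        problems = []
        if not 0 < self.alpha < 1:
            problems.append(f"analysis.alpha must be in (0, 1), got {self.alpha}")
        if self.lfc_min < 0:
            problems.append(f"analysis.lfc_min must be >= 0, got {self.lfc_min}")
        if self.detection_threshold < 0:
            problems.append("analysis.detection_threshold must be >= 0")
        if self.pseudocount <= 0:
            problems.append("analysis.pseudocount must be > 0")
        if not 0 < self.conf_level < 1:
            problems.append(f"analysis.conf_level must be in (0, 1), got {self.conf_level}")
        return problems


@dataclass
class RunConfig:
    seed: int = 0
    stages: dict = field(
        default_factory=lambda: {"expression": True, "survival": True, "gating": True}
    )
    expression_sim: ExpressionSimConfig = field(default_factory=ExpressionSimConfig)
    survival_sim: SurvivalSimConfig = field(default_factory=SurvivalSimConfig)
    cell_sim: CellSimConfig = field(default_factory=CellSimConfig)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    gating: GatingConfig | None = None  # None -> simulator-matched defaults
    write_tables: bool = True

    def resolved_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "stages": dict(self.stages),
            "expression_sim": dataclasses.asdict(self.expression_sim),
            "survival_sim": _survival_sim_dict(self.survival_sim),
            "cell_sim": dataclasses.asdict(self.cell_sim),
            "analysis": dataclasses.asdict(self.analysis),
            "gating": (self.gating or default_gating_config()).to_dict(),
            "write_tables": self.write_tables,
        }
        # canonical JSON form (tuples -> lists) so resolve -> dump -> resolve
        # is the identity and the config hash is stable
        return json.loads(json.dumps(d, sort_keys=True, default=_json_default))

    def config_hash(self) -> str:
        payload = json.dumps(self.resolved_dict(), sort_keys=True, default=_json_default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _survival_sim_dict(cfg: SurvivalSimConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["groups"] = {
        name: dataclasses.asdict(g) if dataclasses.is_dataclass(g) else dict(g)
        for name, g in cfg.groups.items()
    }
    return d


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


_TOP_KEYS = {
    "seed",
    "stages",
    "expression_sim",
    "survival_sim",
    "cell_sim",
    "analysis",
    "gating",
    "write_tables",
}


def _build_section(cls, data: dict, section: str, problems: list[str]):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        problems.append(f"{section}: unknown key(s) {sorted(unknown)}")
        data = {k: v for k, v in data.items() if k in known}
    for key in ("tissues", "baseline_mean_log2"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    try:
        obj = cls(**data)
    except (TypeError, ConfigurationError) as exc:
        problems.append(f"{section}: {exc}")
        return cls()
    return obj


def validate_config(path_or_dict) -> RunConfig:
    """Resolve a YAML config (strict keys); raise listing every violation."""
    if isinstance(path_or_dict, (str, Path)):
        raw = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        raw = dict(path_or_dict)
    problems: list[str] = []
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        problems.append(f"unknown top-level key(s): {sorted(unknown)}")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        problems.append(f"seed must be a non-negative integer, got {seed!r}")
        seed = 0
    stages = {"expression": True, "survival": True, "gating": True}
    for k, v in (raw.get("stages") or {}).items():
        if k not in stages:
            problems.append(f"stages: unknown stage '{k}'")
        elif not isinstance(v, bool):
            problems.append(f"stages.{k} must be boolean")
        else:
            stages[k] = v

    expr = _build_section(
        ExpressionSimConfig, raw.get("expression_sim") or {}, "expression_sim", problems
    )
    surv = _build_section(SurvivalSimConfig, raw.get("survival_sim") or {}, "survival_sim", problems)
    cell = _build_section(CellSimConfig, raw.get("cell_sim") or {}, "cell_sim", problems)
    analysis = _build_section(AnalysisParams, raw.get("analysis") or {}, "analysis", problems)
    problems.extend(analysis.validate())
    for cfg, section in ((expr, "expression_sim"), (surv, "survival_sim"), (cell, "cell_sim")):
        try:
            cfg.validate()
        except ConfigurationError as exc:
            problems.append(f"{section}: {exc}")

    gating = None
    if raw.get("gating") is not None:
        try:
            gating = GatingConfig.from_dict(raw["gating"])
        except (ConfigurationError, KeyError, TypeError) as exc:
            problems.append(f"gating: {exc}")

    write_tables = raw.get("write_tables", True)
    if not isinstance(write_tables, bool):
        problems.append("write_tables must be boolean")
        write_tables = True

    if problems:
        raise ConfigurationError("invalid configuration:\n  - " + "\n  - ".join(problems))
    return RunConfig(
        seed=seed,
        stages=stages,
        expression_sim=expr,
        survival_sim=surv,
        cell_sim=cell,
        analysis=analysis,
        gating=gating,
        write_tables=write_tables,
    )


def demo_config_path() -> Path:
    """Path of the packaged end-to-end demo configuration."""
    return Path(resources.files("senokit") / "configs" / "demo.yaml")


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage child seed (< 2**31) derived from the master seed."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(STAGE_SPAWN_KEYS[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the enabled stages and write the deterministic run report.

    Returns the report dict; also writes ``report.json`` plus per-stage
    TSV/CSV tables under ``out_dir``.  Failures abort with the failing stage
    named.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    report: dict = {
        "provenance": {
            "config_hash": chash,
            "seed": config.seed,
            "software": f"senokit {__version__}",
            "prng": "numpy PCG64 (default_rng), per-stage SeedSequence spawn",
        },
        "stages": {},
    }

    if config.stages.get("expression", True):
        log.info("stage expression: start")
        try:
            expr_cfg = dataclasses.replace(
                config.expression_sim, seed=stage_seed(config.seed, "expression")
            )
            cm, truth = simulate_counts(expr_cfg)
            log.info(
                "stage expression: simulated %d genes x %d samples",
                len(cm.gene_ids),
                len(cm.sample_ids),
            )
            rep = rejuvenation_report(
                cm,
                truth.sasp_gene_ids,
                alpha=config.analysis.alpha,
                lfc_min=config.analysis.lfc_min,
                detection_threshold=config.analysis.detection_threshold,
                pseudocount=config.analysis.pseudocount,
                conf_level=config.analysis.conf_level,
            )
            rep["simulation_truth"] = {
                "true_tilt": truth.true_tilt,
                "rejuvenation_kappa": expr_cfg.rejuvenation_kappa,
                "n_sasp_genes": len(truth.sasp_gene_ids),
            }
            report["stages"]["expression"] = rep
            if config.write_tables:
                write_counts(cm, out / "counts.tsv", out / "sample_metadata.csv")
                truth.table.to_csv(out / "expression_truth.csv", index=False)
                from .expression import fold_change_table, log_expression, size_factors

                factors = size_factors(cm.counts)
                log_mat = log_expression(cm.counts, factors, config.analysis.pseudocount)
                for tissue in expr_cfg.tissues:
                    fct = fold_change_table(
                        log_mat, cm.metadata, tissue,
                        config.analysis.detection_threshold, config.analysis.pseudocount,
                    )
                    with open(out / f"fold_changes_{tissue}.tsv", "w") as fh:
                        fh.write(
                            f"# tissue={tissue} config_hash={chash} "
                            f"detection_threshold={config.analysis.detection_threshold} "
                            f"pseudocount={config.analysis.pseudocount} log_base=2\n"
                        )
                        fct.table.to_csv(fh, sep="\t")
        except StageError:
            raise
        except Exception as exc:  # wrap with stage context
            raise StageError("expression", str(exc)) from exc
        log.info("stage expression: done")

    if config.stages.get("survival", True):
        log.info("stage survival: start")
        try:
            surv_cfg = dataclasses.replace(
                config.survival_sim, seed=stage_seed(config.seed, "survival")
            )
            table = simulate_survival(surv_cfg)
            groups = sorted(table["group"].unique())
            medians = {}
            curves = []
            for g in groups:
                km = km_estimate(table, g)
                medians[g] = km.median
                c = km.curve()
                c.insert(0, "group", g)
                curves.append(c)
            test = gehan_breslow_wilcoxon(table, groups)
            report["stages"]["survival"] = {
                "n_subjects": int(len(table)),
                "n_events": int(table["event"].sum()),
                "medians_days": medians,
                "gbw": test.to_dict(),
                "gbw_pairwise": pairwise_gbw(table, groups).to_dict(orient="records"),
            }
            if config.write_tables:
                table.to_csv(out / "survival.csv", index=False)
                pd.concat(curves, ignore_index=True).to_csv(out / "km_curves.csv", index=False)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("survival", str(exc)) from exc
        log.info("stage survival: done")

    if config.stages.get("gating", True):
        log.info("stage gating: start")
        try:
            cell_cfg = dataclasses.replace(config.cell_sim, seed=stage_seed(config.seed, "gating"))
            cells, cell_truth = simulate_cell_features(cell_cfg)
            gcfg = config.gating or default_gating_config()
            result = senescent_fraction(cells, gcfg)
            report["stages"]["gating"] = {
                "result": result.to_dict(),
                "true_senescent_fraction": cell_truth.senescent_fraction,
            }
            if config.write_tables:
                cells.to_csv(out / "cell_features.csv")
                cell_truth.labels.to_csv(out / "cell_labels.csv")
        except StageError:
            raise
        except Exception as exc:
            raise StageError("gating", str(exc)) from exc
        log.info("stage gating: done")

    text = serialize_report(_with_hash(report, chash))
    (out / "report.json").write_text(text)
    (out / "config.resolved.yaml").write_text(
        f"# config_hash: {chash}\n"
        + yaml.safe_dump(json.loads(json.dumps(config.resolved_dict(), default=_json_default)))
    )
    return json.loads(text)


def _with_hash(report: dict, chash: str) -> dict:
    report = dict(report)
    report["provenance"] = dict(report["provenance"], config_hash=chash)
    return report
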