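"""End-to-end orchestration: simulate/load -> select -> score -> quantify -> panel.

A run is described by a YAML config (see :class:`RunConfig`). Every output
table is plain TSV with a metadata preamble (tool version, seed, config
hash), so a run is reproducible and each stage can be re-run from its
on-disk inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .bisulfite_scoring import conversion_rate, score_traces
from .candidate_selection import (
    ExpressionMatrix,
    SelectionConfig,
    select_candidates,
    top_candidates,
)
from .errors import ConfigError, MethPanelError
from .io import config_hash, read_tsv, write_tsv
from .panel_stats import (
    CONTROL_GROUPS,
    PanelConfig,
    calibrate_threshold,
    fisher_exact,
    frequency_table,
    mann_whitney,
    panel_score,
    roc_auc,
    validate_cohort,
)
from .qmsp_quant import quantify_plate
from .synthio import (
    SimulationConfig,
    simulate_expression,
    simulate_qmsp_cohort,
    simulate_traces,
)

log = logging.getLogger("methpanel")


@dataclass
class RunConfig:
    """Parsed pipeline run configuration.

    Exactly one of ``simulate`` (a :class:`SimulationConfig` block) or
    ``inputs`` (paths to expression/meta/plate/cohort/traces TSVs) must be
    provided.
    """

    outdir: Path
    seed: int = 0
    simulate: SimulationConfig | None = None
    inputs: dict[str, Path] = field(default_factory=dict)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    panel_genes: tuple[str, ...] | None = None
    threshold: float | str = "auto"
    top: int | None = 24
    plots: bool = False
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        if "outdir" not in data:
            raise ConfigError("run config requires 'outdir'")
        seed = int(data.get("seed", 0))
        simulate = None
        inputs: dict[str, Path] = {}
        if "simulate" in data:
            sim = dict(data["simulate"] or {})
            sim.setdefault("seed", seed)
            simulate = SimulationConfig.from_dict(sim)
        elif "inputs" in data:
            required = ("expression", "meta", "plate", "cohort", "traces")
            for key in required:
                if key not in data["inputs"]:
                    raise ConfigError(f"inputs block missing path for {key!r}")
                path = Path(data["inputs"][key])
                if not path.exists():
                    raise ConfigError(f"input file does not exist: {path}")
                inputs[key] = path
        else:
            raise ConfigError("run config requires a 'simulate' or 'inputs' block")
        panel_block = dict(data.get("panel", {}) or {})
        genes = panel_block.get("genes")
        return cls(
            outdir=Path(data["outdir"]),
            seed=seed,
            simulate=simulate,
            inputs=inputs,
            selection=SelectionConfig(**(data.get("selection", {}) or {})),
            panel_genes=tuple(genes) if genes else None,
            threshold=panel_block.get("threshold", "auto"),
            top=data.get("top", 24),
            plots=bool(data.get("plots", False)),
            raw=dict(data),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"run config file does not exist: {path}")
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _meta(cfg: RunConfig) -> dict[str, Any]:
    # hash characterises the analysis, not where it is written
    hashed = {k: v for k, v in cfg.raw.items() if k != "outdir"}
    return {"seed": cfg.seed, "config_sha256": config_hash(hashed)}


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute all stages and write the report bundle to ``cfg.outdir``.

    Returns a summary dict (also written as ``summary.json``). Any stage
    error aborts the run with the stage name in the log record.
    """
    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    meta = _meta(cfg)
    summary: dict[str, Any] = {
        "version": __version__, "seed": cfg.seed,
        "config_sha256": meta["config_sha256"],
    }

    stage = "simulate" if cfg.simulate else "load"
    try:
        if cfg.simulate:
            log.info("[simulate] generating synthetic tables (seed=%d)", cfg.seed)
            expr, expr_truth = simulate_expression(cfg.simulate)
            plate, cohort, qmsp_truth = simulate_qmsp_cohort(cfg.simulate)
            traces, trace_truth = simulate_traces(cfg.simulate)
            values = expr.values.rename_axis("gene").reset_index()
            write_tsv(values, out / "expression.tsv", meta)
            write_tsv(expr.meta, out / "meta.tsv", meta)
            write_tsv(plate, out / "plate.tsv", meta)
            write_tsv(cohort, out / "cohort.tsv", meta)
            write_tsv(traces, out / "traces.tsv", meta)
            write_tsv(expr_truth, out / "truth_candidates.tsv", meta)
            write_tsv(qmsp_truth, out / "truth_pmr.tsv", meta)
            write_tsv(trace_truth, out / "truth_traces.tsv", meta)
        else:
            log.info("[load] reading input tables")
            values = read_tsv(cfg.inputs["expression"]).set_index("gene")
            expr = ExpressionMatrix(values, read_tsv(cfg.inputs["meta"]))
            plate = read_tsv(cfg.inputs["plate"])
            cohort = read_tsv(cfg.inputs["cohort"])
            traces = read_tsv(cfg.inputs["traces"])

        stage = "select"
        log.info("[select] running three-criteria candidate screen")
        report = select_candidates(expr, cfg.selection)
        write_tsv(report, out / "candidates.tsv", meta)
        selected = top_candidates(report, cfg.top)
        summary["n_candidates"] = int(report["selected"].sum())

        stage = "score-bisulfite"
        log.info("[score-bisulfite] scoring %d trace rows", len(traces))
        calls = score_traces(traces)
        write_tsv(calls, out / "cpg_calls.tsv", meta)
        if "site_type" in traces.columns and (traces["site_type"] == "non_cpg_c").any():
            summary["bisulfite_conversion_rate"] = conversion_rate(traces)

        stage = "quantify"
        log.info("[quantify] fitting standard curves and computing PMR")
        pmr = quantify_plate(plate)
        write_tsv(pmr, out / "pmr.tsv", meta)

        stage = "panel"
        cohort = validate_cohort(cohort)
        control_samples = cohort.loc[
            cohort["group"].isin(CONTROL_GROUPS), "sample"
        ]
        control_pmrs = pmr.loc[pmr["sample"].isin(control_samples), "pmr"]
        if cfg.threshold == "auto":
            threshold = float(calibrate_threshold(control_pmrs))
        else:
            threshold = float(cfg.threshold)
        genes = cfg.panel_genes or tuple(sorted(pmr["gene"].unique()))
        panel_cfg = PanelConfig(threshold=threshold, genes=genes)
        summary["threshold"] = threshold
        log.info("[panel] threshold=%.1f genes=%s", threshold, ",".join(genes))

        calls_pos = pmr[["sample", "gene", "pmr"]].copy()
        calls_pos["positive"] = calls_pos["pmr"] >= threshold
        freq = frequency_table(calls_pos[["sample", "gene", "positive"]], cohort)
        write_tsv(freq, out / "frequency_table.tsv", meta)

        stats_rows = []
        merged = calls_pos.merge(cohort, on="sample")
        for gene, sub in merged.groupby("gene", sort=True):
            lym = sub[sub["class"] == "lymphoma"]
            ctl = sub[sub["class"] == "non-lymphoma"]
            if len(lym) and len(ctl):
                u, p_mw = mann_whitney(lym["pmr"], ctl["pmr"])
                stats_rows.append(
                    {"gene": gene, "test": "mann_whitney_lymphoma_vs_control",
                     "statistic": u, "p_value": p_mw}
                )
            by_series = {
                s: (int(ssub["positive"].sum()), len(ssub))
                for s, ssub in lym.groupby("series")
            }
            if {"test", "validation"} <= set(by_series):
                (a, na), (c, nc) = by_series["test"], by_series["validation"]
                p_f = fisher_exact(a, na - a, c, nc - c)
                stats_rows.append(
                    {"gene": gene, "test": "fisher_test_vs_validation",
                     "statistic": float("nan"), "p_value": p_f}
                )
        write_tsv(pd.DataFrame(stats_rows), out / "statistics.tsv", meta)

        labels = dict(zip(cohort["sample"], cohort["class"] == "lymphoma"))
        rocs = {}
        for gene, sub in merged.groupby("gene", sort=True):
            rocs[gene] = roc_auc(sub["pmr"], [labels[s] for s in sub["sample"]])
        scores = panel_score(pmr, panel_cfg)
        rocs["panel"] = roc_auc(
            scores["score"], [labels[s] for s in scores["sample"]]
        )
        roc_rows = []
        for name, roc in rocs.items():
            for thr, fpr, tpr in zip(roc.thresholds, roc.fpr, roc.tpr):
                roc_rows.append(
                    {"marker": name, "threshold": thr, "fpr": fpr, "tpr": tpr}
                )
        write_tsv(pd.DataFrame(roc_rows), out / "roc_points.tsv", meta)
        write_tsv(scores, out / "panel_scores.tsv", meta)
        summary["auc"] = {name: roc.auc for name, roc in rocs.items()}

        if cfg.plots:
            from .plots import plot_pmr_dots, plot_roc

            plot_pmr_dots(pmr, cohort, out / "pmr_dots.svg")
            plot_roc(rocs, out / "roc.svg")
    except MethPanelError as exc:
        log.error("[%s] stage failed: %s", stage, exc)
        raise

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("run complete: %s", out)
    return summary
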