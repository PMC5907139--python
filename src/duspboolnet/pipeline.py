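"""End-to-end orchestration: synth → qpcr → cluster → models → inference.

A single :class:`RunConfig` drives the whole analysis with one seed; every
stage writes its outputs into the run directory and contributes to a JSON +
Markdown summary report.  Reports carry no timestamps, so two runs with the
same config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import clustering, models, qpcr, synth
from .engine import symbol_string, export_heatmap, Trajectory
from .inference import infer_regulators, report_to_dict, top_symmetry_classes

__all__ = ["RunConfig", "StageError", "run_pipeline", "DEFAULT_CUT_HEIGHT"]

log = logging.getLogger("duspboolnet")

#: default dendrogram cut height, calibrated on the noise-free fixture to
#: recover the planted cluster count
DEFAULT_CUT_HEIGHT = 0.4

ALL_STAGES = ("synth", "qpcr", "cluster", "models", "inference")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    stages: tuple = ALL_STAGES
    seed: int = 0
    ct_table: str | None = None      # external CT CSV; None -> synth output
    cut_height: float = DEFAULT_CUT_HEIGHT
    deadband: float = clustering.DEFAULT_DEADBAND
    ct_noise_sd: float = 0.15
    herceptin: int = 1
    write_heatmaps: bool = True

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = json.load(fh)
        cfg = cls(**raw)
        cfg.stages = tuple(cfg.stages)
        return cfg


def run_pipeline(cfg: RunConfig, out_dir) -> dict:
    """Execute the enabled stages in order and write the summary report.

    Returns the report dict; ``report["all_expected_outcomes_met"]`` is
    False when any shipped model misses its stated qualitative outcome
    (callers should exit non-zero on that).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": list(cfg.stages)}
    series = None
    assignment = None
    patterns: dict = {}
    ct_path = Path(cfg.ct_table) if cfg.ct_table else None

    if "synth" in cfg.stages:
        log.info("stage synth: generating CT table (seed=%d)", cfg.seed)
        scfg = synth.default_config(seed=cfg.seed, ct_noise_sd=cfg.ct_noise_sd)
        table, truth = synth.generate_ct_table(scfg)
        ct_path = out / "ct_table.csv"
        table.to_csv(ct_path, index=False)
        with open(out / "planted_truth.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "assignment": {str(k): v for k, v in truth.assignment.items()},
                    "patterns": {str(k): v for k, v in truth.patterns.items()},
                    "true_fold_changes": {
                        g: list(map(float, row))
                        for g, row in truth.true_fold_changes.iterrows()
                    },
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        report["synth"] = {
            "n_genes": scfg.n_genes,
            "ct_noise_sd": scfg.ct_noise_sd,
            "ct_table": ct_path.name,
        }

    if "qpcr" in cfg.stages:
        if ct_path is None or not Path(ct_path).exists():
            raise StageError("qpcr", f"CT table not found: {ct_path}")
        log.info("stage qpcr: ΔΔCT on %s", ct_path)
        table = pd.read_csv(ct_path)
        series = qpcr.process_ct_table(table)
        frame = qpcr.series_frame(series)
        frame.to_csv(out / "expression_series.tsv", sep="\t", index=False)
        report["qpcr"] = {
            "n_genes": len(series),
            "n_significant": int(frame["significant"].sum()),
            "series_table": "expression_series.tsv",
        }

    if "cluster" in cfg.stages:
        if series is None:
            raise StageError("cluster", "no expression series (enable qpcr)")
        log.info("stage cluster: cut height %.3f", cfg.cut_height)
        cm = clustering.correlation_matrix(series)
        cm.frame().to_csv(out / "correlation_matrix.tsv", sep="\t")
        assignment = clustering.cluster(cm, cfg.cut_height)
        patterns = clustering.assign_patterns(series, assignment, cfg.deadband)
        pd.DataFrame(
            [
                {"gene": g, "cluster": str(c)}
                for g, c in assignment.assignment.items()
            ]
        ).to_csv(out / "clusters.tsv", sep="\t", index=False)
        _clustermap(cm, out / "clustermap.png")
        report["cluster"] = {
            "cut_height": cfg.cut_height,
            "clusters": {
                str(c): sorted(g)
                for c, g in assignment.members().items()
                if c != clustering.UNCLUSTERED
            },
            "unclustered": sorted(
                assignment.members().get(clustering.UNCLUSTERED, [])
            ),
            "patterns": {str(k): v for k, v in patterns.items()},
        }

    if "models" in cfg.stages:
        log.info("stage models: simulating shipped models")
        rows = []
        for dusp in models.MODELLED_DUSPS:
            facts = models.get_regulation_facts(dusp)
            if facts.inducers == models.UNKNOWN:
                continue
            model = models.build_model(dusp)
            attractor, classes = models.simulate_model(model, cfg.herceptin)
            for node, expected in model.expected.items():
                rows.append(
                    {
                        "dusp": dusp,
                        "node": node,
                        "expected": expected,
                        "observed": classes[node],
                        "agrees": classes[node] == expected,
                    }
                )
            if cfg.write_heatmaps:
                traj = Trajectory(
                    states=attractor.transient + attractor.cycle,
                    mode="sync",
                    clamps={"Herceptin": cfg.herceptin, "Basal": 1},
                )
                export_heatmap(traj, out / f"model_{dusp}")
        outcome = pd.DataFrame(rows)
        outcome.to_csv(out / "model_outcomes.tsv", sep="\t", index=False)
        report["models"] = {
            "outcomes": rows,
            "all_agree": bool(outcome["agrees"].all()),
        }

    if "inference" in cfg.stages:
        log.info("stage inference: ranking inducer hypotheses")
        inference_report = {}
        for dusp in models.INFERENCE_TARGETS:
            exp_pattern = _experimental_pattern(
                dusp, series, assignment, patterns
            )
            if exp_pattern is None:
                continue
            reports = infer_regulators(dusp, exp_pattern)
            inference_report[dusp] = {
                "experimental_pattern": exp_pattern,
                "ranking": [report_to_dict(r) for r in reports],
                "top_classes": [
                    sorted("+".join(sorted(m)) for m in cls)
                    for cls in top_symmetry_classes(reports)
                ],
            }
        report["inference"] = inference_report
        with open(out / "inference.json", "w", encoding="utf-8") as fh:
            json.dump(inference_report, fh, indent=2, sort_keys=True)

    expected_ok = report.get("models", {}).get("all_agree", True)
    report["all_expected_outcomes_met"] = bool(expected_ok)
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    (out / "report.md").write_text(_markdown_report(report), encoding="utf-8")
    return report


def _experimental_pattern(dusp, series, assignment, patterns):
    """Cluster descriptor if the DUSP clustered, else its own series pattern."""
    if assignment is not None and dusp in assignment.assignment:
        cid = assignment.assignment[dusp]
        if cid != clustering.UNCLUSTERED and cid in patterns:
            return patterns[cid]
        if dusp in patterns:
            return patterns[dusp]
    if series is not None and dusp in series:
        return clustering.series_pattern(series[dusp].fold_change)
    return None


def _clustermap(cm, path):
    import matplotlib

    matplotlib.use("Agg")
    import seaborn as sns
    import matplotlib.pyplot as plt

    g = sns.clustermap(cm.frame(), method="average", metric="euclidean",
                       vmin=0, vmax=1, cmap="viridis", figsize=(8, 8))
    g.savefig(path, dpi=120)
    plt.close("all")


def _markdown_report(report: dict) -> str:
    lines = [
        "# Pipeline report",
        "",
        f"- seed: {report['seed']}",
        f"- stages: {', '.join(report['stages']) if report['stages'] else '(none)'}",
        f"- all expected model outcomes met: {report['all_expected_outcomes_met']}",
        "",
    ]
    if "cluster" in report:
        lines.append("## Clusters")
        for cid, genes in sorted(report["cluster"]["clusters"].items()):
            pat = report["cluster"]["patterns"].get(cid, "")
            lines.append(f"- cluster {cid} [{pat}]: {', '.join(genes)}")
        uncl = report["cluster"]["unclustered"]
        if uncl:
            lines.append(f"- unclustered: {', '.join(uncl)}")
        lines.append("")
    if "models" in report:
        lines.append("## Model outcomes (expected vs observed)")
        for row in report["models"]["outcomes"]:
            mark = "ok" if row["agrees"] else "MISMATCH"
            lines.append(
                f"- {row['dusp']} / {row['node']}: expected {row['expected']}, "
                f"observed {row['observed']} [{mark}]"
            )
        lines.append("")
    if "inference" in report:
        lines.append("## Inferred inducers")
        for dusp, rep in sorted(report["inference"].items()):
            tops = ["{" + ", ".join(c) + "}" for c in rep["top_classes"]]
            lines.append(
                f"- {dusp} (pattern {rep['experimental_pattern']}): "
                f"top symmetry class(es) {', '.join(tops)}"
            )
        lines.append("")
    return "\n".join(lines)
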