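"""End-to-end workflow: filter each comparison, build the dynamics table,
summarize pathways, and write all result tables plus a run log."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from ._common import BindynError
from .dynamics import count_by_bin, dynamics_table
from .filtering import DEGCriteria, call_degs, summarize_comparison
from .io import (
    BinMap,
    ExperimentManifest,
    read_bin_map,
    read_deg_table,
    read_manifest,
    write_table,
)
from .pathways import (
    DEFAULT_PATHWAYS,
    PathwayDef,
    load_pathway_config,
    pathway_summary,
    pathway_summary_table,
)


@dataclass
class RunConfig:
    criteria: DEGCriteria = field(default_factory=DEGCriteria)
    outdir: Path = Path(".")
    baseline_stage: str | None = None  # default: first manifest stage
    pathway_defs: Sequence[PathwayDef] = DEFAULT_PATHWAYS
    adjust_pvalues: bool = False


@dataclass(frozen=True)
class RunResult:
    summary: Path
    dynamics: Path
    pathway: Path
    run_log: Path


def run_pipeline(
    config: RunConfig,
    manifest: ExperimentManifest | str | Path,
    binmap: BinMap | str | Path,
) -> RunResult:
    """Run filter -> dynamics -> pathways over every manifest comparison.

    Writes summary.tsv (per-comparison DEG summary), dynamics.tsv
    (per-bin counts, percent changes, patterns), pathway_summary.tsv and
    run_log.json into ``config.outdir``.
    """
    if not isinstance(manifest, ExperimentManifest):
        manifest = read_manifest(manifest)
    if not isinstance(binmap, BinMap):
        binmap = read_bin_map(binmap)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.baseline_stage is not None and config.baseline_stage not in {
        c.stage for c in manifest.comparisons
    }:
        raise BindynError(
            f"baseline stage {config.baseline_stage!r} not in manifest"
        )

    degs_per_stage: dict[str, list] = {}
    summary_rows = []
    for entry in manifest.comparisons:
        records = read_deg_table(entry.deg_table)
        degs = call_degs(records, config.criteria, adjust=config.adjust_pvalues)
        degs_per_stage[entry.stage] = degs
        s = summarize_comparison(degs, binmap)
        summary_rows.append(
            {
                "comparison_id": entry.comparison_id,
                "stage": entry.stage,
                "water_status": entry.water_status,
                **vars(s),
            }
        )
    summary_path = outdir / "summary.tsv"
    write_table(pd.DataFrame(summary_rows), summary_path, "table2_summary")

    # reorder so the requested baseline stage leads the transitions
    if config.baseline_stage is not None:
        stages = sorted(
            degs_per_stage,
            key=lambda s: (s != config.baseline_stage, list(degs_per_stage).index(s)),
        )
        degs_per_stage = {s: degs_per_stage[s] for s in stages}

    matrix = count_by_bin(degs_per_stage, binmap)
    dynamics_path = outdir / "dynamics.tsv"
    write_table(dynamics_table(matrix), dynamics_path, "dynamics_matrix")

    summaries = pathway_summary(degs_per_stage, config.pathway_defs, binmap)
    pathway_path = outdir / "pathway_summary.tsv"
    write_table(pathway_summary_table(summaries), pathway_path, "pathway_summary")

    log_path = outdir / "run_log.json"
    with open(log_path, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "bindyn_version": __version__,
                "lfc_min": config.criteria.lfc_min,
                "alpha": config.criteria.alpha,
                "adjust_pvalues": config.adjust_pvalues,
                "baseline_stage": config.baseline_stage,
                "comparisons": [c.comparison_id for c in manifest.comparisons],
                "pathways": [p.name for p in config.pathway_defs],
            },
            fh,
            indent=2,
        )
        fh.write("\n")
    return RunResult(
        summary=summary_path,
        dynamics=dynamics_path,
        pathway=pathway_path,
        run_log=log_path,
    )


def pathway_defs_from(path: str | Path | None) -> Sequence[PathwayDef]:
    return DEFAULT_PATHWAYS if path is None else load_pathway_config(path)
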