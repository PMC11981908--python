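"""Seedable synthetic DEG-table generator.

Generates the full set of artifacts a comparative functional-group
analysis consumes — a gene->bin map, one DEG table per stage (every gene
in the universe appears, with log2 fold-change and adjusted p-value),
per-stage replicate tables, and an experiment manifest — realizing any
feasible target per-bin/per-stage DEG count matrix exactly.

The generator plants DEGs deterministically given the seed: exactly
``target_counts[bin][stage]`` genes per bin pass |log2FC| > 1 and
p_adj <= 0.05 at each stage, with construction margins (no |log2FC| near
1, no p in (0.05, null_p_floor)) so floating point cannot flip a gene's
DEG status.  The pipeline therefore recovers the target matrix exactly,
which is the property the test suite leans on.  Distributional realism
beyond the thresholds is deliberately not modeled: the downstream
analysis only consumes threshold exceedance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._common import ConfigurationError, round_half_away
from .dynamics import CountMatrix
from .io import (
    NOT_ASSIGNED,
    ComparisonEntry,
    ExperimentManifest,
    write_manifest,
)

_P_TRUE_MAX = 0.049  # planted DEG p-values stay strictly below alpha
_NULL_LFC_MAX = 0.9  # non-DEG small fold-changes stay clear of the |1| boundary


@dataclass
class SimSpec:
    """Targets and noise parameters for one synthetic experiment.

    target_counts : desired DEGs per bin per stage; a row named
        "Not assigned" (if present) gives the unmapped-DEG counts.
    gene_universe_size : total genes per DEG table.
    up_fraction : per-stage (or scalar) fraction of DEGs that are
        up-regulated; realized as round(fraction * total).
    unknown_fraction : optional per-stage (or scalar) share of DEGs left
        unmapped, used only when target_counts has no "Not assigned" row
        (a row is appended so that row/(column total) matches).
    effect_size_range : (low, high) |log2FC| magnitudes for planted DEGs;
        low > 1 guarantees they pass the strict filter.
    null_p_floor : lower bound (> 0.05) on adjusted p for genes meant to
        fail on significance.
    replicate_noise_sd : SD (in DEG counts) of the Gaussian jitter applied
        per bin per replicate table.
    stage_overlap : fraction of a bin's DEGs reused from the previous
        stage (controls cross-stage unique/shared structure).
    """

    target_counts: CountMatrix
    gene_universe_size: int = 24000
    up_fraction: Mapping[str, float] | float = 0.5
    unknown_fraction: Mapping[str, float] | float | None = None
    water_status: Mapping[str, str] = field(default_factory=dict)
    effect_size_range: tuple[float, float] = (1.5, 8.0)
    null_p_floor: float = 0.2
    replicate_noise_sd: float = 50.0
    n_replicates: int = 3
    stage_overlap: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.effect_size_range
        if not (1.0 < low < high):
            raise ConfigurationError(
                "effect_size_range must satisfy 1 < low < high "
                "(low > 1 keeps planted DEGs past the strict |log2FC| filter)"
            )
        if self.null_p_floor <= 0.05:
            raise ConfigurationError("null_p_floor must exceed 0.05")
        if self.replicate_noise_sd < 0:
            raise ConfigurationError("replicate_noise_sd must be non-negative")
        if not (0.0 <= self.stage_overlap <= 1.0):
            raise ConfigurationError("stage_overlap must lie in [0, 1]")
        for s in self.target_counts.stages:
            f = self._up_fraction(s)
            if not (0.0 <= f <= 1.0):
                raise ConfigurationError(f"up_fraction for {s} outside [0, 1]")
        if (
            self.unknown_fraction is not None
            and NOT_ASSIGNED in self.target_counts.bins
        ):
            raise ConfigurationError(
                "give either an explicit 'Not assigned' row or unknown_fraction"
            )
        if self.unknown_fraction is not None:
            self.target_counts = _append_unassigned_row(
                self.target_counts, self.unknown_fraction
            )
        totals = self.target_counts.column_totals()
        margin = self._pool_margin()
        named = [b for b in self.target_counts.bins if b != NOT_ASSIGNED]
        need = sum(
            int(self.target_counts.counts.loc[b].max()) + margin for b in named
        )
        na_need = (
            int(self.target_counts.counts.loc[NOT_ASSIGNED].max()) + margin
            if NOT_ASSIGNED in self.target_counts.bins
            else 0
        )
        if need + na_need > self.gene_universe_size:
            raise ConfigurationError(
                f"infeasible spec: bins need {need + na_need} genes "
                f"(including replicate-jitter margin) but the universe has "
                f"{self.gene_universe_size}; totals were {dict(totals)}"
            )

    def _up_fraction(self, stage: str) -> float:
        if isinstance(self.up_fraction, Mapping):
            return float(self.up_fraction[stage])
        return float(self.up_fraction)

    def _pool_margin(self) -> int:
        # spare mapped genes per bin so replicate jitter can promote extras
        if self.n_replicates == 0 and self.replicate_noise_sd == 0:
            return 0
        return int(math.ceil(4 * self.replicate_noise_sd)) + 4

    # -- JSON round-trip (CLI surface) ----------------------------------

    def to_json(self, path: str | Path) -> None:
        m = self.target_counts
        data = {
            "stages": m.stages,
            "bins": [
                {
                    "code": m.bin_codes.get(b, str(i + 1)),
                    "name": b,
                    "counts": [int(m[b, s]) for s in m.stages],
                }
                for i, b in enumerate(m.bins)
            ],
            "gene_universe_size": self.gene_universe_size,
            "up_fraction": self.up_fraction
            if not isinstance(self.up_fraction, Mapping)
            else dict(self.up_fraction),
            "water_status": dict(self.water_status),
            "effect_size_range": list(self.effect_size_range),
            "null_p_floor": self.null_p_floor,
            "replicate_noise_sd": self.replicate_noise_sd,
            "n_replicates": self.n_replicates,
            "stage_overlap": self.stage_overlap,
            "seed": self.seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(data, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimSpec":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        stages = data["stages"]
        names = [b["name"] for b in data["bins"]]
        counts = pd.DataFrame(
            {s: [b["counts"][i] for b in data["bins"]] for i, s in enumerate(stages)},
            index=names,
        )
        codes = {b["name"]: b["code"] for b in data["bins"]}
        kwargs = {
            k: data[k]
            for k in (
                "gene_universe_size",
                "up_fraction",
                "water_status",
                "null_p_floor",
                "replicate_noise_sd",
                "n_replicates",
                "stage_overlap",
                "seed",
            )
            if k in data
        }
        if "effect_size_range" in data:
            kwargs["effect_size_range"] = tuple(data["effect_size_range"])
        return cls(
            target_counts=CountMatrix(counts=counts, bin_codes=codes), **kwargs
        )


def _append_unassigned_row(
    matrix: CountMatrix, unknown_fraction: Mapping[str, float] | float
) -> CountMatrix:
    counts = matrix.counts.copy()
    row = []
    for s in matrix.stages:
        f = (
            float(unknown_fraction[s])
            if isinstance(unknown_fraction, Mapping)
            else float(unknown_fraction)
        )
        if not (0.0 <= f < 1.0):
            raise ConfigurationError("unknown_fraction must lie in [0, 1)")
        assigned = int(counts[s].sum())
        row.append(round_half_away(f / (1.0 - f) * assigned))
    counts.loc[NOT_ASSIGNED] = row
    return CountMatrix(counts=counts, bin_codes=dict(matrix.bin_codes))


def simulate_replicates(
    targets: Sequence[int],
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Replicate-level DEG counts: target + rounded Gaussian jitter, >= 0.

    Returns an (n_replicates, len(targets)) integer array.  With
    noise_sd = 0 every replicate equals the target exactly.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    base = np.asarray(targets, dtype=float)
    jitter = rng.normal(0.0, noise_sd, size=(n_replicates, base.size)) if noise_sd else 0.0
    return np.maximum(0, np.rint(base + jitter)).astype(int)


@dataclass(frozen=True)
class SimOutput:
    """Paths to everything one simulated experiment wrote."""

    outdir: Path
    bin_map: Path
    manifest: Path
    deg_tables: dict[str, Path]
    replicate_tables: dict[str, tuple[Path, ...]]


def simulate_experiment(spec: SimSpec, outdir: str | Path) -> SimOutput:
    """Write a complete synthetic experiment realizing ``spec``.

    Produces binmap.tsv, one stage_<label>.tsv DEG table per stage, three
    (by default) replicate tables per stage, and manifest.json.  The same
    spec and seed produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    matrix = spec.target_counts
    stages = matrix.stages
    named = [b for b in matrix.bins if b != NOT_ASSIGNED]
    n_genes = spec.gene_universe_size
    margin = spec._pool_margin()

    # disjoint per-bin gene pools (as integer indices into the universe)
    perm = rng.permutation(n_genes)
    pools: dict[str, np.ndarray] = {}
    cursor = 0
    for b in named:
        size = int(matrix.counts.loc[b].max()) + margin
        pools[b] = perm[cursor : cursor + size]
        cursor += size
    pools[NOT_ASSIGNED] = perm[cursor:]

    gene_ids = np.array([f"g{i + 1:06d}" for i in range(n_genes)])
    bin_map_path = outdir / "binmap.tsv"
    with open(bin_map_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("bin_code\tbin_name\tgene_id\n")
        for b in named:
            code = matrix.bin_codes.get(b, str(named.index(b) + 1))
            for idx in sorted(pools[b]):
                fh.write(f"{code}\t{b}\t{gene_ids[idx]}\n")

    # plant per-stage DEG sets with cross-stage overlap
    sim_bins = named + ([NOT_ASSIGNED] if NOT_ASSIGNED in matrix.bins else [])
    chosen: dict[str, dict[str, np.ndarray]] = {}
    used: dict[str, set[int]] = {b: set() for b in sim_bins}
    prev: dict[str, np.ndarray] = {}
    for stage in stages:
        chosen[stage] = {}
        for b in sim_bins:
            n = matrix[b, stage]
            prev_set = prev.get(b, np.empty(0, dtype=int))
            k = min(round_half_away(spec.stage_overlap * n), prev_set.size)
            reused = (
                rng.choice(prev_set, size=k, replace=False)
                if k
                else np.empty(0, dtype=int)
            )
            fresh_pool = np.setdiff1d(pools[b], np.fromiter(used[b], dtype=int, count=len(used[b])))
            if fresh_pool.size < n - k:  # pool exhausted: allow re-draws
                fresh_pool = np.setdiff1d(pools[b], reused)
            fresh = rng.choice(fresh_pool, size=n - k, replace=False)
            sel = np.concatenate([reused, fresh]).astype(int)
            chosen[stage][b] = sel
            used[b].update(int(i) for i in fresh)
            prev[b] = sel

    deg_tables: dict[str, Path] = {}
    replicate_tables: dict[str, tuple[Path, ...]] = {}
    for stage in stages:
        deg_idx = (
            np.concatenate([chosen[stage][b] for b in sim_bins])
            if sim_bins
            else np.empty(0, dtype=int)
        )
        path = outdir / f"stage_{stage}.tsv"
        _write_stage_table(path, gene_ids, deg_idx, spec, spec._up_fraction(stage), rng)
        deg_tables[stage] = path

        reps = []
        if spec.n_replicates:
            targets = [matrix[b, stage] for b in sim_bins]
            rep_counts = simulate_replicates(
                targets, spec.n_replicates, spec.replicate_noise_sd, rng
            )
            for r in range(spec.n_replicates):
                parts = []
                for j, b in enumerate(sim_bins):
                    n, m = len(chosen[stage][b]), int(rep_counts[r, j])
                    sel = rng.permutation(chosen[stage][b])
                    if m <= n:
                        parts.append(sel[:m])
                    else:
                        spare = np.setdiff1d(pools[b], sel)
                        extra = rng.choice(
                            spare, size=min(m - n, spare.size), replace=False
                        )
                        parts.append(np.concatenate([sel, extra]).astype(int))
                rep_idx = (
                    np.concatenate(parts) if parts else np.empty(0, dtype=int)
                )
                rpath = outdir / f"stage_{stage}_rep{r + 1}.tsv"
                _write_stage_table(
                    rpath, gene_ids, rep_idx, spec, spec._up_fraction(stage), rng
                )
                reps.append(rpath)
        replicate_tables[stage] = tuple(reps)

    manifest = ExperimentManifest(
        comparisons=[
            ComparisonEntry(
                comparison_id=f"C{i + 1}",
                stage=stage,
                water_status=spec.water_status.get(stage, "ww"),
                deg_table=deg_tables[stage],
                replicates=replicate_tables[stage],
            )
            for i, stage in enumerate(stages)
        ],
        bin_map=bin_map_path,
    )
    manifest_path = outdir / "manifest.json"
    write_manifest(manifest, manifest_path)
    return SimOutput(
        outdir=outdir,
        bin_map=bin_map_path,
        manifest=manifest_path,
        deg_tables=deg_tables,
        replicate_tables=replicate_tables,
    )


def _write_stage_table(
    path: Path,
    gene_ids: np.ndarray,
    deg_idx: np.ndarray,
    spec: SimSpec,
    up_fraction: float,
    rng: np.random.Generator,
) -> None:
    """One full-universe DEG table with the given genes planted as DEGs.

    Non-DEG genes fall into three background classes, all safely outside
    the filter: small fold-change + non-significant p (80%), large
    fold-change but non-significant p (10%), and significant p but small
    fold-change (10%) — so both criteria are individually exercised.
    """
    n = gene_ids.size
    low, high = spec.effect_size_range
    cat = rng.random(n)
    p = rng.uniform(spec.null_p_floor, 1.0, size=n)
    lfc = rng.uniform(-_NULL_LFC_MAX, _NULL_LFC_MAX, size=n)
    big = cat >= 0.8
    signs = np.where(rng.random(n) < 0.5, -1.0, 1.0)
    lfc[big & (cat < 0.9)] = (signs * rng.uniform(low, high, size=n))[
        big & (cat < 0.9)
    ]
    sig = cat >= 0.9
    p[sig] = rng.uniform(1e-4, _P_TRUE_MAX, size=n)[sig]

    if deg_idx.size:
        n_up = round_half_away(up_fraction * deg_idx.size)
        order = rng.permutation(deg_idx)
        up, down = order[:n_up], order[n_up:]
        mag = rng.uniform(low, high, size=deg_idx.size)
        lfc[up] = mag[: up.size]
        lfc[down] = -mag[up.size :]
        p[deg_idx] = rng.uniform(1e-6, _P_TRUE_MAX, size=deg_idx.size)

    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\tlog2fc\tp_adj\n")
        for g, f, q in zip(gene_ids, lfc, p):
            fh.write(f"{g}\t{f:.4f}\t{q:.6g}\n")
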