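# bindyn — functional-bin DEG dynamics across growth stages

`bindyn` is a desk-scale pipeline for comparative functional-group analysis
of differential-expression results from time-course experiments. It was
built around a field CO₂-enrichment study of peanut (*Arachis hypogaea*,
runner type) grown under semiarid conditions, where leaf RNA-seq contrasts
between elevated and ambient CO₂ were profiled across reproductive growth
stages (R2–R8) spanning drought/re-watering cycles — but it works on any
set of per-comparison DEG tables plus a Mercator/MapMan-style gene→bin map.

## What it computes

A gene is a **DEG** in one pairwise comparison when |log₂FC| > 1 (strict)
and adjusted p ≤ 0.05 (inclusive). DEGs are tallied per functional bin
(photosynthesis, major CHO metabolism, …, plus a reserved "Not assigned"
bin), giving a bins × stages count matrix **N**. Two statistics summarize
its dynamics:

* **Percentage of total** — `100 · N[b,s] / Σ_b N[b,s]`: the conventional
  per-function profile, dominated by gene-rich categories (protein, RNA,
  signaling).
* **Percentage change from baseline** —
  `100 · (N[b,t] − N[b,s]) / N[b,s]` for a stage transition s→t, undefined
  (`na`) when the baseline count is zero. By normalizing each bin against
  its own baseline, it surfaces strongly re-regulated small pathways (e.g.
  photosynthesis, redox) that the percentage-of-total view hides.

Each transition is labeled **up / down / nc** from the raw counts, and a
bin's trajectory collapses to an up-, down-, unchanged- or
mixed-pattern(`up/down`, `unchanged/up`, …) composite. Sub-pathway
accounting (light reactions, Calvin cycle, photorespiration,
sucrose/starch synthesis and degradation) pools per-stage DEG identifier
sets and splits them into stage-specific ("unique") and shared DEGs, and a
pooled-variance t-test compares replicate-level DEG counts between stages.

A seedable synthetic generator produces complete experiments — bin map,
full-universe DEG tables, replicate tables, manifest — realizing any
feasible target count matrix *exactly*, so the whole pipeline is testable
without the original sequencing data.

## Worked example

Simulate the reference peanut experiment (published per-bin counts for
pre-water deficit pwd/R2, first water deficit wd/R3, first recovery ww/R4)
and run the pipeline:

```python
import bindyn as bd
from bindyn.datasets import peanut_co2_counts, peanut_up_fractions, PEANUT_WATER_STATUS

spec = bd.SimSpec(
    target_counts=peanut_co2_counts(),
    up_fraction=peanut_up_fractions(),
    water_status=PEANUT_WATER_STATUS,
    seed=42,
)
out = bd.simulate_experiment(spec, "sim/")
binmap = bd.read_bin_map(out.bin_map)
degs = {c.stage: bd.call_degs(bd.read_deg_table(c.deg_table))
        for c in bd.read_manifest(out.manifest).comparisons}
matrix = bd.count_by_bin(degs, binmap)
print(dict(matrix.column_totals()))
# {'R2': 1182, 'R3': 2980, 'R4': 3044}
print(bd.pct_change(matrix["photosynthesis", "R2"], matrix["photosynthesis", "R3"]))
# 533
print([bd.mean_pct_change(matrix, t) for t in bd.default_transitions(matrix.stages)])
# [307, 6, 191]
```

1182 / 2980 / 3044 are the per-stage DEG totals; photosynthesis jumps
533 % from pre-water deficit into water deficit; and the mean percent
change across all 34 bins is 307 % entering drought, 6 % into recovery,
191 % between the two well-watered stages — drought, not CO₂ alone, drives
the bulk of the reprogramming.

The same workflow from the shell:

```sh
bindyn simulate --spec spec.json --outdir sim/
bindyn run --manifest sim/manifest.json --binmap sim/binmap.tsv --outdir results/
```

writes `summary.tsv` (per-comparison DEG summary), `dynamics.tsv`
(counts, % change and pattern per bin, with trailing Total and % mean
rows), `pathway_summary.tsv` and a `run_log.json` recording the applied
thresholds.

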