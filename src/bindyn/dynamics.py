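"""Functional-group DEG dynamics across growth stages.

This module implements the two summary statistics for functional-bin DEG
counts and the pattern taxonomy built on them:

* **percentage of total** — a bin's DEG count as a percentage of all DEGs
  in that stage's comparison.  This is the conventional profile (the pie
  chart of an annotation tool); it is dominated by gene-rich categories.

* **percentage change from baseline** — the change in a bin's DEG count
  between two stages as a percentage of the earlier (baseline) stage's
  count, ``100 * (later - baseline) / baseline``.  It is undefined
  (``na``) when the baseline count is zero, and deliberately asymmetric:
  pct_change(a, b) is not -pct_change(b, a).  Because it normalizes each
  bin by its own baseline, it surfaces strongly re-regulated small
  categories that the percentage-of-total profile hides.

Per-transition counts are classified as up / down / nc (no change), and a
bin's trajectory over consecutive transitions collapses to one of four
composite patterns: up-pattern, down-pattern, unchanged-pattern, or
mixed-pattern (with the ordered detail, e.g. "up/down").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._common import IntegrityError, round_half_away
from .io import NOT_ASSIGNED, BinMap, DEGRecord, bin_code_key

Transition = tuple[str, str]

PATTERN_UP = "up"
PATTERN_DOWN = "down"
PATTERN_NC = "nc"


@dataclass
class CountMatrix:
    """Functional bins x stages table of DEG counts.

    ``counts`` is a pandas DataFrame indexed by bin name (including the
    reserved "Not assigned" bin) with one integer column per stage, in
    presentation order.  Column sums equal each comparison's total DEGs.
    """

    counts: pd.DataFrame
    bin_codes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise IntegrityError("DEG counts must be non-negative")
        self.counts = self.counts.astype(int)

    @property
    def bins(self) -> list[str]:
        return list(self.counts.index)

    @property
    def stages(self) -> list[str]:
        return list(self.counts.columns)

    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def __getitem__(self, bin_stage: tuple[str, str]) -> int:
        b, s = bin_stage
        return int(self.counts.at[b, s])


def count_by_bin(
    degs_per_stage: Mapping[str, Sequence[DEGRecord]], binmap: BinMap
) -> CountMatrix:
    """Count each stage's DEGs by primary functional bin.

    The bin universe is the union of bins observed at any stage plus the
    reserved unassigned bin, ordered by bin code with "Not assigned" last;
    bins absent at every stage are omitted.  Column sums are conserved: a
    DEG is counted exactly once, unmapped genes under "Not assigned".
    """
    stages = list(degs_per_stage)
    per_stage: dict[str, dict[str, int]] = {}
    codes: dict[str, str] = {}
    for stage, degs in degs_per_stage.items():
        tally: dict[str, int] = {}
        for deg in degs:
            code, name = binmap.lookup(deg.gene_id)
            tally[name] = tally.get(name, 0) + 1
            if code is not None:
                codes[name] = code
        per_stage[stage] = tally
    observed = set().union(*per_stage.values()) if per_stage else set()
    named = sorted(
        observed - {binmap.not_assigned_name},
        key=lambda n: bin_code_key(codes[n]) if n in codes else (1 << 30,),
    )
    order = named + (
        [binmap.not_assigned_name] if binmap.not_assigned_name in observed else []
    )
    data = {
        stage: [per_stage[stage].get(b, 0) for b in order] for stage in stages
    }
    return CountMatrix(
        counts=pd.DataFrame(data, index=order, columns=stages), bin_codes=codes
    )


def pct_of_total(matrix: CountMatrix) -> pd.DataFrame:
    """Per-(bin, stage) percentage of the stage's total DEG count.

    Stages with a zero column total yield an all-NaN column (flagged by
    the caller as not reportable) rather than raising.
    """
    totals = matrix.column_totals().astype(float)
    out = 100.0 * matrix.counts / totals.replace(0, np.nan)
    return out


def pct_change(baseline: int, later: int) -> int | None:
    """Percent change of a count relative to its baseline, or None.

    Returns ``round_half_away(100 * (later - baseline) / baseline)`` when
    the baseline is positive, None (serialized as ``na``) when it is zero.
    """
    if baseline < 0 or later < 0:
        raise IntegrityError("counts must be non-negative")
    if baseline == 0:
        return None
    return round_half_away(100.0 * (later - baseline) / baseline)


def classify_transition(baseline: int, later: int) -> str:
    """Label a count transition: up / down / nc.

    The label derives from the raw counts, so a 0 -> k transition is
    "up" even though its percent change is undefined.
    """
    if baseline < 0 or later < 0:
        raise IntegrityError("counts must be non-negative")
    if later > baseline:
        return PATTERN_UP
    if later < baseline:
        return PATTERN_DOWN
    return PATTERN_NC


def classify_trajectory(labels: Sequence[str]) -> str:
    """Collapse ordered transition labels into a composite pattern.

    all up -> "up-pattern"; all down -> "down-pattern"; all nc ->
    "unchanged-pattern"; anything else -> "mixed-pattern(<detail>)" where
    the detail preserves transition order, nc spelled "unchanged"
    (e.g. "up/down", "unchanged/up").
    """
    if not labels:
        raise IntegrityError("trajectory needs at least one transition label")
    unique = set(labels)
    if unique == {PATTERN_UP}:
        return "up-pattern"
    if unique == {PATTERN_DOWN}:
        return "down-pattern"
    if unique == {PATTERN_NC}:
        return "unchanged-pattern"
    detail = "/".join("unchanged" if l == PATTERN_NC else l for l in labels)
    return f"mixed-pattern({detail})"


def mean_pct_change(matrix: CountMatrix, transition: Transition) -> int | None:
    """Mean percent change across bins for one stage transition.

    Averages the per-bin integer percent changes over every bin with a
    defined value — the unassigned bin included, zero-baseline bins
    excluded — rounded half-away-from-zero.  None if no bin is defined.
    """
    base_stage, later_stage = transition
    values = [
        pc
        for b in matrix.bins
        if (pc := pct_change(matrix[b, base_stage], matrix[b, later_stage]))
        is not None
    ]
    if not values:
        return None
    return round_half_away(sum(values) / len(values))


def timepoint_modification(
    counts_a: Mapping[str, int], counts_b: Mapping[str, int]
) -> dict[str, str]:
    """Per-bin treatment contrast at one time point: modified / unchanged.

    A bin is "modified" iff its DEG count differs between the two
    treatments (e.g. ambient vs elevated CO2) at that time point.
    """
    if set(counts_a) != set(counts_b):
        raise IntegrityError("both treatments must cover the same bins")
    return {
        b: ("modified" if counts_a[b] != counts_b[b] else "unchanged")
        for b in counts_a
    }


def default_transitions(stages: Sequence[str]) -> list[Transition]:
    """Consecutive stage pairs, plus first-vs-last when there are >2 stages."""
    pairs = [(stages[i], stages[i + 1]) for i in range(len(stages) - 1)]
    if len(stages) > 2:
        pairs.append((stages[0], stages[-1]))
    return pairs


def dynamics_table(
    matrix: CountMatrix, transitions: Sequence[Transition] | None = None
) -> pd.DataFrame:
    """Assemble the full dynamics table for a count matrix.

    One row per bin with per-stage counts, per-transition percent change
    and pattern label, and the composite trajectory pattern (from the
    consecutive transitions); then a "Total" row of column sums and a
    "% mean" row of per-transition mean percent changes.
    """
    stages = matrix.stages
    if transitions is None:
        transitions = default_transitions(stages)
    consecutive = [
        t for t in transitions
        if stages.index(t[1]) == stages.index(t[0]) + 1
    ] or list(transitions)

    rows = []
    for b in matrix.bins:
        row: dict[str, object] = {"bin": b}
        for s in stages:
            row[f"count:{s}"] = matrix[b, s]
        for base, later in transitions:
            key = f"{base}/{later}"
            pc = pct_change(matrix[b, base], matrix[b, later])
            row[f"pct_change:{key}"] = pd.NA if pc is None else pc
            row[f"pattern:{key}"] = classify_transition(
                matrix[b, base], matrix[b, later]
            )
        row["composite"] = classify_trajectory(
            [classify_transition(matrix[b, a], matrix[b, c]) for a, c in consecutive]
        )
        rows.append(row)

    totals: dict[str, object] = {"bin": "Total"}
    for s in stages:
        totals[f"count:{s}"] = int(matrix.column_totals()[s])
    means: dict[str, object] = {"bin": "% mean"}
    for base, later in transitions:
        m = mean_pct_change(matrix, (base, later))
        means[f"pct_change:{base}/{later}"] = pd.NA if m is None else m
    rows.extend([totals, means])

    columns = ["bin"] + [f"count:{s}" for s in stages]
    for base, later in transitions:
        columns += [f"pct_change:{base}/{later}", f"pattern:{base}/{later}"]
    columns.append("composite")
    return pd.DataFrame(rows, columns=columns)
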