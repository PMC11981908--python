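"""DEG calling by fixed thresholds and per-comparison summaries.

A differentially expressed gene (DEG) is a gene with |log2 fold-change|
strictly greater than ``lfc_min`` AND adjusted p-value at most ``alpha``
in one pairwise comparison.  Defaults are the conventional |log2FC| > 1,
adjusted p <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from statsmodels.stats.multitest import multipletests

from ._common import IntegrityError, round_half_away
from .io import BinMap, DEGRecord


@dataclass(frozen=True)
class DEGCriteria:
    """Thresholds for DEG calling.

    lfc_min : strict threshold on |log2 fold-change| (a gene with
        |log2FC| exactly equal to lfc_min is NOT a DEG).
    alpha : inclusive threshold on the adjusted p-value.
    """

    lfc_min: float = 1.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.lfc_min <= 0:
            raise IntegrityError("lfc_min must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise IntegrityError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class ComparisonSummary:
    """Per-comparison DEG summary: totals, bin-map coverage, up/down split."""

    n_degs: int
    n_assigned: int
    n_unknown: int
    n_up: int
    n_down: int
    pct_up: int
    pct_down: int


def call_degs(
    records: Sequence[DEGRecord],
    criteria: DEGCriteria = DEGCriteria(),
    *,
    adjust: bool = False,
) -> list[DEGRecord]:
    """Return the records passing the DEG criteria, tagged with direction.

    Input order is preserved.  p-values are consumed as already adjusted;
    pass ``adjust=True`` to apply a Benjamini-Hochberg correction first
    (explicit opt-in for tables carrying raw p-values).
    """
    if adjust and records:
        adjusted = multipletests([r.p_adj for r in records], method="fdr_bh")[1]
        records = [replace(r, p_adj=p) for r, p in zip(records, adjusted)]
    out = []
    for rec in records:
        if abs(rec.log2fc) > criteria.lfc_min and rec.p_adj <= criteria.alpha:
            out.append(replace(rec, direction="up" if rec.log2fc > 0 else "down"))
    return out


def summarize_comparison(
    degs: Sequence[DEGRecord], binmap: BinMap
) -> ComparisonSummary:
    """Summarize an already-filtered DEG list (Table-2-style row).

    Percentages are of n_degs, rounded half-away-from-zero, so
    pct_up + pct_down may be 99 or 101 by independent rounding.
    """
    n = len(degs)
    n_up = sum(1 for d in degs if d.log2fc > 0)
    n_assigned = sum(1 for d in degs if binmap.lookup(d.gene_id)[0] is not None)
    return ComparisonSummary(
        n_degs=n,
        n_assigned=n_assigned,
        n_unknown=n - n_assigned,
        n_up=n_up,
        n_down=n - n_up,
        pct_up=round_half_away(100.0 * n_up / n) if n else 0,
        pct_down=round_half_away(100.0 * (n - n_up) / n) if n else 0,
    )
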