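"""Sub-pathway DEG accounting and replicate-level stage comparisons.

Pools each pathway's DEG identifier sets across stages and splits them
into stage-specific ("unique": observed in exactly one stage) and shared
DEGs, as in per-pathway summaries for photosynthesis (light reactions,
Calvin cycle, photorespiration) and major carbohydrate metabolism
(sucrose/starch synthesis and degradation).  Also provides the
two-sample t-test used to compare replicate-level DEG counts between
stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from ._common import ConfigurationError, IntegrityError
from .io import BinMap, DEGRecord, bin_code_key


@dataclass(frozen=True)
class PathwayDef:
    """A named pathway as a set of bin-code prefixes or explicit genes.

    A gene belongs to the pathway if its primary bin code equals one of
    ``bin_prefixes`` or falls under it (prefix "1.1" covers "1.1.2"), or
    if it is listed in ``genes``.
    """

    name: str
    bin_prefixes: tuple[str, ...] = ()
    genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.bin_prefixes and not self.genes:
            raise ConfigurationError(
                f"pathway {self.name!r} has neither bin prefixes nor genes"
            )
        for code in self.bin_prefixes:
            bin_code_key(code)  # validate format

    def contains(self, gene_id: str, bin_code: str | None) -> bool:
        if gene_id in self.genes:
            return True
        if bin_code is None:
            return False
        key = bin_code_key(bin_code)
        for prefix in self.bin_prefixes:
            pk = bin_code_key(prefix)
            if key[: len(pk)] == pk:
                return True
        return False


#: Default sub-pathway map over MapMan-style bin codes: photosynthesis
#: splits into light reactions (1.1), photorespiration (1.2) and the
#: Calvin cycle (1.3); major CHO metabolism into sucrose/starch
#: synthesis (2.1.1 / 2.1.2) and degradation (2.2.1 / 2.2.2).
DEFAULT_PATHWAYS: tuple[PathwayDef, ...] = (
    PathwayDef("light reactions", ("1.1",)),
    PathwayDef("photorespiration (C2)", ("1.2",)),
    PathwayDef("Calvin cycle (C3)", ("1.3",)),
    PathwayDef("sucrose synthesis", ("2.1.1",)),
    PathwayDef("starch synthesis", ("2.1.2",)),
    PathwayDef("sucrose degradation", ("2.2.1",)),
    PathwayDef("starch degradation", ("2.2.2",)),
)


def load_pathway_config(path: str | Path) -> tuple[PathwayDef, ...]:
    """Read a pathway config (JSON: name -> {bins: [...], genes: [...]})."""
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    return tuple(
        PathwayDef(
            name=name,
            bin_prefixes=tuple(entry.get("bins", [])),
            genes=frozenset(entry.get("genes", [])),
        )
        for name, entry in data.items()
    )


@dataclass(frozen=True)
class PathwaySummary:
    """Per-pathway DEG set accounting across stages.

    unique + shared = total distinct DEGs pooled over stages; a DEG is
    unique (stage-specific) iff it occurs in exactly one stage's set.
    """

    pathway: str
    per_stage: Mapping[str, frozenset[str]]

    @property
    def per_stage_counts(self) -> dict[str, int]:
        return {s: len(g) for s, g in self.per_stage.items()}

    @property
    def total(self) -> int:
        return len(frozenset().union(*self.per_stage.values()))

    @property
    def unique(self) -> int:
        return sum(1 for _, k in self._occurrences() if k == 1)

    @property
    def shared(self) -> int:
        return sum(1 for _, k in self._occurrences() if k > 1)

    def _occurrences(self) -> Iterable[tuple[str, int]]:
        pooled: dict[str, int] = {}
        for genes in self.per_stage.values():
            for g in genes:
                pooled[g] = pooled.get(g, 0) + 1
        return pooled.items()


def pathway_summary(
    degs_per_stage: Mapping[str, Sequence[DEGRecord] | Iterable[str]],
    pathway_defs: Sequence[PathwayDef],
    binmap: BinMap | None = None,
) -> dict[str, PathwaySummary]:
    """Total / unique / shared DEG accounting per pathway.

    ``degs_per_stage`` maps stage label to that stage's filtered DEGs
    (records, or bare gene ids when pathways are defined by gene lists).
    Pathway membership is resolved through the bin map when the pathway
    is defined by bin-code prefixes.
    """
    names = [p.name for p in pathway_defs]
    if len(set(names)) != len(names):
        raise ConfigurationError("pathway names must be unique")
    out: dict[str, PathwaySummary] = {}
    for pdef in pathway_defs:
        if pdef.bin_prefixes and binmap is None:
            raise ConfigurationError(
                f"pathway {pdef.name!r} uses bin prefixes but no bin map given"
            )
        per_stage: dict[str, frozenset[str]] = {}
        for stage, degs in degs_per_stage.items():
            members = set()
            for deg in degs:
                gene = deg.gene_id if isinstance(deg, DEGRecord) else deg
                code = binmap.lookup(gene)[0] if binmap is not None else None
                if pdef.contains(gene, code):
                    members.add(gene)
            per_stage[stage] = frozenset(members)
        out[pdef.name] = PathwaySummary(pathway=pdef.name, per_stage=per_stage)
    return out


def pathway_summary_table(summaries: Mapping[str, PathwaySummary]) -> pd.DataFrame:
    """Flatten pathway summaries into the pathway_summary output schema."""
    rows = []
    for summary in summaries.values():
        row: dict[str, object] = {"pathway": summary.pathway}
        for stage, n in summary.per_stage_counts.items():
            row[f"count:{stage}"] = n
        row.update(total=summary.total, unique=summary.unique, shared=summary.shared)
        rows.append(row)
    return pd.DataFrame(rows)


def stage_count_ttest(
    replicate_counts_a: Sequence[float],
    replicate_counts_b: Sequence[float],
    *,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> tuple[float, float, bool]:
    """Two-sample two-sided t-test on replicate-level DEG counts.

    Pooled-variance (Student) by default — the conventional choice for a
    balanced n=3 design; set ``equal_var=False`` for Welch.  Returns
    (t, two-sided p, significant at ``alpha``, strict).  Two constant
    samples with equal means give t=0, p=1 by convention.
    """
    a, b = list(replicate_counts_a), list(replicate_counts_b)
    if len(a) < 2 or len(b) < 2:
        raise IntegrityError("each group needs at least 2 replicate values")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if t != t:  # zero variance on both sides
        if float(pd.Series(a).mean()) == float(pd.Series(b).mean()):
            t, p = 0.0, 1.0
        else:
            t, p = float("inf"), 0.0
    return float(t), float(p), bool(p < alpha)
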