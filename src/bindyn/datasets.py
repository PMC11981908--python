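"""Reference dataset: published functional-bin DEG counts for peanut under
elevated CO2 across a drought cycle.

The counts come from a field CO2-enrichment leaf RNA-seq study of peanut
(*Arachis hypogaea*, runner type) grown under semiarid conditions: DEGs
(|log2FC| > 1, adjusted p <= 0.05, elevated vs ambient CO2) per Mercator
functional bin at three stages of the first water-deficit cycle —
pre-water deficit (pwd, growth stage R2), first water deficit (wd, R3)
and first well-watered recovery (ww, R4).  Bin codes follow the classic
MapMan top-level numbering; the reserved "Not assigned" bin holds genes
without a functional annotation.

These tables serve as targets for the synthetic generator and as the
ground truth for the percentage-change / pattern analyses.
"""

from __future__ import annotations

import pandas as pd

from .io import NOT_ASSIGNED
from .dynamics import CountMatrix

PEANUT_STAGES = ("R2", "R3", "R4")
PEANUT_WATER_STATUS = {"R2": "pwd", "R3": "wd", "R4": "ww"}

#: (bin_code, bin_name, counts at R2/R3/R4)
PEANUT_BIN_COUNTS: tuple[tuple[str, str, tuple[int, int, int]], ...] = (
    ("1", "photosynthesis", (3, 19, 16)),
    ("2", "major CHO", (6, 26, 8)),
    ("3", "minor CHO", (2, 24, 11)),
    ("4", "glycolysis", (2, 5, 6)),
    ("5", "fermentation", (3, 4, 1)),
    ("6", "gluconeogenesis", (0, 1, 1)),
    ("7", "OPP", (0, 1, 2)),
    ("8", "tricarboxylic acid", (1, 6, 1)),
    ("9", "mitochondrial electron transport", (2, 4, 7)),
    ("10", "cell wall", (11, 74, 39)),
    ("11", "lipid metabolism", (9, 63, 17)),
    ("12", "N-metabolism", (0, 2, 3)),
    ("13", "amino acid metabolism", (15, 28, 17)),
    ("14", "S-assimilation", (0, 0, 1)),
    ("15", "metal handling", (6, 9, 3)),
    ("16", "secondary metabolism", (33, 57, 50)),
    ("17", "hormone metabolism", (26, 39, 41)),
    ("18", "Co-factor, vitamin", (6, 7, 9)),
    ("19", "tetrapyrrole synthesis", (2, 1, 8)),
    ("20", "stress biotic", (32, 95, 102)),
    ("21", "redox", (1, 22, 17)),
    ("22", "polyamine metabolism", (4, 3, 3)),
    ("23", "nucleotide metabolism", (5, 15, 8)),
    ("24", "biodegradation of xenobiotics", (3, 7, 3)),
    ("25", "C1-metabolism", (0, 1, 1)),
    ("26", "miscellaneous", (56, 169, 82)),
    ("27", "RNA", (58, 165, 155)),
    ("28", "DNA", (7, 49, 41)),
    ("29", "protein", (84, 205, 218)),
    ("30", "signaling", (49, 139, 151)),
    ("31", "cell", (20, 70, 52)),
    ("33", "development", (24, 61, 39)),
    ("34", "transport", (34, 140, 86)),
    ("35", NOT_ASSIGNED, (678, 1469, 1845)),
)

#: Per-stage up-regulated DEG counts and totals from the study's summary
#: (the published per-bin matrix totals 2980 at R3 against a summary total
#: of 2979 — a one-count discrepancy in the source; the per-bin matrix is
#: authoritative here).
PEANUT_UP_COUNTS = {"R2": 527, "R3": 1782, "R4": 1893}
PEANUT_SUMMARY_TOTALS = {"R2": 1182, "R3": 2979, "R4": 3044}


def peanut_co2_counts() -> CountMatrix:
    """The published 34-bin x 3-stage DEG count matrix."""
    names = [name for _, name, _ in PEANUT_BIN_COUNTS]
    counts = pd.DataFrame(
        {
            stage: [row[2][i] for row in PEANUT_BIN_COUNTS]
            for i, stage in enumerate(PEANUT_STAGES)
        },
        index=names,
    )
    codes = {name: code for code, name, _ in PEANUT_BIN_COUNTS}
    return CountMatrix(counts=counts, bin_codes=codes)


def peanut_up_fractions() -> dict[str, float]:
    """Per-stage up-regulated fraction implied by the published summary."""
    return {
        s: PEANUT_UP_COUNTS[s] / PEANUT_SUMMARY_TOTALS[s] for s in PEANUT_STAGES
    }
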