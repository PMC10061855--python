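"""Trajectory-based drought-memory gene (DMG) classification.

Each gene is assigned one of eight trajectory categories (or none) from the
significance calls of two contrasts: S1 vs R0 (first dehydration vs
control) and S3 vs S1 (third dehydration vs first).  The symbols encode the
direction of each step, with '=' meaning "not significant at the DEG
thresholds" (not numerical equality):

====================  =========  =========
category              S1 vs R0   S3 vs S1
====================  =========  =========
[+/+]  memory          up         up
[-/-]  memory          down       down
[+/-]  memory          up         down
[-/+]  memory          down       up
[+/=]  non-memory      up         ns
[-/=]  non-memory      down       ns
[=/+]  late-response   ns         up
[=/-]  late-response   ns         down
none                   ns         ns
====================  =========  =========

The summary reproduces the field's standard tabulation with its percentage
bases: drought-responsive (DEG) percent of all genes; memory and non-memory
percents of DEGs; each memory subtype percent of memory genes; late-response
percent of all genes.  Printed percentages round half-up to one decimal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .de import CALL_DOWN, CALL_NS, CALL_UP
from .errors import DroughtMemError

logger = logging.getLogger(__name__)

MEMORY_CATEGORIES = ("[+/+]", "[-/-]", "[+/-]", "[-/+]")
NON_MEMORY_CATEGORIES = ("[+/=]", "[-/=]")
LATE_CATEGORIES = ("[=/+]", "[=/-]")
ALL_CATEGORIES = MEMORY_CATEGORIES + NON_MEMORY_CATEGORIES + LATE_CATEGORIES
NONE_CATEGORY = "none"

_CALL_SYMBOL = {CALL_UP: "+", CALL_DOWN: "-", CALL_NS: "="}


def classify_gene(s1_call: str, s3_call: str) -> str:
    """Map a pair of contrast calls to a trajectory category."""
    for call in (s1_call, s3_call):
        if call not in _CALL_SYMBOL:
            raise DroughtMemError(f"unknown call token '{call}'")
    if s1_call == CALL_NS and s3_call == CALL_NS:
        return NONE_CATEGORY
    return f"[{_CALL_SYMBOL[s1_call]}/{_CALL_SYMBOL[s3_call]}]"


def classify_all(
    contrast_s1: pd.DataFrame, contrast_s3: pd.DataFrame, ecotype: str
) -> pd.DataFrame:
    """One record per gene in the union of both contrasts.

    ``contrast_s1`` is S1-vs-R0 and ``contrast_s3`` is S3-vs-S1 (DataFrames
    with at least ``gene`` and ``call`` columns).  Genes present in only one
    contrast are treated as ns in the other, with a warning.
    """
    for name, df in (("S1", contrast_s1), ("S3", contrast_s3)):
        dups = df["gene"][df["gene"].duplicated()].unique()
        if len(dups):
            raise DroughtMemError(f"duplicate gene(s) in {name} contrast: {list(dups)[:5]}")
    s1 = contrast_s1.set_index("gene")["call"]
    s3 = contrast_s3.set_index("gene")["call"]
    merged = pd.concat({"s1_call": s1, "s3_call": s3}, axis=1)
    n_fill = int(merged.isna().to_numpy().sum())
    if n_fill:
        logger.warning("%d gene/contrast cell(s) missing; treated as ns", n_fill)
    merged = merged.fillna(CALL_NS)
    merged["category"] = [
        classify_gene(a, b) for a, b in zip(merged["s1_call"], merged["s3_call"])
    ]
    merged["ecotype"] = ecotype
    return merged.rename_axis("gene").reset_index()[
        ["gene", "ecotype", "s1_call", "s3_call", "category"]
    ]


def round_percent(x: float, digits: int = 1) -> float:
    """Half-up rounding matching printed-table formatting."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ClassificationSummary:
    """Counts and percentages of the trajectory-category tabulation."""

    total_genes: int
    deg: int
    deg_pct: float
    induced: int
    repressed: int
    non_memory: int
    non_memory_pct: float  # of DEGs
    memory: int
    memory_pct: float  # of DEGs
    late: int
    late_pct: float  # of total genes
    by_category: dict[str, int] = field(default_factory=dict)
    memory_subtype_pct: dict[str, float] = field(default_factory=dict)  # of memory genes
    none: int = 0

    def to_dict(self) -> dict:
        return {
            "total_genes": self.total_genes,
            "deg": self.deg,
            "deg_pct": self.deg_pct,
            "induced": self.induced,
            "repressed": self.repressed,
            "non_memory": self.non_memory,
            "non_memory_pct": self.non_memory_pct,
            "memory": self.memory,
            "memory_pct": self.memory_pct,
            "late": self.late,
            "late_pct": self.late_pct,
            "by_category": dict(self.by_category),
            "memory_subtype_pct": dict(self.memory_subtype_pct),
            "none": self.none,
        }


def summarize(records: pd.DataFrame, total_genes: int) -> ClassificationSummary:
    """Build the category tabulation from per-gene records.

    ``records`` needs ``s1_call`` and ``category`` columns.  ``total_genes``
    is the RNA-seq gene universe (>= the number of classified genes); it is
    the base for the DEG and late-response percentages.
    """
    if total_genes <= 0:
        raise DroughtMemError("total_genes must be positive")
    n_distinct = records["gene"].nunique() if "gene" in records else len(records)
    if total_genes < n_distinct:
        raise DroughtMemError(
            f"total_genes ({total_genes}) < classified genes ({n_distinct})"
        )
    counts = {c: int((records["category"] == c).sum()) for c in ALL_CATEGORIES}
    none = int((records["category"] == NONE_CATEGORY).sum())
    memory = sum(counts[c] for c in MEMORY_CATEGORIES)
    non_memory = sum(counts[c] for c in NON_MEMORY_CATEGORIES)
    late = sum(counts[c] for c in LATE_CATEGORIES)
    deg = memory + non_memory
    induced = int((records["s1_call"] == CALL_UP).sum())
    repressed = int((records["s1_call"] == CALL_DOWN).sum())
    pct = lambda a, b: round_percent(100.0 * a / b) if b else 0.0
    return ClassificationSummary(
        total_genes=int(total_genes),
        deg=deg,
        deg_pct=pct(deg, total_genes),
        induced=induced,
        repressed=repressed,
        non_memory=non_memory,
        non_memory_pct=pct(non_memory, deg),
        memory=memory,
        memory_pct=pct(memory, deg),
        late=late,
        late_pct=pct(late, total_genes),
        by_category=counts,
        memory_subtype_pct={c: pct(counts[c], memory) for c in MEMORY_CATEGORIES},
        none=none,
    )


def records_from_category_counts(counts: dict[str, int], ecotype: str) -> pd.DataFrame:
    """Expand a category -> count table into per-gene records.

    Convenience for re-running the summary arithmetic on published count
    tables without per-gene data.
    """
    rows = []
    i = 0
    sym_to_call = {"+": CALL_UP, "-": CALL_DOWN, "=": CALL_NS}
    for cat, n in counts.items():
        if cat == NONE_CATEGORY:
            s1 = s3 = CALL_NS
        else:
            s1, s3 = sym_to_call[cat[1]], sym_to_call[cat[3]]
        for _ in range(int(n)):
            rows.append((f"g{i:06d}", ecotype, s1, s3, cat))
            i += 1
    return pd.DataFrame(rows, columns=["gene", "ecotype", "s1_call", "s3_call", "category"])
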