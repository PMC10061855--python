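"""Leaf water-status indices and per-stage group comparisons.

Two indices quantify drought response across the recurring
dehydration/re-watering design (stages R0, S1, R1, S2, R2, S3):

* relative water content, RWC (%) = (FW - DW) / (TW - DW) * 100
* water loss of isolated leaves (g/g) = (FW - wilted) / DW

where FW is fresh weight, TW turgid weight after 24 h water saturation,
DW oven-dry weight, and "wilted" the weight after 6 h bench wilting.
Group summaries report mean +/- SD with n, a within-ecotype one-way ANOVA
across stages with a compact-letter display from pairwise t-tests, and
between-ecotype per-stage t-test flags at the 0.05 / 0.01 levels.

Pairwise letters use raw (uncorrected) p-values at ``alpha`` by default, the
convention of the original field analysis; pass ``correct="bh"`` to apply a
Benjamini-Hochberg correction within each ecotype instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidRecordError, LoadError

logger = logging.getLogger(__name__)

STAGES = ("R0", "S1", "R1", "S2", "R2", "S3")


@dataclass(frozen=True)
class LeafWeightRecord:
    """One leaf's four weights (grams) at one stage.

    ``wilted`` is the weight after bench wilting (the "WW" of the index
    formulas, renamed to avoid clashing with the WW ecotype label).
    """

    sample_id: str
    ecotype: str
    stage: str
    fw: float
    tw: float
    wilted: float
    dw: float

    def violations(self) -> list[str]:
        v = []
        if not self.dw > 0:
            v.append(f"DW must be positive (got {self.dw})")
        if self.dw > self.wilted:
            v.append(f"DW {self.dw} > wilted {self.wilted}")
        if self.dw > self.fw:
            v.append(f"DW {self.dw} > FW {self.fw}")
        if self.fw > self.tw:
            v.append(f"FW {self.fw} > TW {self.tw}")
        return v

    def validate(self) -> "LeafWeightRecord":
        v = self.violations()
        if v:
            raise InvalidRecordError(f"record {self.sample_id}: " + "; ".join(v))
        return self


def read_weight_records(path: str | Path) -> list[LeafWeightRecord]:
    """Read a TSV of sample_id, ecotype, stage, FW, TW, wilted, DW.

    Every invariant violation in the file is collected and reported in one
    error; records are never silently clipped.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "ecotype", "stage", "FW", "TW", "wilted", "DW"}
    missing = required - set(df.columns)
    if missing:
        raise LoadError(f"{path}: missing columns {sorted(missing)}")
    records, problems = [], []
    for _, row in df.iterrows():
        rec = LeafWeightRecord(
            str(row["sample_id"]), str(row["ecotype"]), str(row["stage"]),
            float(row["FW"]), float(row["TW"]), float(row["wilted"]), float(row["DW"]),
        )
        v = rec.violations()
        if v:
            problems.append(f"{rec.sample_id}: " + "; ".join(v))
        else:
            records.append(rec)
    if problems:
        raise InvalidRecordError(
            f"{len(problems)} invalid weight record(s):\n" + "\n".join(problems)
        )
    return records


def relative_water_content(record: LeafWeightRecord) -> float:
    """RWC (%) = (FW - DW) / (TW - DW) * 100."""
    denom = record.tw - record.dw
    if denom <= 0:
        raise InvalidRecordError(
            f"record {record.sample_id}: TW - DW must be positive (got {denom})"
        )
    return (record.fw - record.dw) / denom * 100.0


def water_loss(record: LeafWeightRecord) -> float:
    """Water loss (g/g) = (FW - wilted) / DW."""
    if record.dw <= 0:
        raise InvalidRecordError(
            f"record {record.sample_id}: DW must be positive (got {record.dw})"
        )
    return (record.fw - record.wilted) / record.dw


_INDEX_FUNCS = {"rwc": relative_water_content, "water_loss": water_loss}


def _letter_display(levels: list[str], nonsig: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display: groups sharing a letter are not significantly
    different. Insert-and-absorb over the non-significant pair graph."""
    letter_sets: list[set[str]] = []
    for lv in levels:
        # maximal sets of mutually non-different levels, greedy by order
        placed = False
        for s in letter_sets:
            if all((lv, o) in nonsig or (o, lv) in nonsig for o in s):
                s.add(lv)
                placed = True
        if not placed:
            letter_sets.append({lv})
    # absorb subsets
    kept: list[set[str]] = []
    for s in letter_sets:
        if not any(s < t for t in letter_sets if s is not t):
            if s not in kept:
                kept.append(s)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lv: "" for lv in levels}
    for i, s in enumerate(kept):
        for lv in levels:
            if lv in s:
                out[lv] += alphabet[i % len(alphabet)]
    return out


def summarize_groups(
    records: list[LeafWeightRecord],
    index: str = "rwc",
    alpha: float = 0.05,
    correct: str | None = None,
) -> pd.DataFrame:
    """Per-(ecotype, stage) mean/sd/n with significance annotations.

    Columns: ecotype, stage, mean, sd, n, letters (within-ecotype compact
    letter display across stages), between_flag ('' / '*' / '**' from the
    per-stage two-ecotype t-test).
    """
    if index not in _INDEX_FUNCS:
        raise ValueError(f"index must be one of {sorted(_INDEX_FUNCS)}")
    fn = _INDEX_FUNCS[index]
    df = pd.DataFrame(
        {
            "ecotype": [r.ecotype for r in records],
            "stage": [r.stage for r in records],
            "value": [fn(r) for r in records],
        }
    )
    if df.empty:
        raise ValueError("no records supplied")

    rows = []
    stage_order = [s for s in STAGES if s in set(df["stage"])] or sorted(set(df["stage"]))
    for eco, sub in df.groupby("ecotype", sort=True):
        groups = {st: sub.loc[sub["stage"] == st, "value"].to_numpy() for st in stage_order
                  if (sub["stage"] == st).any()}
        testable = {st: v for st, v in groups.items() if len(v) >= 2}
        letters = {st: "" for st in groups}
        anova_p = np.nan
        if len(testable) >= 2:
            anova_p = stats.f_oneway(*testable.values()).pvalue
            pairs = list(combinations(testable, 2))
            pvals = np.array(
                [stats.ttest_ind(testable[a], testable[b]).pvalue for a, b in pairs]
            )
            if correct == "bh":
                from .de import bh_adjust

                pvals = bh_adjust(pvals)
            nonsig = {p for p, pv in zip(pairs, pvals) if not pv < alpha}
            letters = _letter_display([st for st in stage_order if st in testable], nonsig)
        elif len(groups) > 1:
            logger.warning("ecotype %s: fewer than 2 testable stages, letters omitted", eco)
        for st in stage_order:
            if st not in groups:
                continue
            v = groups[st]
            rows.append(
                {
                    "ecotype": eco,
                    "stage": st,
                    "mean": float(np.mean(v)),
                    "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
                    "n": int(len(v)),
                    "letters": letters.get(st, ""),
                    "anova_p": float(anova_p) if np.isfinite(anova_p) else np.nan,
                }
            )
    out = pd.DataFrame(rows)

    # between-ecotype per-stage t-tests
    flags = {}
    ecotypes = sorted(set(df["ecotype"]))
    if len(ecotypes) == 2:
        a, b = ecotypes
        for st in stage_order:
            va = df.loc[(df["ecotype"] == a) & (df["stage"] == st), "value"].to_numpy()
            vb = df.loc[(df["ecotype"] == b) & (df["stage"] == st), "value"].to_numpy()
            if len(va) >= 2 and len(vb) >= 2:
                p = stats.ttest_ind(va, vb).pvalue
                flags[st] = "**" if p < 0.01 else ("*" if p < alpha else "")
    out["between_flag"] = [flags.get(st, "") for st in out["stage"]]
    return out
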