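"""Orthogroup-based cross-species partition of drought-memory genes.

Given an OrthoFinder-style ``Orthogroups.tsv`` table and per-species DMG
sets, orthogroups containing at least one DMG are partitioned into
mutually exclusive tiers of a three-party Venn diagram: the two focal
ecotypes (treated as species) against all outgroup species collapsed into
one "other plants" party:

* ``shared``                 - DMGs from both focal ecotypes and >=1 outgroup
* ``focal_shared``           - both focal ecotypes, no outgroup ("AS" tier)
* ``ecotype_a_unique``       - first focal ecotype only
* ``ecotype_b_unique``       - second focal ecotype only
* ``ecotype_a_with_outgroup`` / ``ecotype_b_with_outgroup``
                             - one focal ecotype plus outgroup DMGs
* ``other_only``             - outgroup DMGs only

Containment is driven by DMG membership, not mere gene presence: an
orthogroup "contains" a party when at least one of that party's DMGs is a
member.  Focal DMGs that belong to no orthogroup ("novel genes") are, by
default, retained as singleton ecotype-unique entries flagged
``singleton=True``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import DroughtMemError, LoadError

logger = logging.getLogger(__name__)

TIER_SHARED = "shared"
TIER_FOCAL_SHARED = "focal_shared"
TIER_A_UNIQUE = "ecotype_a_unique"
TIER_B_UNIQUE = "ecotype_b_unique"
TIER_A_OUTGROUP = "ecotype_a_with_outgroup"
TIER_B_OUTGROUP = "ecotype_b_with_outgroup"
TIER_OTHER_ONLY = "other_only"
ALL_TIERS = (
    TIER_SHARED,
    TIER_FOCAL_SHARED,
    TIER_A_UNIQUE,
    TIER_B_UNIQUE,
    TIER_A_OUTGROUP,
    TIER_B_OUTGROUP,
    TIER_OTHER_ONLY,
)


@dataclass
class OrthogroupTable:
    """orthogroup ID -> {species -> gene list}."""

    groups: dict[str, dict[str, list[str]]]
    species: list[str]

    def genes_of(self, og: str, species: str) -> list[str]:
        return self.groups[og].get(species, [])


def load_orthogroups(path: str | Path) -> OrthogroupTable:
    """Parse an ``Orthogroups.tsv``-dialect file.

    First column is the orthogroup ID; one column per species holds a
    comma-separated gene list (empty cells allowed).  A gene appearing in
    more than one orthogroup within the same species is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise LoadError(f"{path}: need an orthogroup column plus >=1 species column")
    species = list(df.columns[1:])
    groups: dict[str, dict[str, list[str]]] = {}
    seen: dict[str, Counter] = {sp: Counter() for sp in species}
    for _, row in df.iterrows():
        og = row.iloc[0].strip()
        cell: dict[str, list[str]] = {}
        for sp in species:
            genes = [g.strip() for g in row[sp].split(",") if g.strip()]
            if genes:
                cell[sp] = genes
                seen[sp].update(genes)
        groups[og] = cell
    offenders = {
        sp: [g for g, c in cnt.items() if c > 1] for sp, cnt in seen.items()
    }
    offenders = {sp: gs for sp, gs in offenders.items() if gs}
    if offenders:
        raise LoadError(f"genes present in multiple orthogroups: {offenders}")
    return OrthogroupTable(groups, species)


@dataclass
class HierarchyPartition:
    """Tier assignment per orthogroup plus per-gene projections."""

    og_tier: dict[str, str]
    gene_tier: dict[str, dict[str, str]]  # focal species -> {gene -> tier}
    singletons: dict[str, set[str]] = field(default_factory=dict)  # focal sp -> genes
    focal: tuple[str, str] = ("", "")


def partition(
    ogs: OrthogroupTable,
    dmg_sets: dict[str, set[str]],
    focal: tuple[str, str],
    outgroups: set[str] | list[str],
    include_singletons: bool = True,
) -> HierarchyPartition:
    """Assign each DMG-containing orthogroup to one Venn tier."""
    sp_a, sp_b = focal
    outgroups = set(outgroups)
    known = set(ogs.species)
    for sp in {sp_a, sp_b} | outgroups:
        if sp not in known:
            raise DroughtMemError(f"species '{sp}' absent from orthogroup table")
    unknown_dmg_sp = set(dmg_sets) - known
    if unknown_dmg_sp:
        raise DroughtMemError(f"DMG sets given for unknown species: {sorted(unknown_dmg_sp)}")

    og_tier: dict[str, str] = {}
    gene_tier: dict[str, dict[str, str]] = {sp_a: {}, sp_b: {}}
    assigned: dict[str, set[str]] = {sp_a: set(), sp_b: set()}

    for og, cell in ogs.groups.items():
        def hits(sp: str) -> set[str]:
            return set(cell.get(sp, [])) & dmg_sets.get(sp, set())

        a_hits, b_hits = hits(sp_a), hits(sp_b)
        other = any(hits(sp) for sp in outgroups)
        has_a, has_b = bool(a_hits), bool(b_hits)
        if not (has_a or has_b or other):
            continue  # no DMG member: outside the partition
        if has_a and has_b and other:
            tier = TIER_SHARED
        elif has_a and has_b:
            tier = TIER_FOCAL_SHARED
        elif has_a and other:
            tier = TIER_A_OUTGROUP
        elif has_b and other:
            tier = TIER_B_OUTGROUP
        elif has_a:
            tier = TIER_A_UNIQUE
        elif has_b:
            tier = TIER_B_UNIQUE
        else:
            tier = TIER_OTHER_ONLY
        og_tier[og] = tier
        for g in a_hits:
            gene_tier[sp_a][g] = tier
            assigned[sp_a].add(g)
        for g in b_hits:
            gene_tier[sp_b][g] = tier
            assigned[sp_b].add(g)

    singletons: dict[str, set[str]] = {sp_a: set(), sp_b: set()}
    if include_singletons:
        unique_tier = {sp_a: TIER_A_UNIQUE, sp_b: TIER_B_UNIQUE}
        for sp in (sp_a, sp_b):
            in_any_og = {
                g for cell in ogs.groups.values() for g in cell.get(sp, [])
            }
            loose = dmg_sets.get(sp, set()) - in_any_og
            for g in loose:
                gene_tier[sp][g] = unique_tier[sp]
                singletons[sp].add(g)
            if loose:
                logger.info(
                    "%s: %d DMG(s) outside any orthogroup kept as %s singletons",
                    sp, len(loose), unique_tier[sp],
                )
    return HierarchyPartition(og_tier, gene_tier, singletons, (sp_a, sp_b))


def venn_counts(part: HierarchyPartition, include_singletons: bool = False) -> dict[str, int]:
    """Orthogroup counts per tier (singleton genes optionally counted as
    one entry each)."""
    counts = {t: 0 for t in ALL_TIERS}
    for tier in part.og_tier.values():
        counts[tier] += 1
    if include_singletons:
        sp_a, sp_b = part.focal
        counts[TIER_A_UNIQUE] += len(part.singletons.get(sp_a, ()))
        counts[TIER_B_UNIQUE] += len(part.singletons.get(sp_b, ()))
    return counts
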