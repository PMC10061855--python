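"""Signed TF co-expression and "molecular switch" module detection.

The core inference of the package: drought-memory genes (DMGs) are split
into regulatory genes (transcription factors/regulators, TFs/TRs) and
functional genes; every TF-target pair is scored with a Pearson
correlation across one ecotype's sample expression profiles; edges are
retained at |r| > 0.9 and p < 0.05 (strict, two-sided t-test on
t = r*sqrt(m-2)/sqrt(1-r^2) with df = m-2); and functional genes are
grouped by their exact signed TF signature.  A signature group whose TF set
contains at least one positively and one negatively correlated regulator is
a "molecular switch" module: a TF pair (or larger group) plausibly toggling
the same gene set between high and low expression across recurring drought.

The retention rule applies to |r| because both strong positive and strong
negative co-expression carry regulatory signal; the sign is kept on each
edge.  Correlation is computed on log2(FPKM+1) replicate-level profiles by
default (treatment means would leave only one degree of freedom, making
p < 0.05 unattainable).  Constant (zero-variance) genes are skipped with a
logged warning since r is undefined for them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DroughtMemError

logger = logging.getLogger(__name__)


def split_regulatory(dmgs: set[str], regulators: set[str]) -> tuple[set[str], set[str]]:
    """Partition DMGs into (regulatory, functional) by regulator membership."""
    dmgs = set(dmgs)
    regulators = set(regulators)
    outside = regulators - dmgs
    if outside:
        logger.warning("%d regulator(s) not in the DMG set ignored", len(outside))
    reg = dmgs & regulators
    return reg, dmgs - reg


def correlate(
    expr: pd.DataFrame, tfs: set[str], targets: set[str]
) -> pd.DataFrame:
    """Pearson r and two-sided p for every TF-target pair.

    ``expr`` is a genes x samples matrix (log2(FPKM+1) profiles of one
    ecotype).  Requires >= 3 samples.  Returns a DataFrame with columns
    tf, target, r, pvalue, sign.
    """
    m = expr.shape[1]
    if m < 3:
        raise DroughtMemError(f"need >= 3 samples for correlation, got {m}")
    tfs = sorted(set(tfs) & set(expr.index))
    targets = sorted(set(targets) & set(expr.index))
    if not tfs or not targets:
        return pd.DataFrame(columns=["tf", "target", "r", "pvalue", "sign"])

    def standardized(genes: list[str]) -> tuple[np.ndarray, list[str]]:
        x = expr.loc[genes].to_numpy(dtype=float)
        x = x - x.mean(axis=1, keepdims=True)
        norm = np.sqrt((x ** 2).sum(axis=1))
        keep = norm > 0
        dropped = [g for g, k in zip(genes, keep) if not k]
        if dropped:
            logger.warning("%d constant gene(s) skipped: %s...", len(dropped), dropped[:3])
        return x[keep] / norm[keep, None], [g for g, k in zip(genes, keep) if k]

    zt, tfs_kept = standardized(tfs)
    zg, targets_kept = standardized(targets)
    if not tfs_kept or not targets_kept:
        return pd.DataFrame(columns=["tf", "target", "r", "pvalue", "sign"])
    r = np.clip(zt @ zg.T, -1.0, 1.0)
    pvalue = correlation_pvalue(r, m)
    tf_idx, tg_idx = np.meshgrid(
        np.arange(len(tfs_kept)), np.arange(len(targets_kept)), indexing="ij"
    )
    out = pd.DataFrame(
        {
            "tf": np.asarray(tfs_kept)[tf_idx.ravel()],
            "target": np.asarray(targets_kept)[tg_idx.ravel()],
            "r": r.ravel(),
            "pvalue": pvalue.ravel(),
        }
    )
    out["sign"] = np.where(out["r"] >= 0, "+", "-")
    return out


def correlation_pvalue(r: np.ndarray | float, m: int) -> np.ndarray:
    """Two-sided p for Pearson r with m samples via the t transform."""
    r = np.asarray(r, dtype=float)
    df = m - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df) / np.sqrt(1.0 - r ** 2)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(np.isclose(np.abs(r), 1.0), 0.0, p)


def filter_edges(
    edges: pd.DataFrame, r_min: float = 0.9, p_max: float = 0.05
) -> pd.DataFrame:
    """Keep edges with |r| > r_min and p < p_max (both strict)."""
    if edges.empty:
        return edges
    keep = (edges["r"].abs() > r_min) & (edges["pvalue"] < p_max)
    return edges[keep].reset_index(drop=True)


@dataclass
class SwitchModule:
    """A functional gene set sharing one signed TF signature with both
    positive and negative regulators ("on-off" requirement)."""

    positive_tfs: frozenset[str]
    negative_tfs: frozenset[str]
    members: frozenset[str]
    hierarchy: str = ""
    ecotype: str = ""

    @property
    def signature(self) -> frozenset[tuple[str, str]]:
        return frozenset(
            [(tf, "+") for tf in self.positive_tfs]
            + [(tf, "-") for tf in self.negative_tfs]
        )

    def to_dict(self) -> dict:
        return {
            "positive_tfs": sorted(self.positive_tfs),
            "negative_tfs": sorted(self.negative_tfs),
            "members": sorted(self.members),
            "hierarchy": self.hierarchy,
            "ecotype": self.ecotype,
        }


def detect_switch_modules(
    edges: pd.DataFrame,
    min_module_size: int = 5,
    min_tfs_per_sign: int = 1,
    hierarchy: str = "",
    ecotype: str = "",
    jaccard_merge: float | None = None,
) -> list[SwitchModule]:
    """Group functional genes by exact signed TF signature.

    Each group with >= ``min_tfs_per_sign`` positive AND negative TFs and
    >= ``min_module_size`` members becomes a module; groups are disjoint in
    members by construction.  ``jaccard_merge`` (e.g. 0.8) optionally merges
    signature groups whose TF signatures overlap at or above that Jaccard
    index before applying the thresholds (relaxed mode, off by default).
    """
    if edges.empty:
        return []
    sig_members: dict[frozenset[tuple[str, str]], set[str]] = {}
    for target, sub in edges.groupby("target"):
        signature = frozenset(zip(sub["tf"], sub["sign"]))
        sig_members.setdefault(signature, set()).add(target)

    groups = [(sig, members) for sig, members in sig_members.items()]
    if jaccard_merge is not None:
        groups = _merge_similar(groups, jaccard_merge)

    modules = []
    for sig, members in groups:
        pos = frozenset(tf for tf, s in sig if s == "+")
        neg = frozenset(tf for tf, s in sig if s == "-")
        if (
            len(pos) >= min_tfs_per_sign
            and len(neg) >= min_tfs_per_sign
            and len(members) >= min_module_size
        ):
            modules.append(
                SwitchModule(pos, neg, frozenset(members), hierarchy, ecotype)
            )
    modules.sort(key=lambda mod: (-len(mod.members), sorted(mod.members)[0]))
    return modules


def _merge_similar(groups, threshold: float):
    """Single-link merge of signature groups by Jaccard similarity of
    signatures; merged signature is the union, members are pooled."""
    groups = [(set(sig), set(members)) for sig, members in groups]
    merged = True
    while merged:
        merged = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a, b = groups[i][0], groups[j][0]
                jac = len(a & b) / len(a | b) if a | b else 0.0
                if jac >= threshold:
                    groups[i] = (a | b, groups[i][1] | groups[j][1])
                    del groups[j]
                    merged = True
                    break
            if merged:
                break
    return [(frozenset(sig), members) for sig, members in groups]
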