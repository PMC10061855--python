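"""Hypergeometric over-representation analysis of annotation terms.

For a query gene set of size n drawn from a background universe of size N,
a term annotating K background genes and k query genes is scored with the
upper-tail hypergeometric probability P(X >= k), X ~ Hypergeometric(N, K, n).
P-values are Benjamini-Hochberg adjusted over all tested terms.  Term
hierarchies (GO parent terms, KEGG maps) are not traversed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .de import bh_adjust
from .errors import DroughtMemError, LoadError

logger = logging.getLogger(__name__)


@dataclass
class TermAnnotation:
    """term ID -> (name, namespace, annotated gene set) over a background."""

    terms: dict[str, tuple[str, str, frozenset[str]]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        stray = {
            t: sorted(g - self.background)[:3]
            for t, (_, _, g) in self.terms.items()
            if g - self.background
        }
        if stray:
            raise LoadError(f"annotated genes outside background: {stray}")


def load_annotation(
    path: str | Path, background: set[str] | None = None
) -> TermAnnotation:
    """Read a TSV of gene, term_id, term_name, namespace.

    With no explicit background, the union of annotated genes is used.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"gene", "term_id"}
    if need - set(df.columns):
        raise LoadError(f"{path}: requires columns gene, term_id[, term_name, namespace]")
    if "term_name" not in df:
        df["term_name"] = df["term_id"]
    if "namespace" not in df:
        df["namespace"] = ""
    terms: dict[str, tuple[str, str, frozenset[str]]] = {}
    for tid, sub in df.groupby("term_id"):
        terms[tid] = (
            sub["term_name"].iloc[0],
            sub["namespace"].iloc[0],
            frozenset(sub["gene"]),
        )
    bg = frozenset(background) if background is not None else frozenset(df["gene"])
    return TermAnnotation(terms, bg)


def hypergeom_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise DroughtMemError(
            f"inconsistent counts: k={k}, n={n}, K={K}, N={N}"
        )
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: set[str],
    ann: TermAnnotation,
    alpha: float = 0.05,
    min_term_size: int = 2,
) -> pd.DataFrame:
    """Term over-representation of ``query`` against ``ann.background``.

    Returns one row per term with >=1 query hit (and K >= ``min_term_size``),
    sorted by adjusted p-value: term_id, term_name, namespace, k, n, K, N,
    fold_enrichment, pvalue, padj, significant.
    """
    if not ann.background:
        raise DroughtMemError("empty background universe")
    stray = set(query) - ann.background
    if stray:
        logger.warning("%d query gene(s) outside background dropped", len(stray))
    q = set(query) & ann.background
    n, N = len(q), len(ann.background)
    rows = []
    for tid, (name, ns, genes) in ann.terms.items():
        K = len(genes)
        if K < min_term_size:
            continue
        k = len(q & genes)
        if k == 0:
            continue
        p = hypergeom_test(k, n, K, N)
        fe = (k / n) / (K / N)
        rows.append((tid, name, ns, k, n, K, N, fe, p))
    out = pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_name", "namespace",
            "k", "n", "K", "N", "fold_enrichment", "pvalue",
        ],
    )
    if out.empty:
        out["padj"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    out["significant"] = out["padj"] < alpha
    return out.sort_values(["padj", "pvalue", "term_id"]).reset_index(drop=True)
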