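"""Negative-binomial differential-expression caller.

A light-weight stand-in for the usual R-based NB machinery, preserving the
decision rule downstream classification consumes: a gene is differentially
expressed between two treatments when its BH-adjusted p-value is < alpha
(default 0.05) and |log2 fold change| >= lfc_min (default 1).

Pipeline per contrast:

1. median-of-ratios size factors (geometric-mean reference over genes with
   all-positive counts);
2. per-gene method-of-moments NB dispersion on normalized counts,
   alpha_hat = max(0, (s^2 - mu) / mu^2), pooled over every treatment group
   of the tested ecotype (dispersion is a property of the gene, not of one
   contrast) and moderated toward the across-gene median dispersion with a
   prior weight of ``prior_df`` (default 6) residual degrees of freedom,
   then floored at 1e-8.  Moderation is essential at the 2-3 replicates
   typical of these designs: raw method-of-moments dispersions are so noisy
   there that the test is either anticonservative (normal reference) or
   badly underpowered (t reference), and a modest empirical-Bayes pull
   toward the typical dispersion restores both calibration and power;
3. Wald-type test on log2 of normalized group means with a delta-method
   standard error under Var(K) = mu + alpha*mu^2; two-sided p-value from a
   t reference whose degrees of freedom are the pooled residual df plus
   ``prior_df``, mirroring the moderated-t convention;
4. Benjamini-Hochberg adjustment over all tested genes.

A pseudo-count of 0.5 enters only the reported log2 fold change (to avoid
infinities), never the test statistic denominator's mean estimates.
Externally produced contrast tables (e.g. DESeq2 output) can be loaded with
:func:`read_contrast_table` and fed to the classifier unchanged.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DroughtMemError, LoadError
from .expression import CountMatrix

logger = logging.getLogger(__name__)

CALL_UP = "up"
CALL_DOWN = "down"
CALL_NS = "ns"

_DISPERSION_FLOOR = 1e-8
_PSEUDOCOUNT = 0.5

CONTRAST_COLUMNS = ["gene", "baseline", "comparison", "log2fc", "pvalue", "padj", "call"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def estimate_size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors (DESeq-style).

    Falls back to relative library sizes (column sums scaled to geometric
    mean 1) with a warning when no gene has positive counts in every sample.
    """
    values = counts.values if isinstance(counts, CountMatrix) else counts
    arr = values.to_numpy(dtype=float)
    all_pos = np.all(arr > 0, axis=1)
    if all_pos.any():
        logref = np.log(arr[all_pos]).mean(axis=1, keepdims=True)
        ratios = np.log(arr[all_pos]) - logref
        factors = np.exp(np.median(ratios, axis=0))
    else:
        logger.warning(
            "no gene with positive counts in all samples; "
            "falling back to library-size factors"
        )
        libs = arr.sum(axis=0)
        if not np.all(libs > 0):
            raise DroughtMemError("cannot estimate size factors: empty samples present")
        factors = libs / np.exp(np.mean(np.log(libs)))
    return pd.Series(factors, index=values.columns, name="size_factor")


def _group_arrays(counts: CountMatrix, treatment: str, ecotype: str | None) -> np.ndarray:
    cols = counts.samples_for(ecotype=ecotype, treatment=treatment)
    if len(cols) < 2:
        raise DroughtMemError(
            f"treatment '{treatment}'"
            + (f" in ecotype '{ecotype}'" if ecotype else "")
            + f" has {len(cols)} replicate(s); at least 2 required"
        )
    return counts.values[cols].to_numpy(dtype=float), cols


def _pooled_dispersion(
    counts: CountMatrix,
    size_factors: pd.Series,
    ecotype: str | None,
    prior_df: float,
) -> tuple[np.ndarray, int]:
    """Moderated method-of-moments dispersion and the pooled residual df.

    Per treatment group g with n_g replicates: alpha_g = (s^2 - mu) / mu^2
    on normalized counts; these are pooled with weights (n_g - 1), truncated
    at 0, then shrunk toward the across-gene median dispersion (computed on
    genes with pooled mean > 5 to avoid the low-count noise floor) with
    prior weight ``prior_df``.
    """
    sub = counts.subset(ecotype=ecotype) if ecotype else counts
    disp_num = 0.0
    resid_df = 0
    mu_sum = 0.0
    n_groups = 0
    for tr in sorted(set(sub.design["treatment"])):
        cols = sub.samples_for(treatment=tr)
        if len(cols) < 2:
            continue
        q = sub.values[cols].to_numpy(dtype=float) / size_factors[cols].to_numpy()
        mu = q.mean(axis=1)
        s2 = q.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (s2 - mu) / np.square(mu)
        a = np.where(np.isfinite(a), a, 0.0)
        disp_num = disp_num + a * (len(cols) - 1)
        resid_df += len(cols) - 1
        mu_sum = mu_sum + mu
        n_groups += 1
    raw = np.maximum(disp_num / resid_df, 0.0)
    mu_all = mu_sum / max(n_groups, 1)
    expressed = mu_all > 5
    trend = float(np.median(raw[expressed])) if np.any(expressed) else float(np.median(raw))
    trend = max(trend, _DISPERSION_FLOOR)
    disp = (resid_df * raw + prior_df * trend) / (resid_df + prior_df)
    return np.maximum(disp, _DISPERSION_FLOOR), resid_df


def nb_test(
    counts: CountMatrix,
    baseline: str,
    comparison: str,
    ecotype: str | None = None,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    size_factors: pd.Series | None = None,
    prior_df: float = 6.0,
) -> pd.DataFrame:
    """Per-gene NB Wald-type contrast of ``comparison`` over ``baseline``.

    Returns a DataFrame with columns gene, baseline, comparison, log2fc,
    pvalue, padj, call.  Genes with zero counts in every sample of both
    groups are excluded from testing (reported via a warning).
    """
    kb, cols_b = _group_arrays(counts, baseline, ecotype)
    kc, cols_c = _group_arrays(counts, comparison, ecotype)
    if size_factors is None:
        sub = counts.subset(ecotype=ecotype) if ecotype else counts
        size_factors = estimate_size_factors(sub)
    sf_b = size_factors[cols_b].to_numpy()
    sf_c = size_factors[cols_c].to_numpy()

    qb = kb / sf_b  # normalized counts
    qc = kc / sf_c
    mu_b = qb.mean(axis=1)
    mu_c = qc.mean(axis=1)

    tested = (kb.sum(axis=1) + kc.sum(axis=1)) > 0
    n_skipped = int((~tested).sum())
    if n_skipped:
        logger.warning("%d gene(s) with all-zero counts in both groups excluded", n_skipped)

    disp, resid_df = _pooled_dispersion(counts, size_factors, ecotype, prior_df)

    log2fc = np.log2((mu_c + _PSEUDOCOUNT) / (mu_b + _PSEUDOCOUNT))

    # delta method on log2 of normalized group means, Var(K) = mu + a mu^2
    def mean_var(mu: np.ndarray, sf: np.ndarray) -> np.ndarray:
        per_sample = mu[:, None] / sf[None, :] + disp[:, None] * np.square(mu)[:, None]
        return per_sample.sum(axis=1) / (len(sf) ** 2)

    ln2sq = np.log(2.0) ** 2
    mu_b_safe = np.maximum(mu_b, _PSEUDOCOUNT)
    mu_c_safe = np.maximum(mu_c, _PSEUDOCOUNT)
    se2 = mean_var(mu_b, sf_b) / (np.square(mu_b_safe) * ln2sq) + mean_var(
        mu_c, sf_c
    ) / (np.square(mu_c_safe) * ln2sq)
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    pvalue = 2.0 * stats.t.sf(np.abs(z), resid_df + prior_df)

    genes = np.asarray(counts.gene_ids)
    out = pd.DataFrame(
        {
            "gene": genes[tested],
            "baseline": baseline,
            "comparison": comparison,
            "log2fc": log2fc[tested],
            "pvalue": pvalue[tested],
        }
    )
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    out["call"] = make_calls(out["log2fc"].to_numpy(), out["padj"].to_numpy(), alpha, lfc_min)
    return out


def make_calls(log2fc: np.ndarray, padj: np.ndarray, alpha: float = 0.05, lfc_min: float = 1.0):
    """DEG decision rule: padj < alpha (strict) and |log2fc| >= lfc_min."""
    sig = padj < alpha
    call = np.full(len(log2fc), CALL_NS, dtype=object)
    call[sig & (log2fc >= lfc_min)] = CALL_UP
    call[sig & (log2fc <= -lfc_min)] = CALL_DOWN
    return call


def read_contrast_table(
    path: str | Path, alpha: float = 0.05, lfc_min: float = 1.0
) -> pd.DataFrame:
    """Load an externally produced contrast TSV (gene, log2fc, pvalue, padj[, call]).

    Missing ``call`` columns are derived from padj/log2fc at the given
    thresholds, so DESeq2-style output can be dropped in directly.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    ren = {}
    for want, aliases in {
        "gene": ("gene", "gene_id", "id"),
        "log2fc": ("log2fc", "log2foldchange", "lfc"),
        "pvalue": ("pvalue", "p", "pval"),
        "padj": ("padj", "qvalue", "fdr", "adj_p"),
    }.items():
        for a in aliases:
            if a in cols:
                ren[cols[a]] = want
                break
    df = df.rename(columns=ren)
    for want in ("gene", "log2fc", "padj"):
        if want not in df.columns:
            raise LoadError(f"{path}: no recognizable '{want}' column")
    if "call" not in df.columns:
        df["call"] = make_calls(
            df["log2fc"].to_numpy(float), df["padj"].to_numpy(float), alpha, lfc_min
        )
    return df
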