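"""Count-matrix container, TSV I/O and FPKM normalization.

The central object is :class:`CountMatrix`: a genes x samples matrix of
non-negative integer read counts plus a sample design table mapping each
sample to an ecotype (AEX or WW), a treatment stage (R0 control, S1 first
dehydration, S3 third dehydration) and a replicate number.

FPKM (fragments per kilobase of exon per million mapped reads) is computed
as counts / (mapped_reads_in_millions * exon_length_kb).  Because the
sequencing depth actually mapped is not always known, the per-sample column
sum of the count matrix is used as the default "mapped reads" denominator;
an explicit per-sample mapping can be supplied instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import LoadError

logger = logging.getLogger(__name__)

ECOTYPES = ("AEX", "WW")
TREATMENTS = ("R0", "S1", "S3")

DESIGN_COLUMNS = ("ecotype", "treatment", "replicate")


@dataclass
class CountMatrix:
    """Gene-level read counts with sample design metadata.

    Attributes
    ----------
    values:
        DataFrame indexed by gene ID with one integer column per sample.
    design:
        DataFrame indexed by sample ID with columns ``ecotype``,
        ``treatment`` and ``replicate``.  Row order matches the columns
        of ``values``.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise LoadError(f"duplicate gene IDs: {dups[:5]}")
        if self.values.columns.duplicated().any():
            raise LoadError("duplicate sample IDs in count matrix")
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise LoadError(f"samples missing from design table: {missing}")
        for col in DESIGN_COLUMNS:
            if col not in self.design.columns:
                raise LoadError(f"design table lacks required column '{col}'")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            # allow float input only when every cell is a whole number
            if not np.all(np.isfinite(arr)) or not np.all(arr == np.floor(arr)):
                bad = np.argwhere(~(arr == np.floor(arr)))
                g, s = bad[0]
                raise LoadError(
                    f"non-integer count at gene '{self.values.index[g]}', "
                    f"sample '{self.values.columns[s]}'"
                )
            self.values = self.values.astype(np.int64)
            arr = self.values.to_numpy()
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)
            g, s = bad[0]
            raise LoadError(
                f"negative count at gene '{self.values.index[g]}', "
                f"sample '{self.values.columns[s]}'"
            )
        # keep design aligned with matrix column order
        self.design = self.design.loc[list(self.values.columns)]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_for(self, ecotype: str | None = None, treatment: str | None = None) -> list[str]:
        """Sample IDs matching the given ecotype and/or treatment."""
        mask = pd.Series(True, index=self.design.index)
        if ecotype is not None:
            mask &= self.design["ecotype"] == ecotype
        if treatment is not None:
            mask &= self.design["treatment"] == treatment
        return list(self.design.index[mask])

    def subset(self, ecotype: str | None = None, treatment: str | None = None) -> "CountMatrix":
        cols = self.samples_for(ecotype, treatment)
        return CountMatrix(self.values[cols].copy(), self.design.loc[cols].copy())

    def write(self, counts_path: str | Path, design_path: str | Path) -> None:
        df = self.values.copy()
        df.index.name = "gene_id"
        df.to_csv(counts_path, sep="\t")
        d = self.design.copy()
        d.index.name = "sample"
        d.to_csv(design_path, sep="\t")


def read_counts(path: str | Path, design_path: str | Path) -> CountMatrix:
    """Load a counts TSV (gene_id column + one column per sample) and its design."""
    try:
        values = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise LoadError(f"cannot read count matrix {path}: {exc}") from exc
    try:
        design = pd.read_csv(design_path, sep="\t", index_col=0, dtype={"replicate": int})
    except Exception as exc:
        raise LoadError(f"cannot read design table {design_path}: {exc}") from exc
    values.index.name = None
    design.index.name = None
    return CountMatrix(values, design)


@dataclass
class GeneAnnotation:
    """Per-gene exon length (base pairs) and optional descriptions."""

    lengths_bp: dict[str, float]
    symbols: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [g for g, v in self.lengths_bp.items() if not v > 0]
        if bad:
            raise LoadError(f"non-positive gene lengths for: {bad[:5]}")

    def length_kb(self, gene: str) -> float:
        return self.lengths_bp[gene] / 1000.0


def read_gene_lengths(path: str | Path) -> GeneAnnotation:
    """Read a two-column TSV of gene ID and exon length in bp."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise LoadError(f"{path}: expected columns gene_id, length_bp")
    gene_col, len_col = df.columns[:2]
    return GeneAnnotation(dict(zip(df[gene_col].astype(str), df[len_col].astype(float))))


def compute_fpkm(
    counts: CountMatrix,
    ann: GeneAnnotation,
    mapped_reads: Mapping[str, float] | str = "column-sum",
) -> pd.DataFrame:
    """FPKM normalization: counts / (mapped reads (millions) x exon length (kb)).

    ``mapped_reads`` is either the string ``"column-sum"`` (use each sample's
    total counts) or an explicit sample -> read-count mapping.
    """
    missing = [g for g in counts.gene_ids if g not in ann.lengths_bp]
    if missing:
        raise LoadError(f"genes without length annotation: {missing[:5]}")
    if isinstance(mapped_reads, str):
        if mapped_reads != "column-sum":
            raise LoadError(f"unknown mapped_reads mode '{mapped_reads}'")
        depth = counts.values.sum(axis=0).astype(float)
    else:
        try:
            depth = pd.Series({s: float(mapped_reads[s]) for s in counts.sample_ids})
        except KeyError as exc:
            raise LoadError(f"mapped_reads missing sample {exc}") from exc
    if (depth <= 0).any():
        bad = list(depth.index[depth <= 0])
        raise LoadError(f"zero/negative mapped reads for samples: {bad}")
    len_kb = np.array([ann.length_kb(g) for g in counts.gene_ids])
    fpkm = counts.values.to_numpy(dtype=float) / (depth.to_numpy() / 1e6)
    fpkm = fpkm / len_kb[:, None]
    return pd.DataFrame(fpkm, index=counts.values.index, columns=counts.values.columns)


def effective_mapped_reads(counts: CountMatrix) -> pd.Series:
    """Composition-robust per-sample depths for FPKM normalization.

    Median-of-ratios size factors rescaled to the geometric-mean library
    size.  Unlike raw column sums, these depths are not dragged around by a
    handful of strongly regulated high-expression genes, so between-sample
    depth correction does not leak treatment signal into every profile.
    Intended as the ``mapped_reads`` argument of :func:`compute_fpkm` when
    the FPKM matrix feeds co-expression analysis.
    """
    from .de import estimate_size_factors  # local import to avoid a cycle

    sf = estimate_size_factors(counts)
    depth = counts.values.sum(axis=0).astype(float)
    scale = float(np.exp(np.mean(np.log(depth / sf))))
    return sf * scale


def log_fpkm(fpkm: pd.DataFrame) -> pd.DataFrame:
    """log2(FPKM + 1), the expression scale used for co-expression analysis."""
    return np.log2(fpkm + 1.0)


def pca_diagnostics(fpkm: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Sample-level PCA scores on log2(FPKM+1), a replicate-quality diagnostic."""
    x = log_fpkm(fpkm).to_numpy().T
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    return pd.DataFrame(
        scores, index=fpkm.columns, columns=[f"PC{i+1}" for i in range(k)]
    )


def replicate_correlation(fpkm: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between sample profiles on log2(FPKM+1)."""
    return log_fpkm(fpkm).corr(method="pearson")
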