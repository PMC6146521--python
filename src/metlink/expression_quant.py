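"""Count normalization, per-pair fold-change rankings, BH adjustment,
PCA-based sample QC and Fisher term overrepresentation."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, NormalizationError, UsageError

__all__ = [
    "CountMatrix",
    "FCRanking",
    "compute_size_factors",
    "pair_fold_change",
    "bh_adjust",
    "pca_outlier_flags",
    "term_overrepresentation",
    "read_counts_tsv",
]

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Gene x sample matrix.  ``counts`` holds raw non-negative integers;
    after :meth:`normalized` the returned matrix holds reals and carries the
    size factors used."""

    counts: pd.DataFrame
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise DataError("duplicate gene identifiers in count matrix")
        if self.counts.columns.has_duplicates:
            raise DataError("duplicate sample identifiers in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise DataError("negative entries in count matrix")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def normalized(self) -> "CountMatrix":
        factors = compute_size_factors(self)
        norm = self.counts.div(factors, axis=1)
        return CountMatrix(counts=norm, size_factors=factors)


def compute_size_factors(m: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample: the median, over genes with strictly positive counts in
    every sample, of count / per-gene geometric mean.
    """
    df = m.counts if isinstance(m, CountMatrix) else m
    if df.shape[1] < 2:
        raise UsageError("size factors need at least two samples")
    x = df.to_numpy(dtype=float)
    all_pos = (x > 0).all(axis=1)
    if not all_pos.any():
        raise NormalizationError("no gene with nonzero counts in every sample")
    logx = np.log(x[all_pos])
    log_geomean = logx.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logx - log_geomean, axis=0))
    return pd.Series(factors, index=df.columns, name="size_factor")


@dataclass
class FCRanking:
    """Genes of one tumour/normal pair ordered by descending fold change.

    ``table`` is indexed by gene with columns ``fc`` and ``rank``; ranks are
    a permutation of 1..G, ties in FC broken lexicographically by gene id.
    """

    tumour_sample: str
    normal_sample: str
    table: pd.DataFrame
    pseudocount: float
    dropped_genes: list[str]

    def ranks_of(self, genes: Sequence[str]) -> np.ndarray:
        return self.table.loc[list(genes), "rank"].to_numpy()

    @property
    def n_genes(self) -> int:
        return len(self.table)


def pair_fold_change(
    m_norm: CountMatrix,
    tumour: str,
    normal: str,
    pseudocount: float = 0.5,
    sample_sheet: pd.DataFrame | None = None,
) -> FCRanking:
    """Gene-wise FC = (normalized tumour + c) / (normalized normal + c).

    Genes with zero counts in both samples are dropped and logged.  When a
    sample sheet is supplied the two samples must belong to one patient.
    """
    for s in (tumour, normal):
        if s not in m_norm.counts.columns:
            raise DataError(f"sample {s} not in count matrix")
    if sample_sheet is not None:
        pats = sample_sheet.set_index("sample_id")["patient_id"]
        if pats.get(tumour) != pats.get(normal):
            raise UsageError(f"samples {tumour} and {normal} belong to different patients")
    if pseudocount <= 0:
        raise UsageError("pseudocount must be positive")

    t = m_norm.counts[tumour]
    n = m_norm.counts[normal]
    both_zero = (t == 0) & (n == 0)
    dropped = list(m_norm.counts.index[both_zero])
    if dropped:
        logger.info("dropping %d genes with zero counts in both %s and %s", len(dropped), tumour, normal)
    t, n = t[~both_zero], n[~both_zero]
    fc = (t + pseudocount) / (n + pseudocount)
    # stable sort on a gene-id-sorted frame = descending FC with lexicographic tie-break
    tbl = pd.DataFrame({"fc": fc}).sort_index(kind="mergesort")
    tbl = tbl.sort_values("fc", ascending=False, kind="mergesort")
    tbl["rank"] = np.arange(1, len(tbl) + 1)
    return FCRanking(
        tumour_sample=tumour,
        normal_sample=normal,
        table=tbl,
        pseudocount=pseudocount,
        dropped_genes=dropped,
    )


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise UsageError("bh_adjust expects a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DataError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def pca_outlier_flags(
    m: CountMatrix, n_components: int = 4, z_threshold: float = 6.0
) -> list[str]:
    """Flag samples far from the cohort centroid in PCA space.

    PCA is run on log2(normalized + 1) with gene-centering; a sample is
    flagged when its Euclidean distance to the centroid over the first
    ``n_components`` components exceeds ``z_threshold`` robust z-scores
    (median / scaled MAD over samples).
    """
    n_samples = m.counts.shape[1]
    if n_samples < 3:
        raise UsageError("PCA QC needs at least three samples")
    if n_components >= n_samples:
        raise UsageError("n_components must be smaller than the number of samples")

    norm = m if m.size_factors is not None else m.normalized()
    logx = np.log2(norm.counts.to_numpy(dtype=float) + 1.0)
    centered = logx - logx.mean(axis=1, keepdims=True)
    # samples as rows for the SVD
    u, s, vt = np.linalg.svd(centered.T, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    centroid = scores.mean(axis=0)
    dist = np.sqrt(((scores - centroid) ** 2).sum(axis=1))
    # tolerance guards against floating-point dust on degenerate matrices
    tol = 1e-9 * max(1.0, float(np.abs(logx).max()))
    dist[dist < tol] = 0.0
    med = np.median(dist)
    mad = np.median(np.abs(dist - med)) * 1.4826
    if mad < tol:
        z = np.where(dist - med > tol, np.inf, 0.0)
    else:
        z = (dist - med) / mad
    flagged = [str(c) for c, zz in zip(m.counts.columns, z) if zz > z_threshold]
    return flagged


def term_overrepresentation(
    selected_genes: Sequence[str],
    universe: Sequence[str],
    term_map: Mapping[str, Sequence[str]],
    min_term: int = 3,
    max_term_frac: float = 0.02,
) -> pd.DataFrame:
    """One-sided Fisher overrepresentation of terms in a selected gene set.

    Terms are tested only when their in-universe size is at least
    ``min_term`` and below ``max_term_frac`` of the universe.  Reports the
    observed count, the expected count under the hypergeometric null, the
    Fisher p and its BH adjustment.
    """
    uni = set(universe)
    if not uni:
        raise UsageError("empty gene universe")
    sel = set(selected_genes)
    if not sel <= uni:
        raise UsageError("selected genes must be a subset of the universe")
    n_uni, n_sel = len(uni), len(sel)
    max_size = max_term_frac * n_uni

    rows = []
    for term in sorted(term_map):
        members = set(term_map[term]) & uni
        size = len(members)
        if size < min_term or size >= max_size:
            continue
        count = len(members & sel)
        table = [
            [count, n_sel - count],
            [size - count, n_uni - n_sel - (size - count)],
        ]
        _, p = stats.fisher_exact(table, alternative="greater")
        rows.append(
            {
                "term": term,
                "term_size": size,
                "count": count,
                "expected_count": size * n_sel / n_uni,
                "p_value": float(p),
            }
        )
    df = pd.DataFrame(rows, columns=["term", "term_size", "count", "expected_count", "p_value"])
    if len(df):
        df["p_adjusted"] = bh_adjust(df["p_value"].to_numpy())
        df = df.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)
    else:
        df["p_adjusted"] = pd.Series(dtype=float)
    return df


def read_counts_tsv(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(counts=df)
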