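"""Rank-based association between mutation load and expression change.

For each tumour sample and mutation class, the positions of altered genes on
that sample's fold-change-sorted gene list are compared with the positions of
all remaining genes by a two-sample Kolmogorov-Smirnov test.  Results are
assembled into a samples x classes matrix with -log10 p entries, a sentinel
"Inf" for values above 10, and significance flagged at p < 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .errors import UsageError
from .expression_quant import FCRanking
from .variant_filtering import MUTATION_CLASSES, VariantRecord, mutation_class_membership

__all__ = [
    "AssociationResult",
    "AssociationMatrix",
    "ks_two_sample",
    "associate",
    "build_association_matrix",
    "format_neglog10p",
]

logger = logging.getLogger(__name__)

NEGLOG10_CAP = 10.0  # rendered as the sentinel "Inf" beyond this


def _ks_statistic_int(a: np.ndarray, b: np.ndarray) -> int:
    """sup |ECDF_a - ECDF_b| scaled by n*m, as an exact integer."""
    n, m = len(a), len(b)
    pooled = np.unique(np.concatenate([a, b]))
    ia = np.searchsorted(np.sort(a), pooled, side="right")
    ib = np.searchsorted(np.sort(b), pooled, side="right")
    return int(np.max(np.abs(ia.astype(np.int64) * m - ib.astype(np.int64) * n)))


def _exact_ks_pvalue(n: int, m: int, d_int: int) -> float:
    """P(D >= d_int / (n*m)) under random assignment of n+m distinct values.

    Counts monotone lattice paths from (0,0) to (n,m) whose deviation
    |i*m - j*n| stays strictly below d_int, with exact integer arithmetic.
    Equivalent to enumerating all C(n+m, n) label assignments.
    """
    if d_int <= 0:
        return 1.0
    # column[j] = number of admissible paths reaching (i, j)
    col = [1] * (m + 1)
    for j in range(1, m + 1):
        if abs(0 * m - j * n) >= d_int:
            col[j] = 0
        else:
            col[j] = col[j - 1]
    for i in range(1, n + 1):
        new = [0] * (m + 1)
        new[0] = col[0] if abs(i * m) < d_int else 0
        for j in range(1, m + 1):
            if abs(i * m - j * n) >= d_int:
                new[j] = 0
            else:
                new[j] = new[j - 1] + col[j]
        col = new
    total = math.comb(n + m, n)
    return float((total - col[m]) / total)


def ks_two_sample(
    a: Sequence[float] | np.ndarray,
    b: Sequence[float] | np.ndarray,
    mode: str = "auto",
) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test.

    Returns (D, p).  D = sup |ECDF_a - ECDF_b|.  With ``mode="auto"`` the
    p-value is exact (lattice-path enumeration over label assignments) when
    min(|a|, |b|) <= 10 and all pooled values are distinct, otherwise the
    asymptotic Kolmogorov distribution at effective size
    n_e = |a||b| / (|a|+|b|) is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise UsageError("ks_two_sample requires non-empty samples")
    if mode not in ("auto", "exact", "asymptotic"):
        raise UsageError(f"unknown mode {mode!r}")
    n, m = a.size, b.size
    d_int = _ks_statistic_int(a, b)
    d = d_int / (n * m)

    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    use_exact = mode == "exact" or (mode == "auto" and min(n, m) <= 10 and no_ties)
    if use_exact:
        if not no_ties:
            raise UsageError("exact KS p-value requires distinct pooled values")
        p = _exact_ks_pvalue(n, m, d_int)
    else:
        n_e = n * m / (n + m)
        p = float(special.kolmogorov(math.sqrt(n_e) * d))
    p = min(1.0, max(p, 0.0))
    return d, p


@dataclass(slots=True)
class AssociationResult:
    sample_id: str
    mutation_class: str
    n_altered: int
    n_unaltered: int
    D: float
    p: float
    neglog10p: float
    significant: bool
    tested: bool

    @staticmethod
    def not_tested(sample_id: str, mutation_class: str, n_altered: int = 0, n_unaltered: int = 0) -> "AssociationResult":
        return AssociationResult(
            sample_id=sample_id,
            mutation_class=mutation_class,
            n_altered=n_altered,
            n_unaltered=n_unaltered,
            D=math.nan,
            p=math.nan,
            neglog10p=math.nan,
            significant=False,
            tested=False,
        )


def format_neglog10p(result: AssociationResult, digits: int = 2) -> str:
    """Table cell: blank when not tested, "Inf" above the cap, else -log10 p."""
    if not result.tested:
        return ""
    if result.neglog10p > NEGLOG10_CAP:
        return "Inf"
    return f"{result.neglog10p:.{digits}f}"


def associate(
    rank: FCRanking,
    variants: Sequence[VariantRecord],
    cls: str,
    min_altered: int = 3,
    ks_mode: str = "auto",
) -> AssociationResult:
    """KS comparison of altered vs unaltered gene ranks for one class.

    Altered genes are those in the ranking carrying at least one variant of
    class ``cls`` in this sample (gene-level collapse; variants without a
    gene assignment or intergenic are ignored).  Cells with fewer than
    ``min_altered`` altered genes are returned as not-tested.
    """
    if cls not in MUTATION_CLASSES:
        raise UsageError(f"unknown mutation class {cls!r}")
    ranked_genes = set(rank.table.index)
    altered = {
        v.gene
        for v in variants
        if v.gene is not None
        and v.func_region != "intergenic"
        and v.gene in ranked_genes
        and mutation_class_membership(v, cls)
    }
    n_alt = len(altered)
    n_unalt = rank.n_genes - n_alt
    if n_alt == 0:
        return AssociationResult.not_tested(rank.tumour_sample, cls, 0, n_unalt)
    if n_unalt == 0:
        raise UsageError(
            f"every ranked gene is altered for class {cls} in {rank.tumour_sample}; no comparison group"
        )
    if n_alt < min_altered:
        return AssociationResult.not_tested(rank.tumour_sample, cls, n_alt, n_unalt)

    all_ranks = rank.table["rank"]
    alt_ranks = all_ranks.loc[sorted(altered)].to_numpy(dtype=float)
    unalt_ranks = all_ranks.drop(index=sorted(altered)).to_numpy(dtype=float)
    d, p = ks_two_sample(alt_ranks, unalt_ranks, mode=ks_mode)
    neglog = math.inf if p == 0 else -math.log10(p)
    return AssociationResult(
        sample_id=rank.tumour_sample,
        mutation_class=cls,
        n_altered=n_alt,
        n_unaltered=n_unalt,
        D=d,
        p=p,
        neglog10p=neglog,
        significant=p < 0.05,
        tested=True,
    )


@dataclass(slots=True)
class AssociationMatrix:
    """Samples x classes grid of AssociationResult cells (the table object)."""

    samples: list[str]
    classes: list[str]
    cells: dict[tuple[str, str], AssociationResult]

    def result(self, sample: str, cls: str) -> AssociationResult:
        return self.cells[(sample, cls)]

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            for c in self.classes:
                r = self.cells[(s, c)]
                rows.append(
                    {
                        "sample_id": s,
                        "mutation_class": c,
                        "n_altered": r.n_altered,
                        "n_unaltered": r.n_unaltered,
                        "D": r.D,
                        "p_value": r.p,
                        "neglog10_p": r.neglog10p,
                        "significant": r.significant,
                        "tested": r.tested,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "sample_id",
                "mutation_class",
                "n_altered",
                "n_unaltered",
                "D",
                "p_value",
                "neglog10_p",
                "significant",
                "tested",
            ],
        )

    def to_wide_frame(self, digits: int = 2) -> pd.DataFrame:
        """Classes as rows, samples as columns, formatted -log10 p strings."""
        data = {
            s: [format_neglog10p(self.cells[(s, c)], digits) for c in self.classes]
            for s in self.samples
        }
        return pd.DataFrame(data, index=pd.Index(self.classes, name="mutation_class"))


def build_association_matrix(
    rankings: Mapping[str, FCRanking],
    variants_by_sample: Mapping[str, Sequence[VariantRecord]],
    sample_order: Sequence[str],
    classes: Sequence[str] = MUTATION_CLASSES,
    min_altered: int = 3,
    ks_mode: str = "auto",
) -> AssociationMatrix:
    """One cell per (tumour sample, class).

    ``sample_order`` lists the tumour samples to include (QC-excluded samples
    are simply not listed).  A sample without a ranking yields a not-tested
    column with a warning rather than an error.
    """
    for c in classes:
        if c not in MUTATION_CLASSES:
            raise UsageError(f"unknown mutation class {c!r}")
    cells: dict[tuple[str, str], AssociationResult] = {}
    for s in sample_order:
        rank = rankings.get(s)
        if rank is None:
            logger.warning("no fold-change ranking for sample %s; column marked not-tested", s)
            for c in classes:
                cells[(s, c)] = AssociationResult.not_tested(s, c)
            continue
        variants = variants_by_sample.get(s, [])
        for c in classes:
            cells[(s, c)] = associate(rank, variants, c, min_altered=min_altered, ks_mode=ks_mode)
    return AssociationMatrix(samples=list(sample_order), classes=list(classes), cells=cells)
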