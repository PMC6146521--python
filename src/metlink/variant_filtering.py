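"""Somatic variant filter cascade, functional classification and spectrum summaries.

The cascade consumes tumour-vs-normal caller output (the matched normal is
already subtracted upstream) and applies, in order:

1. allele-fraction floor (SNVs only — indels bypass it),
2. removal of homozygous variants common in the reference exome panel,
3. read-depth and per-strand non-reference read floors,
4. removal of variants common (population AF above threshold) in any panel.

All four predicates are conjunctive, so the surviving set is order-invariant;
the per-stage log is not, and records the order above.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DataError, UsageError

__all__ = [
    "VariantRecord",
    "FilterConfig",
    "SpectrumSummary",
    "FilterStageLog",
    "passes_allele_fraction",
    "passes_depth_strand",
    "is_common_variant",
    "run_filter_cascade",
    "classify_substitution",
    "mutation_class_membership",
    "summarize_spectrum",
    "read_variant_table",
    "write_variant_table",
    "read_vcf_with_annotations",
    "MUTATION_CLASSES",
    "POP_AF_KEYS",
]

BASES = frozenset("ACGT")
POP_AF_KEYS = ("exac_all", "esp6500_all", "kg_all", "kg_eur")
FUNC_REGIONS = (
    "exonic",
    "intronic",
    "splicing",
    "UTR3",
    "UTR5",
    "upstream",
    "downstream",
    "intergenic",
)
EXONIC_FUNCS = (
    "nonsynonymous",
    "synonymous",
    "stopgain",
    "stoploss",
    "frameshift_indel",
    "nonframeshift_indel",
    "none",
)
VARIANT_TYPES = ("SNV", "insertion", "deletion", "substitution_block")
MUTATION_CLASSES = (
    "stopgain",
    "non_silent",
    "hom_non_silent",
    "silent_exonic",
    "indel_all",
)


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """One called somatic variant in one tumour sample, with evidence fields."""

    patient_id: str
    sample_id: str
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    variant_type: str
    depth: int
    alt_forward: int
    alt_reverse: int
    allele_fraction: float
    zygosity: str  # "het" | "hom_alt"
    gene: str | None
    func_region: str
    exonic_func: str
    pop_af: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variant_type not in VARIANT_TYPES:
            raise DataError(f"unknown variant_type {self.variant_type!r} at {self.key()}")
        if self.func_region not in FUNC_REGIONS:
            raise DataError(f"unknown func_region {self.func_region!r} at {self.key()}")
        if self.exonic_func not in EXONIC_FUNCS:
            raise DataError(f"unknown exonic_func {self.exonic_func!r} at {self.key()}")
        if self.zygosity not in ("het", "hom_alt"):
            raise DataError(f"unknown zygosity {self.zygosity!r} at {self.key()}")
        if self.depth is not None and self.alt_forward is not None and self.alt_reverse is not None:
            if self.alt_forward + self.alt_reverse > self.depth:
                raise DataError(f"alt reads exceed depth at {self.key()}")
        if self.allele_fraction is not None and not (0.0 <= self.allele_fraction <= 1.0):
            raise DataError(f"allele fraction outside [0,1] at {self.key()}")
        is_snv = len(self.ref) == 1 and len(self.alt) == 1 and self.ref in BASES and self.alt in BASES
        if (self.variant_type == "SNV") != is_snv:
            raise DataError(f"variant_type/allele mismatch at {self.key()}")

    def key(self) -> tuple[str, int, str, str]:
        """Variant identity used by all set algebra: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True, slots=True)
class FilterConfig:
    min_allele_fraction: float = 0.1
    min_depth: int = 20
    min_alt_per_strand: int = 4
    max_pop_af: float = 0.01
    common_hom_af: float = 0.5

    def __post_init__(self) -> None:
        for name in ("min_allele_fraction", "max_pop_af", "common_hom_af"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise UsageError(f"{name} must lie in [0,1], got {v}")
        for name in ("min_depth", "min_alt_per_strand"):
            if getattr(self, name) < 0:
                raise UsageError(f"{name} must be non-negative")


def passes_allele_fraction(v: VariantRecord, cfg: FilterConfig) -> bool:
    """Inclusive floor on tumour allele fraction (the min-var-frac rule).

    Applies to SNVs only; indels and block substitutions pass unconditionally.
    """
    if v.variant_type != "SNV":
        return True
    if v.allele_fraction is None or (isinstance(v.allele_fraction, float) and math.isnan(v.allele_fraction)):
        raise DataError(f"missing allele_fraction for variant {v.key()} in {v.sample_id}")
    return v.allele_fraction >= cfg.min_allele_fraction


def passes_depth_strand(v: VariantRecord, cfg: FilterConfig) -> bool:
    """Inclusive floors: site depth and non-reference reads on each strand."""
    for name in ("depth", "alt_forward", "alt_reverse"):
        val = getattr(v, name)
        if val is None or (isinstance(val, float) and math.isnan(val)):
            raise DataError(f"missing {name} for variant {v.key()} in {v.sample_id}")
    return (
        v.depth >= cfg.min_depth
        and v.alt_forward >= cfg.min_alt_per_strand
        and v.alt_reverse >= cfg.min_alt_per_strand
    )


def _pop_af(v: VariantRecord, key: str) -> float:
    """Population AF with absence treated as 0 (absence is not commonness)."""
    val = v.pop_af.get(key) if v.pop_af else None
    if val is None or (isinstance(val, float) and math.isnan(val)):
        return 0.0
    return float(val)


def is_common_variant(v: VariantRecord, cfg: FilterConfig) -> bool:
    """True iff the variant is common in any population panel.

    Strict inequalities: AF strictly above ``max_pop_af`` in any of the four
    panels, or a homozygous call strictly above ``common_hom_af`` in ExAC.
    """
    if any(_pop_af(v, k) > cfg.max_pop_af for k in POP_AF_KEYS):
        return True
    return v.zygosity == "hom_alt" and _pop_af(v, "exac_all") > cfg.common_hom_af


def _is_common_hom(v: VariantRecord, cfg: FilterConfig) -> bool:
    return v.zygosity == "hom_alt" and _pop_af(v, "exac_all") > cfg.common_hom_af


@dataclass(slots=True)
class FilterStageLog:
    input: int = 0
    af_pass: int = 0
    hom_common_removed: int = 0
    depth_strand_pass: int = 0
    pop_pass: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "input": self.input,
            "af_pass": self.af_pass,
            "hom_common_removed": self.hom_common_removed,
            "depth_strand_pass": self.depth_strand_pass,
            "pop_pass": self.pop_pass,
        }


def run_filter_cascade(
    variants: Iterable[VariantRecord], cfg: FilterConfig | None = None
) -> tuple[list[VariantRecord], FilterStageLog]:
    """Apply the four-stage cascade; returns survivors (order preserved) and the stage log."""
    cfg = cfg or FilterConfig()
    records = list(variants)
    log = FilterStageLog(input=len(records))

    stage1 = [v for v in records if passes_allele_fraction(v, cfg)]
    log.af_pass = len(stage1)

    stage2 = [v for v in stage1 if not _is_common_hom(v, cfg)]
    log.hom_common_removed = len(stage1) - len(stage2)

    stage3 = [v for v in stage2 if passes_depth_strand(v, cfg)]
    log.depth_strand_pass = len(stage3)

    stage4 = [v for v in stage3 if not any(_pop_af(v, k) > cfg.max_pop_af for k in POP_AF_KEYS)]
    log.pop_pass = len(stage4)

    return stage4, log


_TRANSITIONS = frozenset({frozenset("AG"), frozenset("CT")})


def classify_substitution(ref: str, alt: str) -> tuple[str, str]:
    """Classify a single-base substitution.

    Returns ``(pair_class, change_class)`` with pair_class in {"CG", "AT"}
    (which Watson-Crick pair the reference base belongs to) and change_class
    in {"transition", "transversion"}.
    """
    if ref not in BASES or alt not in BASES or ref == alt:
        raise UsageError(f"not a single-base substitution: {ref}>{alt}")
    pair = "CG" if ref in "CG" else "AT"
    change = "transition" if frozenset((ref, alt)) in _TRANSITIONS else "transversion"
    return pair, change


def mutation_class_membership(v: VariantRecord, cls: str) -> bool:
    """Membership in one of the five analysis classes.

    non_silent covers protein-altering changes (nonsynonymous, stopgain,
    stoploss, frameshift indels) plus splicing-region variants; nonframeshift
    indels are excluded.
    """
    if cls == "stopgain":
        return v.exonic_func == "stopgain"
    if cls == "non_silent":
        return (
            v.exonic_func in ("nonsynonymous", "stopgain", "stoploss", "frameshift_indel")
            or v.func_region == "splicing"
        )
    if cls == "hom_non_silent":
        return mutation_class_membership(v, "non_silent") and v.zygosity == "hom_alt"
    if cls == "silent_exonic":
        return v.exonic_func == "synonymous"
    if cls == "indel_all":
        return v.variant_type in ("insertion", "deletion")
    raise UsageError(f"unknown mutation class {cls!r}")


@dataclass(slots=True)
class SpectrumSummary:
    substitution_counts: dict[str, int]
    transitions: int
    transversions: int
    cg_pair_mutations: int
    at_pair_mutations: int
    func_region_fractions: dict[str, float]
    exonic_func_fractions: dict[str, float]
    n_variants: int
    n_snvs: int

    def as_dict(self) -> dict:
        return {
            "n_variants": self.n_variants,
            "n_snvs": self.n_snvs,
            "substitution_counts": dict(self.substitution_counts),
            "transitions": self.transitions,
            "transversions": self.transversions,
            "cg_pair_mutations": self.cg_pair_mutations,
            "at_pair_mutations": self.at_pair_mutations,
            "func_region_fractions": dict(self.func_region_fractions),
            "exonic_func_fractions": dict(self.exonic_func_fractions),
        }


def summarize_spectrum(variants: Iterable[VariantRecord]) -> SpectrumSummary:
    """Count the 12 substitution types, Ts/Tv and pair-class totals, and
    functional-region / exonic-consequence fractions.

    func_region fractions are over all variants; exonic_func fractions are
    over exonic variants only.  Fractions are NaN for an empty denominator.
    """
    records = list(variants)
    subs: Counter[str] = Counter()
    ts = tv = cg = at = 0
    region: Counter[str] = Counter()
    exonic: Counter[str] = Counter()
    n_snv = 0
    for v in records:
        region[v.func_region] += 1
        if v.func_region == "exonic":
            exonic[v.exonic_func] += 1
        if v.variant_type == "SNV":
            n_snv += 1
            subs[f"{v.ref}>{v.alt}"] += 1
            pair, change = classify_substitution(v.ref, v.alt)
            if change == "transition":
                ts += 1
            else:
                tv += 1
            if pair == "CG":
                cg += 1
            else:
                at += 1
    n = len(records)
    n_ex = sum(exonic.values())
    region_frac = {k: (region[k] / n if n else math.nan) for k in FUNC_REGIONS}
    exonic_frac = {k: (exonic[k] / n_ex if n_ex else math.nan) for k in EXONIC_FUNCS if k != "none"}
    return SpectrumSummary(
        substitution_counts={f"{r}>{a}": subs[f"{r}>{a}"] for r in "ACGT" for a in "ACGT" if r != a},
        transitions=ts,
        transversions=tv,
        cg_pair_mutations=cg,
        at_pair_mutations=at,
        func_region_fractions=region_frac,
        exonic_func_fractions=exonic_frac,
        n_variants=n,
        n_snvs=n_snv,
    )


# ---------------------------------------------------------------------------
# I/O: flat TSV round-trip and VCF + annotation-table ingestion
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "patient_id",
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_type",
    "depth",
    "alt_forward",
    "alt_reverse",
    "allele_fraction",
    "zygosity",
    "gene",
    "func_region",
    "exonic_func",
    "exac_all",
    "esp6500_all",
    "kg_all",
    "kg_eur",
]


def write_variant_table(variants: Sequence[VariantRecord], path: str | Path) -> None:
    rows = []
    for v in variants:
        row = {
            "patient_id": v.patient_id,
            "sample_id": v.sample_id,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "variant_type": v.variant_type,
            "depth": v.depth,
            "alt_forward": v.alt_forward,
            "alt_reverse": v.alt_reverse,
            "allele_fraction": repr(float(v.allele_fraction)),
            "zygosity": v.zygosity,
            "gene": v.gene if v.gene is not None else "",
            "func_region": v.func_region,
            "exonic_func": v.exonic_func,
        }
        for k in POP_AF_KEYS:
            val = v.pop_af.get(k)
            row[k] = "" if val is None else repr(float(val))
        rows.append(row)
    df = pd.DataFrame(rows, columns=_TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"variant table {path} lacks columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        pop = {}
        for k in POP_AF_KEYS:
            raw = getattr(row, k)
            if raw != "":
                pop[k] = float(raw)
        out.append(
            VariantRecord(
                patient_id=row.patient_id,
                sample_id=row.sample_id,
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                variant_type=row.variant_type,
                depth=int(row.depth),
                alt_forward=int(row.alt_forward),
                alt_reverse=int(row.alt_reverse),
                allele_fraction=float(row.allele_fraction),
                zygosity=row.zygosity,
                gene=row.gene if row.gene != "" else None,
                func_region=row.func_region,
                exonic_func=row.exonic_func,
                pop_af=pop,
            )
        )
    return out


def _variant_type_from_alleles(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(ref) < len(alt):
        return "insertion"
    if len(ref) > len(alt):
        return "deletion"
    return "substitution_block"


def read_vcf_with_annotations(
    vcf_path: str | Path,
    annotations: pd.DataFrame,
    sample_id: str,
    patient_id: str,
) -> list[VariantRecord]:
    """Read one per-sample VCF and join per-identity annotation rows.

    The annotation frame is indexed by (chrom, pos, ref, alt) and carries
    gene, func_region, exonic_func and the four population-AF columns.
    Allele fraction is derived from ADF+ADR over DP so that integer evidence
    round-trips exactly; the AF_TUM INFO field is used only as a fallback.
    """
    import pysam

    out = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            ref = rec.ref
            alt = rec.alts[0]
            key = (rec.chrom, rec.pos, ref, alt)
            try:
                ann = annotations.loc[key]
            except KeyError as exc:
                raise DataError(f"no annotation row for variant {key}") from exc
            depth = int(rec.info["DP"])
            adf = int(rec.info["ADF"])
            adr = int(rec.info["ADR"])
            if depth > 0:
                af = (adf + adr) / depth
            else:
                af = float(rec.info.get("AF_TUM", 0.0))
            gt = rec.samples[0]["GT"]
            zyg = "hom_alt" if gt == (1, 1) else "het"
            pop = {}
            for k in POP_AF_KEYS:
                val = ann[k]
                if val != "" and not (isinstance(val, float) and math.isnan(val)):
                    pop[k] = float(val)
            gene = ann["gene"]
            if gene == "" or (isinstance(gene, float) and math.isnan(gene)):
                gene = None
            out.append(
                VariantRecord(
                    patient_id=patient_id,
                    sample_id=sample_id,
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=ref,
                    alt=alt,
                    variant_type=_variant_type_from_alleles(ref, alt),
                    depth=depth,
                    alt_forward=adf,
                    alt_reverse=adr,
                    allele_fraction=af,
                    zygosity=zyg,
                    gene=gene,
                    func_region=ann["func_region"],
                    exonic_func=ann["exonic_func"],
                    pop_af=pop,
                )
            )
    return out
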