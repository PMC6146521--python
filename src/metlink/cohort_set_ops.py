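"""Multi-sample set algebra on filtered variant sets.

Variant identity throughout is (chrom, pos, ref, alt) — genotype is
deliberately not part of the identity, so a site that is het in a primary
region and hom in the metastasis still counts as detected in the primary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DataError
from .variant_filtering import VariantRecord

__all__ = [
    "VariantKey",
    "PatientSampleSet",
    "RecurrenceTable",
    "derive_emv",
    "cross_patient_recurrence",
    "gene_mutation_rates",
    "build_patient_sets",
]

logger = logging.getLogger(__name__)

VariantKey = tuple[str, int, str, str]


@dataclass(slots=True)
class PatientSampleSet:
    """One patient's normal / primary-region / metastasis grouping with
    per-sample filtered variant sets keyed by variant identity."""

    patient_id: str
    normal_sample: str
    pt_samples: list[str]
    mt_sample: str
    variant_sets: dict[str, set[VariantKey]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pt_samples:
            raise DataError(f"patient {self.patient_id} has no primary-tumour samples")
        if not self.mt_sample:
            raise DataError(f"patient {self.patient_id} has no metastasis sample")

    def mt_set(self) -> set[VariantKey]:
        return self.variant_sets.get(self.mt_sample, set())

    def pt_union(self) -> set[VariantKey]:
        u: set[VariantKey] = set()
        for s in self.pt_samples:
            u |= self.variant_sets.get(s, set())
        return u


def derive_emv(p: PatientSampleSet) -> set[VariantKey]:
    """Exclusive metastatic variants: the metastasis set minus the union of
    all primary-region sets of the same patient (normal is excluded upstream
    by somatic calling)."""
    if p.mt_sample not in p.variant_sets:
        raise DataError(f"patient {p.patient_id}: no variant set for MT sample {p.mt_sample}")
    emv = p.mt_set() - p.pt_union()
    assert emv <= p.mt_set() and not (emv & p.pt_union())
    return emv


@dataclass(slots=True)
class RecurrenceTable:
    variant_patients: dict[VariantKey, int]
    gene_patients: dict[str, int]
    n_patients: int

    def variants_in_at_least(self, k: int) -> int:
        return sum(1 for n in self.variant_patients.values() if n >= k)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chrom": c, "pos": p, "ref": r, "alt": a, "n_patients": n}
            for (c, p, r, a), n in sorted(self.variant_patients.items())
        ]
        return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "n_patients"])


def cross_patient_recurrence(
    cohort: Sequence[PatientSampleSet],
    variants_by_sample: Mapping[str, Sequence[VariantRecord]] | None = None,
) -> RecurrenceTable:
    """Count, per variant identity and per gene, the number of distinct
    patients carrying it.  A variant found in several samples of one patient
    counts once for that patient.

    Gene counts need the full records (for the gene column) and are empty
    when ``variants_by_sample`` is not given.
    """
    if not cohort:
        raise DataError("recurrence requires at least one patient")
    seen_ids = [p.patient_id for p in cohort]
    if len(set(seen_ids)) != len(seen_ids):
        raise DataError("duplicate patient_id in cohort")

    variant_patients: dict[VariantKey, set[str]] = {}
    gene_patients: dict[str, set[str]] = {}
    for p in cohort:
        union: set[VariantKey] = set()
        for s in p.variant_sets.values():
            union |= s
        for key in union:
            variant_patients.setdefault(key, set()).add(p.patient_id)
        if variants_by_sample is not None:
            genes = {
                v.gene
                for sample in [*p.pt_samples, p.mt_sample]
                for v in variants_by_sample.get(sample, [])
                if v.gene is not None
            }
            for g in genes:
                gene_patients.setdefault(g, set()).add(p.patient_id)

    n_pat = len(cohort)
    table = RecurrenceTable(
        variant_patients={k: len(v) for k, v in variant_patients.items()},
        gene_patients={g: len(v) for g, v in gene_patients.items()},
        n_patients=n_pat,
    )
    assert all(n <= n_pat for n in table.variant_patients.values())
    return table


def gene_mutation_rates(
    variants: Iterable[VariantRecord], gene_lengths: Mapping[str, float]
) -> pd.DataFrame:
    """Distinct-variant count per gene divided by gene length, in events per
    kilobase.  Genes absent from the length table are skipped with a warning.
    Output is sorted by descending rate, ties broken lexicographically."""
    per_gene: dict[str, set[VariantKey]] = {}
    for v in variants:
        if v.gene is None:
            continue
        per_gene.setdefault(v.gene, set()).add(v.key())

    rows = []
    for gene in sorted(set(per_gene) | set(gene_lengths)):
        if gene not in gene_lengths:
            logger.warning("gene %s has variants but no length entry; skipped", gene)
            continue
        length = float(gene_lengths[gene])
        if length <= 0:
            raise DataError(f"non-positive length for gene {gene}")
        count = len(per_gene.get(gene, ()))
        rows.append({"gene": gene, "n_variants": count, "length_bp": length, "rate_per_kb": count / length * 1000.0})
    df = pd.DataFrame(rows, columns=["gene", "n_variants", "length_bp", "rate_per_kb"])
    if len(df):
        df = df.sort_values(["rate_per_kb", "gene"], ascending=[False, True], kind="mergesort")
        df = df.reset_index(drop=True)
    return df


def build_patient_sets(
    sample_sheet: pd.DataFrame, variants_by_sample: Mapping[str, Sequence[VariantRecord]]
) -> list[PatientSampleSet]:
    """Assemble PatientSampleSet objects from a sample sheet
    (sample_id, patient_id, role in {N, PT, MT}, region_index) and per-sample
    filtered variant records."""
    patients = []
    for patient_id, grp in sample_sheet.groupby("patient_id", sort=True):
        normals = grp.loc[grp["role"] == "N", "sample_id"].tolist()
        mts = grp.loc[grp["role"] == "MT", "sample_id"].tolist()
        pts_frame = grp.loc[grp["role"] == "PT", ["sample_id", "region_index"]]
        pts = pts_frame.sort_values("region_index")["sample_id"].tolist()
        if len(normals) != 1 or len(mts) != 1:
            raise DataError(
                f"patient {patient_id} must have exactly one normal and one MT sample"
            )
        sets = {
            s: {v.key() for v in variants_by_sample.get(s, [])} for s in [*pts, mts[0]]
        }
        patients.append(
            PatientSampleSet(
                patient_id=str(patient_id),
                normal_sample=normals[0],
                pt_samples=pts,
                mt_sample=mts[0],
                variant_sets=sets,
            )
        )
    return patients
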