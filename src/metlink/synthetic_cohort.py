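"""Synthetic matched-cohort generator.

Produces per-sample somatic variant tables, identity-level annotations with
population allele frequencies, and a negative-binomial expression matrix with
a tunable coupling between a gene's non-silent mutation status in a tumour
sample and its tumour/normal fold change.  Every draw flows from one seeded
generator, so identical (config, seed) gives byte-identical fixtures.

Cohort structure per patient: one normal, ``pt_regions`` primary-tumour
regions and one metastasis.  Each tumour sample carries a shared "trunk" set
plus sample-private variants; the metastasis-private ones are the true
exclusive metastatic variants recorded in the truth object.  Common variants
(population AF above 1%) are injected on top at a configurable rate and are
expected to be removed by the filter cascade.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .variant_filtering import (
    POP_AF_KEYS,
    VariantRecord,
    mutation_class_membership,
    read_vcf_with_annotations,
)

__all__ = [
    "CohortConfig",
    "SimTruth",
    "SimulatedCohort",
    "LoadedCohort",
    "simulate_variant_tables",
    "simulate_counts",
    "simulate_cohort",
    "write_fixtures",
    "load_fixtures",
    "DEFAULT_SPECTRUM_WEIGHTS",
    "DEFAULT_FUNCTIONAL_MIX",
]

BURDEN_INTERVALS = {"low": (54, 306), "high": (1490, 3029)}

SUBSTITUTION_TYPES = tuple(f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a)

# C:G-pair mutations 9x A:T-pair, transversions 3x transitions, independent,
# mass split equally within each (pair, change) cell.
DEFAULT_SPECTRUM_WEIGHTS: dict[str, float] = {
    "C>T": 0.1125, "G>A": 0.1125,                                     # CG transitions
    "C>A": 0.16875, "C>G": 0.16875, "G>C": 0.16875, "G>T": 0.16875,   # CG transversions
    "A>G": 0.0125, "T>C": 0.0125,                                     # AT transitions
    "A>C": 0.01875, "A>T": 0.01875, "T>A": 0.01875, "T>G": 0.01875,   # AT transversions
}

FUNCTIONAL_CLASSES = (
    "nonsynonymous",
    "synonymous",
    "stopgain",
    "stoploss",
    "frameshift_indel",
    "nonframeshift_indel",
    "intronic",
    "UTR3",
    "UTR5",
    "intergenic",
    "splicing",
)

DEFAULT_FUNCTIONAL_MIX: dict[str, float] = {
    "nonsynonymous": 0.29,
    "synonymous": 0.114,
    "stopgain": 0.026,
    "stoploss": 0.004,
    "frameshift_indel": 0.020,
    "nonframeshift_indel": 0.016,
    "splicing": 0.010,
    "intronic": 0.145,
    "UTR3": 0.116,
    "UTR5": 0.050,
    "intergenic": 0.209,
}

# (weight, alpha, beta) Beta-mixture for true allele fraction:
# clonal het, subclonal, and a small homozygous component.
DEFAULT_AF_MODEL: tuple[tuple[float, float, float], ...] = (
    (0.55, 20.0, 20.0),
    (0.35, 8.0, 24.0),
    (0.10, 45.0, 3.0),
)

TRUTH_FORMAT_VERSION = 1


def _check_probs(name: str, probs: Mapping[str, float], keys: Sequence[str]) -> None:
    if set(probs) != set(keys):
        raise ConfigError(f"{name} must have exactly the keys {sorted(keys)}")
    if any(p < 0 for p in probs.values()):
        raise ConfigError(f"{name} has negative entries")
    if abs(sum(probs.values()) - 1.0) > 1e-12:
        raise ConfigError(f"{name} must sum to 1 within 1e-12")


@dataclass
class CohortConfig:
    n_patients: int = 7
    pt_regions_per_patient: int | tuple[int, ...] = 3
    n_genes: int = 2000
    burden_regimes: str | tuple[str, ...] = "low"
    burden_intervals: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {k: v for k, v in BURDEN_INTERVALS.items()}
    )
    emv_fraction: float = 0.3
    spectrum_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECTRUM_WEIGHTS)
    )
    functional_class_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FUNCTIONAL_MIX)
    )
    depth_mean: float = 100.0
    depth_dispersion: float = 0.1
    strand_split: float = 0.5
    allele_fraction_model: tuple[tuple[float, float, float], ...] = DEFAULT_AF_MODEL
    common_variant_rate: float = 0.05
    coupling_delta: float = 0.0
    coupling_fraction: float = 0.5
    nb_dispersion: float = 0.05
    patient_effect_sd: float = 0.15
    library_factor_sd: float = 0.2
    expression_mean_log: float = 5.0
    expression_mean_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be non-negative")
        if self.n_genes < 10:
            raise ConfigError("n_genes must be at least 10")
        for r in self.regions_per_patient():
            if not (1 <= r <= 6):
                raise ConfigError("pt_regions_per_patient must lie in [1, 6]")
        for reg in self.regimes_per_patient():
            if reg not in self.burden_intervals:
                raise ConfigError(f"unknown burden regime {reg!r}")
        for reg, (lo, hi) in self.burden_intervals.items():
            if not (1 <= lo <= hi):
                raise ConfigError(f"invalid burden interval for regime {reg!r}")
        _check_probs("spectrum_weights", self.spectrum_weights, SUBSTITUTION_TYPES)
        _check_probs("functional_class_mix", self.functional_class_mix, FUNCTIONAL_CLASSES)
        w = sum(c[0] for c in self.allele_fraction_model)
        if abs(w - 1.0) > 1e-12:
            raise ConfigError("allele_fraction_model weights must sum to 1")
        for name in ("emv_fraction", "common_variant_rate", "coupling_fraction", "strand_split"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0,1]")
        for name in ("depth_mean", "depth_dispersion", "nb_dispersion", "patient_effect_sd", "library_factor_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")

    def regions_per_patient(self) -> tuple[int, ...]:
        if isinstance(self.pt_regions_per_patient, int):
            return (self.pt_regions_per_patient,) * self.n_patients
        regs = tuple(self.pt_regions_per_patient)
        if len(regs) != self.n_patients:
            raise ConfigError("pt_regions_per_patient list must match n_patients")
        return regs

    def regimes_per_patient(self) -> tuple[str, ...]:
        if isinstance(self.burden_regimes, str):
            return (self.burden_regimes,) * self.n_patients
        regimes = tuple(self.burden_regimes)
        if len(regimes) != self.n_patients:
            raise ConfigError("burden_regimes list must match n_patients")
        return regimes

    def gene_names(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"gene{i:0{width}d}" for i in range(1, self.n_genes + 1)]


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort."""

    sample_sheet: pd.DataFrame
    variants_by_sample: dict[str, list[VariantRecord]]
    emv_by_patient: dict[str, set[tuple[str, int, str, str]]]
    coupling_shifts: dict[str, dict[str, float]]
    library_factors: dict[str, float]
    patient_effects: dict[str, float]
    gene_lengths: pd.Series
    seed: int


@dataclass
class SimulatedCohort:
    config: CohortConfig
    truth: SimTruth
    variants_by_sample: dict[str, list[VariantRecord]]
    counts: "pd.DataFrame | None" = None


@dataclass
class LoadedCohort:
    sample_sheet: pd.DataFrame
    variants_by_sample: dict[str, list[VariantRecord]]
    counts: pd.DataFrame
    gene_lengths: pd.Series


@dataclass(frozen=True)
class _Template:
    """Sample-independent part of a variant (identity + annotation)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_type: str
    gene: str | None
    func_region: str
    exonic_func: str
    pop_af: tuple[tuple[str, float], ...]


_CLASS_TO_ANNOTATION = {
    "nonsynonymous": ("exonic", "nonsynonymous"),
    "synonymous": ("exonic", "synonymous"),
    "stopgain": ("exonic", "stopgain"),
    "stoploss": ("exonic", "stoploss"),
    "frameshift_indel": ("exonic", "frameshift_indel"),
    "nonframeshift_indel": ("exonic", "nonframeshift_indel"),
    "intronic": ("intronic", "none"),
    "UTR3": ("UTR3", "none"),
    "UTR5": ("UTR5", "none"),
    "intergenic": ("intergenic", "none"),
    "splicing": ("splicing", "none"),
}


class _VariantFactory:
    def __init__(self, config: CohortConfig, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        self.genes = config.gene_names()
        self.pos_counter = 0
        self.sub_types = list(SUBSTITUTION_TYPES)
        self.sub_probs = np.array([config.spectrum_weights[t] for t in SUBSTITUTION_TYPES])
        self.classes = list(FUNCTIONAL_CLASSES)
        self.class_probs = np.array([config.functional_class_mix[c] for c in FUNCTIONAL_CLASSES])
        self.af_weights = np.array([c[0] for c in config.allele_fraction_model])

    def _alleles(self, func_class: str) -> tuple[str, str, str]:
        rng = self.rng
        if func_class in ("frameshift_indel", "nonframeshift_indel"):
            size = int(rng.choice([1, 2]) if func_class == "frameshift_indel" else 3)
            anchor = str(rng.choice(list("ACGT")))
            extra = "".join(rng.choice(list("ACGT"), size=size))
            if rng.random() < 0.5:
                return anchor, anchor + extra, "insertion"
            return anchor + extra, anchor, "deletion"
        sub = self.sub_types[int(rng.choice(len(self.sub_types), p=self.sub_probs))]
        ref, alt = sub.split(">")
        return ref, alt, "SNV"

    def make_template(self, common: bool) -> _Template:
        rng = self.rng
        func_class = self.classes[int(rng.choice(len(self.classes), p=self.class_probs))]
        func_region, exonic_func = _CLASS_TO_ANNOTATION[func_class]
        ref, alt, vtype = self._alleles(func_class)
        gene = None if func_region == "intergenic" else str(rng.choice(self.genes))
        self.pos_counter += 1 + int(rng.integers(0, 100))
        pop: list[tuple[str, float]] = []
        if common:
            pop.append(("exac_all", float(rng.uniform(0.011, 0.5))))
            if rng.random() < 0.5:
                pop.append(("kg_all", float(rng.uniform(0.011, 0.5))))
        else:
            # mostly absent from panels; occasionally annotated but rare
            for key in POP_AF_KEYS:
                if rng.random() < 0.15:
                    pop.append((key, float(rng.uniform(0.0, 0.009))))
        return _Template(
            chrom="chrS",
            pos=self.pos_counter,
            ref=ref,
            alt=alt,
            variant_type=vtype,
            gene=gene,
            func_region=func_region,
            exonic_func=exonic_func,
            pop_af=tuple(pop),
        )

    def instantiate(self, t: _Template, patient_id: str, sample_id: str) -> VariantRecord:
        rng = self.rng
        disp = self.cfg.depth_dispersion
        if disp > 0:
            r = 1.0 / disp
            depth = int(rng.negative_binomial(r, r / (r + self.cfg.depth_mean)))
        else:
            depth = int(rng.poisson(self.cfg.depth_mean))
        depth = max(depth, 1)
        comp = int(rng.choice(len(self.af_weights), p=self.af_weights))
        _, a, b = self.cfg.allele_fraction_model[comp]
        af_true = float(rng.beta(a, b))
        alt_total = int(rng.binomial(depth, af_true))
        alt_fwd = int(rng.binomial(alt_total, self.cfg.strand_split))
        alt_rev = alt_total - alt_fwd
        af = alt_total / depth
        return VariantRecord(
            patient_id=patient_id,
            sample_id=sample_id,
            chrom=t.chrom,
            pos=t.pos,
            ref=t.ref,
            alt=t.alt,
            variant_type=t.variant_type,
            depth=depth,
            alt_forward=alt_fwd,
            alt_reverse=alt_rev,
            allele_fraction=af,
            zygosity="hom_alt" if af > 0.8 else "het",
            gene=t.gene,
            func_region=t.func_region,
            exonic_func=t.exonic_func,
            pop_af=dict(t.pop_af),
        )


def simulate_variant_tables(
    config: CohortConfig,
) -> tuple[dict[str, list[VariantRecord]], SimTruth]:
    """Generate per-sample variant tables and the cohort truth record.

    Each tumour sample of a patient receives the same target variant count
    (drawn from the patient's burden-regime interval): a trunk shared by all
    tumour samples plus sample-private variants; the metastasis-private ones
    are the true EMVs.  Common variants are added on top so that they make up
    ``common_variant_rate`` of each sample's injected variants.
    """
    rng = np.random.default_rng([config.seed, 1])
    factory = _VariantFactory(config, rng)

    sheet_rows = []
    variants_by_sample: dict[str, list[VariantRecord]] = {}
    emv_by_patient: dict[str, set[tuple[str, int, str, str]]] = {}
    regions = config.regions_per_patient()
    regimes = config.regimes_per_patient()

    for i in range(config.n_patients):
        patient_id = f"P{i + 1:02d}"
        n_regions = regions[i]
        lo, hi = config.burden_intervals[regimes[i]]
        target = int(rng.integers(lo, hi + 1))
        n_private = int(round(config.emv_fraction * target))
        n_trunk = target - n_private
        rate = config.common_variant_rate
        n_common = int(round(target * rate / (1.0 - rate))) if rate < 1.0 else target

        normal_id = f"{patient_id}.N"
        mt_id = f"{patient_id}.MT"
        pt_ids = [f"{patient_id}.PT{r}" for r in range(1, n_regions + 1)]
        sheet_rows.append((normal_id, patient_id, "N", 0))
        for r, s in enumerate(pt_ids, start=1):
            sheet_rows.append((s, patient_id, "PT", r))
        sheet_rows.append((mt_id, patient_id, "MT", 0))

        trunk = [factory.make_template(common=False) for _ in range(n_trunk)]
        emv_templates = [factory.make_template(common=False) for _ in range(n_private)]
        private_by_pt = {
            s: [factory.make_template(common=False) for _ in range(n_private)] for s in pt_ids
        }
        commons = [factory.make_template(common=True) for _ in range(n_common)]

        emv_by_patient[patient_id] = {
            (t.chrom, t.pos, t.ref, t.alt) for t in emv_templates
        }

        for s in pt_ids:
            templates = trunk + private_by_pt[s] + commons
            templates.sort(key=lambda t: t.pos)
            variants_by_sample[s] = [
                factory.instantiate(t, patient_id, s) for t in templates
            ]
        mt_templates = trunk + emv_templates + commons
        mt_templates.sort(key=lambda t: t.pos)
        variants_by_sample[mt_id] = [
            factory.instantiate(t, patient_id, mt_id) for t in mt_templates
        ]

    sample_sheet = pd.DataFrame(
        sheet_rows, columns=["sample_id", "patient_id", "role", "region_index"]
    )
    lengths = pd.Series(
        rng.integers(500, 5001, size=config.n_genes).astype(float),
        index=pd.Index(config.gene_names(), name="gene"),
        name="length_bp",
    )
    truth = SimTruth(
        sample_sheet=sample_sheet,
        variants_by_sample=variants_by_sample,
        emv_by_patient=emv_by_patient,
        coupling_shifts={},
        library_factors={},
        patient_effects={},
        gene_lengths=lengths,
        seed=config.seed,
    )
    return variants_by_sample, truth


def simulate_counts(truth: SimTruth, config: CohortConfig) -> pd.DataFrame:
    """Negative-binomial gene x sample count matrix.

    For each tumour sample, genes carrying a non-silent injected mutation and
    selected with probability ``coupling_fraction`` get their expected
    log2 tumour/normal ratio shifted by ``coupling_delta``; the selection and
    library-size factors are written back into the truth record.
    """
    rng = np.random.default_rng([config.seed, 2])
    genes = config.gene_names()
    gene_index = {g: k for k, g in enumerate(genes)}
    base_mean = np.exp(rng.normal(config.expression_mean_log, config.expression_mean_sd, size=config.n_genes))

    sheet = truth.sample_sheet
    patient_ids = list(dict.fromkeys(sheet["patient_id"]))
    patient_eff = {
        p: float(np.exp(rng.normal(0.0, config.patient_effect_sd))) for p in patient_ids
    }
    lib = {
        s: float(np.exp(rng.normal(0.0, config.library_factor_sd)))
        for s in sheet["sample_id"]
    }
    truth.patient_effects = patient_eff
    truth.library_factors = lib

    shifts: dict[str, dict[str, float]] = {}
    cols = {}
    for row in sheet.itertuples(index=False):
        s, p, role = row.sample_id, row.patient_id, row.role
        log2_shift = np.zeros(config.n_genes)
        if role in ("PT", "MT"):
            mutated = sorted(
                {
                    v.gene
                    for v in truth.variants_by_sample.get(s, [])
                    if v.gene is not None and mutation_class_membership(v, "non_silent")
                }
            )
            chosen = {}
            for g in mutated:
                if rng.random() < config.coupling_fraction:
                    log2_shift[gene_index[g]] = config.coupling_delta
                    chosen[g] = config.coupling_delta
            shifts[s] = chosen
        mu = base_mean * patient_eff[p] * lib[s] * np.exp2(log2_shift)
        if config.nb_dispersion > 0:
            r = 1.0 / config.nb_dispersion
            cols[s] = rng.negative_binomial(r, r / (r + mu))
        else:
            cols[s] = rng.poisson(mu)
    truth.coupling_shifts = shifts
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    return counts


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Full simulation: variant tables, truth record and count matrix."""
    variants, truth = simulate_variant_tables(config)
    counts = simulate_counts(truth, config)
    return SimulatedCohort(config=config, truth=truth, variants_by_sample=variants, counts=counts)


# ---------------------------------------------------------------------------
# Fixture writing / loading
# ---------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chrS>
##INFO=<ID=DP,Number=1,Type=Integer,Description="High quality read depth">
##INFO=<ID=ADF,Number=1,Type=Integer,Description="Non-reference reads, forward strand">
##INFO=<ID=ADR,Number=1,Type=Integer,Description="Non-reference reads, reverse strand">
##INFO=<ID=AF_TUM,Number=1,Type=Float,Description="Tumour allele fraction">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def _write_vcf(variants: Sequence[VariantRecord], sample_id: str, path: Path) -> None:
    lines = [_VCF_HEADER]
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n")
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        gt = "1/1" if v.zygosity == "hom_alt" else "0/1"
        info = f"DP={v.depth};ADF={v.alt_forward};ADR={v.alt_reverse};AF_TUM={v.allele_fraction:.6g}"
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\tGT\t{gt}\n"
        )
    path.write_text("".join(lines))


def write_fixtures(dataset: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a simulated cohort to plain-text fixtures.

    Writes one VCF per tumour sample, an identity-level annotation TSV, the
    raw counts TSV, the sample sheet, a gene-length table and the truth
    record; everything round-trips losslessly through :func:`load_fixtures`.
    """
    out = Path(out_dir)
    try:
        (out / "vcf").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DataError(f"cannot create fixture directory {out}: {exc}") from exc

    truth = dataset.truth
    paths: dict[str, Path] = {}

    ann_rows: dict[tuple[str, int, str, str], dict] = {}
    for s, variants in sorted(truth.variants_by_sample.items()):
        vcf_path = out / "vcf" / f"{s}.vcf"
        _write_vcf(variants, s, vcf_path)
        paths[f"vcf:{s}"] = vcf_path
        for v in variants:
            row = {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene if v.gene is not None else "",
                "func_region": v.func_region,
                "exonic_func": v.exonic_func,
            }
            for k in POP_AF_KEYS:
                val = v.pop_af.get(k)
                row[k] = "" if val is None else repr(float(val))
            ann_rows[v.key()] = row

    ann = pd.DataFrame(
        [ann_rows[k] for k in sorted(ann_rows)],
        columns=["chrom", "pos", "ref", "alt", "gene", "func_region", "exonic_func", *POP_AF_KEYS],
    )
    paths["annotations"] = out / "annotations.tsv"
    ann.to_csv(paths["annotations"], sep="\t", index=False)

    paths["samples"] = out / "samples.tsv"
    truth.sample_sheet.to_csv(paths["samples"], sep="\t", index=False)

    paths["gene_lengths"] = out / "gene_lengths.tsv"
    truth.gene_lengths.to_frame().to_csv(paths["gene_lengths"], sep="\t")

    if dataset.counts is not None:
        paths["counts"] = out / "counts.tsv"
        dataset.counts.to_csv(paths["counts"], sep="\t")

    truth_obj = {
        "format_version": TRUTH_FORMAT_VERSION,
        "seed": truth.seed,
        "emv_by_patient": {
            p: sorted(list(k) for k in keys) for p, keys in sorted(truth.emv_by_patient.items())
        },
        "coupling_shifts": {s: truth.coupling_shifts[s] for s in sorted(truth.coupling_shifts)},
        "library_factors": {s: truth.library_factors[s] for s in sorted(truth.library_factors)},
        "patient_effects": {p: truth.patient_effects[p] for p in sorted(truth.patient_effects)},
    }
    paths["truth"] = out / "truth.json"
    paths["truth"].write_text(json.dumps(truth_obj, indent=1, sort_keys=True))
    return paths


def load_fixtures(fixture_dir: str | Path) -> LoadedCohort:
    """Read fixtures written by :func:`write_fixtures` back into memory."""
    d = Path(fixture_dir)
    sheet = pd.read_csv(d / "samples.tsv", sep="\t", dtype={"sample_id": str, "patient_id": str})
    ann = pd.read_csv(
        d / "annotations.tsv",
        sep="\t",
        dtype={"chrom": str, "ref": str, "alt": str, "gene": str},
        keep_default_na=False,
    )
    if len(ann):
        ann = ann.set_index(["chrom", "pos", "ref", "alt"])
    else:
        ann = ann.set_index(pd.MultiIndex.from_arrays([[], [], [], []], names=["chrom", "pos", "ref", "alt"]))

    variants_by_sample: dict[str, list[VariantRecord]] = {}
    patient_of = dict(zip(sheet["sample_id"], sheet["patient_id"]))
    for row in sheet.itertuples(index=False):
        if row.role == "N":
            continue
        vcf_path = d / "vcf" / f"{row.sample_id}.vcf"
        variants_by_sample[row.sample_id] = read_vcf_with_annotations(
            vcf_path, ann, row.sample_id, patient_of[row.sample_id]
        )

    counts_path = d / "counts.tsv"
    counts = pd.read_csv(counts_path, sep="\t", index_col=0) if counts_path.exists() else pd.DataFrame()
    lengths = pd.read_csv(d / "gene_lengths.tsv", sep="\t", index_col=0)["length_bp"]
    return LoadedCohort(
        sample_sheet=sheet,
        variants_by_sample=variants_by_sample,
        counts=counts,
        gene_lengths=lengths,
    )
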