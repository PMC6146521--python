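"""End-to-end orchestration: simulate/load -> filter -> set ops -> expression
-> association -> report, with a manifest for reproducibility.

Re-running with the same config and seed reproduces every output file
byte-identically: all randomness flows from the seed, all iteration orders
are fixed, and floats are serialized with repr.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .cohort_set_ops import build_patient_sets, cross_patient_recurrence, derive_emv, gene_mutation_rates
from .errors import ConfigError, DataError, MetlinkError
from .expression_quant import CountMatrix, pair_fold_change, pca_outlier_flags
from .mutation_expression_link import AssociationMatrix, build_association_matrix
from .synthetic_cohort import (
    CohortConfig,
    LoadedCohort,
    load_fixtures,
    simulate_cohort,
    write_fixtures,
)
from .variant_filtering import (
    MUTATION_CLASSES,
    FilterConfig,
    run_filter_cascade,
    summarize_spectrum,
    write_variant_table,
)

__all__ = ["RunConfig", "RunBundle", "run_pipeline", "render_report", "load_run_config"]

logger = logging.getLogger(__name__)


def _coerce_cohort_dict(raw: Mapping[str, Any]) -> CohortConfig:
    """Build a CohortConfig from a parsed flat config mapping (YAML/TOML)."""
    allowed = {f.name for f in dc_fields(CohortConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"unknown cohort config keys: {sorted(unknown)}")
    if "seed" not in raw:
        raise ConfigError("cohort config must set a seed")
    kw = dict(raw)
    for key in ("pt_regions_per_patient", "burden_regimes"):
        if isinstance(kw.get(key), list):
            kw[key] = tuple(kw[key])
    if isinstance(kw.get("allele_fraction_model"), list):
        kw["allele_fraction_model"] = tuple(tuple(c) for c in kw["allele_fraction_model"])
    if isinstance(kw.get("burden_intervals"), dict):
        kw["burden_intervals"] = {k: tuple(v) for k, v in kw["burden_intervals"].items()}
    return CohortConfig(**kw)


@dataclass
class RunConfig:
    out_dir: Path
    seed: int
    simulate: CohortConfig | None = None
    input_dir: Path | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    pseudocount: float = 0.5
    qc_z_threshold: float = 6.0
    qc_components: int = 4
    min_altered: int = 3
    classes: tuple[str, ...] = MUTATION_CLASSES
    emv_only: bool = False
    cohort_level_emv: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.input_dir is None):
            raise ConfigError("exactly one of a simulation block or an input directory is required")

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        if "seed" not in raw or "out_dir" not in raw:
            raise ConfigError("run config requires 'seed' and 'out_dir'")
        sim = None
        if raw.get("simulate") is not None:
            sim_raw = dict(raw["simulate"])
            sim_raw.setdefault("seed", raw["seed"])
            sim = _coerce_cohort_dict(sim_raw)
        flt = FilterConfig(**raw.get("filter", {}))
        expr = raw.get("expression", {})
        assoc = raw.get("association", {})
        inputs = raw.get("inputs", {})
        return cls(
            out_dir=Path(raw["out_dir"]),
            seed=int(raw["seed"]),
            simulate=sim,
            input_dir=Path(inputs["fixture_dir"]) if inputs.get("fixture_dir") else None,
            filter=flt,
            pseudocount=float(expr.get("pseudocount", 0.5)),
            qc_z_threshold=float(expr.get("qc_z_threshold", 6.0)),
            qc_components=int(expr.get("qc_components", 4)),
            min_altered=int(assoc.get("min_altered", 3)),
            classes=tuple(assoc.get("classes", MUTATION_CLASSES)),
            emv_only=bool(assoc.get("emv_only", False)),
            cohort_level_emv=bool(assoc.get("cohort_level_emv", False)),
            log_level=str(raw.get("log_level", "INFO")),
        )


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"run config {path} must be a mapping")
    return RunConfig.from_dict(raw)


@dataclass
class RunBundle:
    """In-memory results of a pipeline run plus the paths written."""

    config: RunConfig
    sample_sheet: pd.DataFrame
    stage_logs: dict[str, dict[str, int]]
    spectrum: dict
    emv_by_patient: dict[str, list]
    recurrence_frame: pd.DataFrame
    gene_rates: pd.DataFrame
    size_factors: pd.Series
    qc_flagged: list[str]
    association: AssociationMatrix
    paths: dict[str, Path]
    complete: bool = False


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except MetlinkError as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc
        return wrapped
    return deco


def run_pipeline(cfg: RunConfig) -> RunBundle:
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    incomplete_marker = out / "INCOMPLETE"
    incomplete_marker.write_text("run in progress or aborted\n")
    paths: dict[str, Path] = {}

    # --- acquire inputs -----------------------------------------------------
    if cfg.simulate is not None:
        dataset = simulate_cohort(cfg.simulate)
        fixture_dir = out / "inputs"
        write_fixtures(dataset, fixture_dir)
        cohort = LoadedCohort(
            sample_sheet=dataset.truth.sample_sheet,
            variants_by_sample=dataset.variants_by_sample,
            counts=dataset.counts,
            gene_lengths=dataset.truth.gene_lengths,
        )
        paths["inputs"] = fixture_dir
    else:
        cohort = _stage("load")(load_fixtures)(cfg.input_dir)

    sheet = cohort.sample_sheet
    tumour_samples = [r.sample_id for r in sheet.itertuples(index=False) if r.role in ("PT", "MT")]

    # --- filter cascade -----------------------------------------------------
    filtered_dir = out / "filtered"
    filtered_dir.mkdir(exist_ok=True)
    filtered: dict[str, list] = {}
    stage_logs: dict[str, dict[str, int]] = {}
    for s in tumour_samples:
        survivors, log = _stage("filter")(run_filter_cascade)(
            cohort.variants_by_sample.get(s, []), cfg.filter
        )
        filtered[s] = survivors
        stage_logs[s] = log.as_dict()
        p = filtered_dir / f"{s}.filtered.tsv"
        write_variant_table(survivors, p)
        paths[f"filtered:{s}"] = p
    paths["stages"] = filtered_dir / "stages.json"
    paths["stages"].write_text(json.dumps(stage_logs, indent=1, sort_keys=True))

    # --- spectrum summary ---------------------------------------------------
    all_filtered = [v for s in tumour_samples for v in filtered[s]]
    spectrum = summarize_spectrum(all_filtered).as_dict()
    paths["spectrum"] = out / "spectrum.json"
    paths["spectrum"].write_text(json.dumps(spectrum, indent=1, sort_keys=True))

    # --- set algebra --------------------------------------------------------
    patient_sets = _stage("setops")(build_patient_sets)(sheet, filtered)
    emv_by_patient: dict[str, list] = {}
    cohort_normal_keys: set = set()
    for p in patient_sets:
        emv = derive_emv(p)
        if cfg.cohort_level_emv:
            emv = emv - cohort_normal_keys  # normals carry no somatic calls here
        emv_by_patient[p.patient_id] = sorted(emv)
    emv_rows = [
        {"patient_id": pid, "chrom": c, "pos": pos, "ref": r, "alt": a}
        for pid, keys in sorted(emv_by_patient.items())
        for (c, pos, r, a) in keys
    ]
    emv_frame = pd.DataFrame(emv_rows, columns=["patient_id", "chrom", "pos", "ref", "alt"])
    paths["emv"] = out / "emv.tsv"
    emv_frame.to_csv(paths["emv"], sep="\t", index=False)

    recurrence = (
        cross_patient_recurrence(patient_sets, filtered) if patient_sets else None
    )
    rec_frame = recurrence.to_frame() if recurrence else pd.DataFrame(
        columns=["chrom", "pos", "ref", "alt", "n_patients"]
    )
    paths["recurrence"] = out / "recurrence.tsv"
    rec_frame.to_csv(paths["recurrence"], sep="\t", index=False)

    mt_samples = [r.sample_id for r in sheet.itertuples(index=False) if r.role == "MT"]
    mt_variants = [v for s in mt_samples for v in filtered.get(s, [])]
    gene_rates = gene_mutation_rates(mt_variants, cohort.gene_lengths.to_dict())
    paths["gene_rates"] = out / "gene_rates_mt.tsv"
    gene_rates.to_csv(paths["gene_rates"], sep="\t", index=False)

    # --- expression ---------------------------------------------------------
    matrix = CountMatrix(counts=cohort.counts)
    norm = _stage("normalize")(matrix.normalized)()
    n_samples = matrix.counts.shape[1]
    qc_components = min(cfg.qc_components, max(1, n_samples - 2))
    qc_flagged = pca_outlier_flags(norm, n_components=qc_components, z_threshold=cfg.qc_z_threshold)
    paths["qc"] = out / "qc.json"
    paths["qc"].write_text(
        json.dumps(
            {
                "size_factors": {s: float(norm.size_factors[s]) for s in norm.size_factors.index},
                "flagged_samples": qc_flagged,
                "n_components": qc_components,
                "z_threshold": cfg.qc_z_threshold,
            },
            indent=1,
            sort_keys=True,
        )
    )

    normal_of = {
        r.patient_id: r.sample_id for r in sheet.itertuples(index=False) if r.role == "N"
    }
    patient_of = dict(zip(sheet["sample_id"], sheet["patient_id"]))
    flagged = set(qc_flagged)
    rankings = {}
    kept_samples = []
    rank_rows = []
    for s in tumour_samples:
        if s in flagged:
            logger.info("sample %s excluded by PCA QC", s)
            continue
        normal = normal_of.get(patient_of[s])
        if normal is None or normal in flagged:
            logger.warning("no usable normal for %s; sample skipped", s)
            continue
        ranking = pair_fold_change(norm, s, normal, pseudocount=cfg.pseudocount, sample_sheet=sheet)
        rankings[s] = ranking
        kept_samples.append(s)
        for gene, row in ranking.table.iterrows():
            rank_rows.append((s, gene, repr(float(row["fc"])), int(row["rank"])))
    rank_frame = pd.DataFrame(rank_rows, columns=["sample_id", "gene", "fc", "rank"])
    paths["fc_rankings"] = out / "fc_rankings.tsv"
    rank_frame.to_csv(paths["fc_rankings"], sep="\t", index=False)

    # --- association --------------------------------------------------------
    assoc_variants = dict(filtered)
    if cfg.emv_only:
        emv_keys = {pid: set(keys) for pid, keys in emv_by_patient.items()}
        for s in mt_samples:
            keys = emv_keys.get(patient_of[s], set())
            assoc_variants[s] = [v for v in filtered.get(s, []) if v.key() in keys]
    association = _stage("associate")(build_association_matrix)(
        rankings, assoc_variants, kept_samples, classes=cfg.classes, min_altered=cfg.min_altered
    )
    paths["association_wide"] = out / "association_wide.tsv"
    association.to_wide_frame().to_csv(paths["association_wide"], sep="\t")
    paths["association_long"] = out / "association_long.tsv"
    association.to_long_frame().to_csv(paths["association_long"], sep="\t", index=False)

    bundle = RunBundle(
        config=cfg,
        sample_sheet=sheet,
        stage_logs=stage_logs,
        spectrum=spectrum,
        emv_by_patient=emv_by_patient,
        recurrence_frame=rec_frame,
        gene_rates=gene_rates,
        size_factors=norm.size_factors,
        qc_flagged=qc_flagged,
        association=association,
        paths=paths,
        complete=True,
    )

    paths["report"] = out / "report.md"
    paths["report"].write_text(render_report(bundle))

    manifest = {
        "metlink_version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "n_samples": int(len(sheet)),
        "n_tumour_samples": len(tumour_samples),
        "outputs": {k: str(v.relative_to(out)) for k, v in sorted(paths.items())},
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True))
    incomplete_marker.unlink()
    return bundle


def _config_hash(cfg: RunConfig) -> str:
    """Hash of the analytic configuration (paths excluded)."""

    def default(o):
        if isinstance(o, Path):
            return None
        if hasattr(o, "__dict__"):
            return o.__dict__
        if hasattr(o, "__dataclass_fields__"):
            return {f: getattr(o, f) for f in o.__dataclass_fields__}
        return repr(o)

    payload = {f: getattr(cfg, f) for f in cfg.__dataclass_fields__ if f not in ("out_dir", "input_dir")}
    blob = json.dumps(payload, default=default, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def render_report(bundle: RunBundle) -> str:
    """Markdown summary with spectrum, recurrence, EMV and association grid."""
    if not bundle.complete:
        missing = [k for k in ("association_wide", "emv", "spectrum") if k not in bundle.paths]
        raise DataError(f"bundle incomplete; missing artifacts: {missing or 'unknown'}")

    lines = ["# metlink run report", ""]
    spec = bundle.spectrum
    lines += [
        "## Mutation spectrum (filtered variants, all tumour samples)",
        "",
        f"- variants: {spec['n_variants']} ({spec['n_snvs']} SNVs)",
        f"- transitions / transversions: {spec['transitions']} / {spec['transversions']}",
        f"- C:G-pair / A:T-pair substitutions: {spec['cg_pair_mutations']} / {spec['at_pair_mutations']}",
        "",
    ]

    lines += ["## Exclusive metastatic variants", ""]
    with_emv = {p: k for p, k in sorted(bundle.emv_by_patient.items()) if k}
    if with_emv:
        for pid, keys in with_emv.items():
            lines.append(f"- {pid}: {len(keys)} EMVs")
    else:
        lines.append("- none")
    lines.append("")

    rec = bundle.recurrence_frame
    n_multi = int((rec["n_patients"] > 1).sum()) if len(rec) else 0
    lines += [
        "## Cross-patient recurrence",
        "",
        f"- variant identities observed: {len(rec)}",
        f"- detected in more than one patient: {n_multi}",
        "",
    ]

    if bundle.qc_flagged:
        lines += ["## QC", "", f"- samples excluded by PCA QC: {', '.join(bundle.qc_flagged)}", ""]

    lines += ["## Mutation-expression association (-log10 p)", ""]
    wide = bundle.association.to_wide_frame()
    sig = {
        (r.sample_id, r.mutation_class)
        for r in bundle.association.cells.values()
        if r.significant
    }
    header = ["class"] + list(wide.columns)
    lines.append("| " + " | ".join(header) + " |")
    lines.append("|" + "---|" * len(header))
    for cls in wide.index:
        row = [cls]
        for s in wide.columns:
            cell = wide.loc[cls, s]
            row.append(f"**{cell}**" if (s, cls) in sig else (cell or ""))
        lines.append("| " + " | ".join(row) + " |")
    lines.append("")
    lines.append("Bold marks significant association (p < 0.05); 'Inf' marks -log10 p > 10.")
    lines.append("")
    return "\n".join(lines)
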