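import numpy as np
import pandas as pd
import pytest

from metlink.variant_filtering import VariantRecord


def make_variant(**overrides) -> VariantRecord:
    """A clean pass-everything SNV; override fields per test."""
    fields = dict(
        patient_id="P01",
        sample_id="P01.MT",
        chrom="chrS",
        pos=100,
        ref="C",
        alt="T",
        variant_type="SNV",
        depth=100,
        alt_forward=20,
        alt_reverse=20,
        allele_fraction=0.4,
        zygosity="het",
        gene="gene0001",
        func_region="exonic",
        exonic_func="nonsynonymous",
        pop_af={},
    )
    fields.update(overrides)
    return VariantRecord(**fields)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_counts():
    """5 genes x 4 samples, two patients (N + tumour each)."""
    counts = pd.DataFrame(
        {
            "P01.N": [100, 50, 10, 0, 5],
            "P01.MT": [200, 25, 10, 0, 5],
            "P02.N": [90, 60, 12, 3, 4],
            "P02.MT": [80, 55, 20, 0, 6],
        },
        index=pd.Index([f"g{i}" for i in range(1, 6)], name="gene"),
    )
    return counts


@pytest.fixture
def toy_sample_sheet():
    return pd.DataFrame(
        {
            "sample_id": ["P01.N", "P01.MT", "P02.N", "P02.MT"],
            "patient_id": ["P01", "P01", "P02", "P02"],
            "role": ["N", "MT", "N", "MT"],
            "region_index": [0, 0, 0, 0],
        }
    )


def random_variant(rng: np.random.Generator, pos: int, sample="S1", patient="P1") -> VariantRecord:
    """Random record exercising every filter branch."""
    ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
    depth = int(rng.integers(1, 60))
    alt_total = int(rng.integers(0, depth + 1))
    fwd = int(rng.integers(0, alt_total + 1))
    pop = {}
    for key in ("exac_all", "esp6500_all", "kg_all", "kg_eur"):
        if rng.random() < 0.4:
            pop[key] = float(rng.uniform(0, 0.8))
    return VariantRecord(
        patient_id=patient,
        sample_id=sample,
        chrom="chrS",
        pos=pos,
        ref=str(ref),
        alt=str(alt),
        variant_type="SNV",
        depth=depth,
        alt_forward=fwd,
        alt_reverse=alt_total - fwd,
        allele_fraction=alt_total / depth,
        zygosity="hom_alt" if rng.random() < 0.3 else "het",
        gene=f"gene{int(rng.integers(1, 20)):04d}",
        func_region="exonic",
        exonic_func="nonsynonymous",
        pop_af=pop,
    )
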