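"""Independent oracles and the toy fixture used by scripts/acceptance.py.

Kept separate from the package so the checks stay independent of the
implementation they verify.
"""

from __future__ import annotations

import bisect
import itertools

from metlink.variant_filtering import VariantRecord


def brute_force_ks(a, b):
    """D by direct ECDF scan; p by full enumeration of label assignments."""
    a, b = sorted(a), sorted(b)
    n, m = len(a), len(b)

    def d_of(x, y):
        xs, ys = sorted(x), sorted(y)
        vals = sorted(set(xs) | set(ys))
        return max(
            abs(bisect.bisect_right(xs, v) / len(xs) - bisect.bisect_right(ys, v) / len(ys))
            for v in vals
        )

    d_obs = d_of(a, b)
    pooled = a + b
    count = total = 0
    for combo in itertools.combinations(range(n + m), n):
        chosen = set(combo)
        xa = [pooled[i] for i in combo]
        xb = [pooled[i] for i in range(n + m) if i not in chosen]
        total += 1
        if d_of(xa, xb) >= d_obs - 1e-12:
            count += 1
    return d_obs, count / total


def _variant(**overrides) -> VariantRecord:
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


def ten_variant_fixture():
    """Hand-built cascade fixture; applying the four rules by hand gives the
    stage log {input:10, af_pass:10, hom_common_removed:1,
    depth_strand_pass:5, pop_pass:3} and survivors at positions 3, 9, 10."""
    return [
        _variant(pos=1, depth=15, alt_forward=5, alt_reverse=5, allele_fraction=10 / 15),
        _variant(pos=2, depth=15, alt_forward=5, alt_reverse=5, allele_fraction=10 / 15),
        _variant(pos=3),
        _variant(pos=4, alt_forward=2, alt_reverse=30, allele_fraction=0.32),
        _variant(pos=5, alt_forward=30, alt_reverse=2, allele_fraction=0.32),
        _variant(pos=6, pop_af={"exac_all": 0.05}),
        _variant(pos=7, depth=15, alt_forward=7, alt_reverse=7, allele_fraction=14 / 15,
                 zygosity="hom_alt", pop_af={"exac_all": 0.6}),
        _variant(pos=8, pop_af={"kg_eur": 0.02}),
        _variant(pos=9),
        _variant(pos=10),
    ]
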