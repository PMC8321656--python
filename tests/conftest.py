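"""Shared fixtures and fast profile builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from graftrace.variants import (
    DB_NAMES,
    FUNCTIONAL_CLASSES,
    AnnotatedVariant,
    ObservedVariant,
    SampleProfile,
    VariantKey,
)

# frequency dictionaries shared across variants for cheap mass construction
COMMON_FREQS = {"dbSNP": 0.05, "gnomAD": 0.05}          # >= 0.001 in two dbs
RARE_FREQS = {"ExAC": 0.00005}                          # below every threshold


def make_observed(
    chrom: str = "1",
    pos: int = 1000,
    ref: str = "A",
    alt: str = "G",
    fclass: str = "nonsynonymous",
    gene: str | None = None,
    freqs: dict | None = None,
    depth: int = 100,
    alt_depth: int = 50,
) -> ObservedVariant:
    annot = AnnotatedVariant(
        VariantKey(chrom, pos, ref, alt), fclass, gene=gene, db_freqs=freqs or {}
    )
    return ObservedVariant(annot, depth, alt_depth)


def bulk_profile(
    n: int,
    sample_id: str = "s",
    role: str = "recipient_tumor",
    sex: str = "unknown",
    start_pos: int = 1,
    freqs: dict | None = None,
    fclass: str = "non_exonic_or_ncRNA",
    chrom: str = "1",
) -> SampleProfile:
    """n variants at consecutive positions, sharing one frequency dict."""
    freqs = freqs if freqs is not None else {}
    variants = [
        ObservedVariant(
            AnnotatedVariant(VariantKey(chrom, start_pos + i, "A", "G"),
                             fclass, db_freqs=freqs),
            100, 50,
        )
        for i in range(n)
    ]
    return SampleProfile(sample_id, role, sex, variants)


def mixed_profile(
    n_common: int,
    n_rare: int,
    sample_id: str = "s",
    role: str = "recipient_tumor",
    start_pos: int = 1,
) -> SampleProfile:
    """First n_common variants flagged common by the default policy, then
    n_rare that survive it; consecutive positions on chromosome 1."""
    variants = []
    for i in range(n_common + n_rare):
        freqs = COMMON_FREQS if i < n_common else RARE_FREQS
        variants.append(
            ObservedVariant(
                AnnotatedVariant(VariantKey("1", start_pos + i, "A", "G"),
                                 "non_exonic_or_ncRNA", db_freqs=freqs),
                100, 50,
            )
        )
    return SampleProfile(sample_id, role, "unknown", variants)


def random_profile(
    rng: np.random.Generator,
    n: int,
    sample_id: str = "r",
    role: str = "recipient_tumor",
) -> SampleProfile:
    """Random positions, classes, frequencies and depths (unique keys)."""
    positions = rng.choice(10 * n + 10, size=n, replace=False) + 1
    variants = []
    for pos in positions:
        fclass = FUNCTIONAL_CLASSES[rng.integers(0, len(FUNCTIONAL_CLASSES))]
        freqs = {}
        for db in DB_NAMES:
            if rng.random() < 0.5:
                freqs[db] = float(rng.uniform(0, 0.1))
        depth = int(rng.integers(0, 300))
        alt = int(rng.integers(0, depth + 1)) if depth else 0
        variants.append(
            ObservedVariant(
                AnnotatedVariant(VariantKey("2", int(pos), "C", "T"),
                                 fclass, db_freqs=freqs),
                depth, alt,
            )
        )
    return SampleProfile(sample_id, role, "unknown", variants)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest donor-derived cohort shared by read-only tests."""
    from graftrace.simulate import CloneSpec, default_config, simulate_cohort

    cfg = default_config(seed=11, n_common=3000, n_rare_per_individual=120)
    cfg = cfg.model_copy(update={"clones": [
        CloneSpec(clone_id="truncal", fraction=1.0, private_mutation_count=150,
                  driver_mutations=[("BRAF", "7:140453136:A:T")]),
        CloneSpec(clone_id="pik3ca_subclone", fraction=0.3,
                  private_mutation_count=40,
                  driver_mutations=[("PIK3CA", "3:178936091:G:A")]),
    ]})
    # keep per-lesion private mutations small so they stay a minority of
    # each somatic profile, as in a freshly transplanted malignancy
    samples = [
        s.model_copy(update={"private_mutation_count": min(s.private_mutation_count, 60)})
        for s in cfg.samples
    ]
    cfg = cfg.model_copy(update={"samples": samples})
    return simulate_cohort(cfg)
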