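"""Putative somatic profile construction.

The somatic profile of a tumor is approximated in two steps that mirror how
donor-derived malignancy is unmasked when only partial germline material is
available:

1. **Germline subtraction** — every variant whose identity key appears in the
   host's constitutional (blood) variant set is removed from the tumor set.
   If the tumor is donor-derived, the remainder still contains the *donor's*
   germline variants, which is precisely the signal used downstream.
2. **Common-polymorphism filtering** — variants present in the population at
   an allele frequency >= 0.001 in more than one reference database
   (1000 Genomes, HapMap, dbSNP, ExAC, gnomAD) are split off as common SNPs.
   "More than one" is read literally: at least two consulted databases must
   meet the threshold.  A database in which the variant was never observed
   contributes nothing (absence is not frequency zero).

Both steps are pure key-set arithmetic; depths and allelic fractions are
carried through from the tumor sample unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .variants import DB_NAMES, FUNCTIONAL_CLASSES, SampleProfile

logger = logging.getLogger("graftrace.profiles")

__all__ = [
    "FilterPolicy",
    "ClassCountTable",
    "subtract_germline",
    "filter_common",
    "classify_counts",
]


@dataclass(frozen=True)
class FilterPolicy:
    """Common-polymorphism filter: AF >= threshold in >= min_databases."""

    af_threshold: float = 0.001
    min_databases: int = 2
    databases: Sequence[str] = DB_NAMES

    def __post_init__(self) -> None:
        if not (0.0 < self.af_threshold <= 1.0):
            raise ValueError("af_threshold must be in (0, 1]")
        if self.min_databases < 1:
            raise ValueError("min_databases must be >= 1")

    def is_common(self, db_freqs: Mapping[str, float]) -> bool:
        hits = sum(
            1
            for db in self.databases
            if db in db_freqs and db_freqs[db] >= self.af_threshold
        )
        return hits >= self.min_databases


@dataclass(frozen=True)
class ClassCountTable:
    """Per-functional-class variant tallies (the seven-row count table)."""

    counts: Mapping[str, int]
    total: int = field(default=-1)

    def __post_init__(self) -> None:
        full = {c: int(self.counts.get(c, 0)) for c in FUNCTIONAL_CLASSES}
        unknown = set(self.counts) - set(FUNCTIONAL_CLASSES)
        if unknown:
            raise ValueError(f"unknown functional classes {sorted(unknown)}")
        object.__setattr__(self, "counts", full)
        total = sum(full.values())
        if self.total == -1:
            object.__setattr__(self, "total", total)
        elif self.total != total:
            raise ValueError(f"total {self.total} != class sum {total}")

    def __getitem__(self, functional_class: str) -> int:
        return self.counts[functional_class]

    def as_dict(self) -> dict[str, int]:
        out = dict(self.counts)
        out["total"] = self.total
        return out


def subtract_germline(tumor: SampleProfile, germline: SampleProfile) -> SampleProfile:
    """Remove from ``tumor`` every variant whose key appears in ``germline``.

    Membership is pure (chrom, pos, ref, alt) identity; the germline het/hom
    state plays no role, as the subtraction acts on variant lists, not
    genotypes.  Depths and allelic fractions of the survivors are those of
    the tumor sample.
    """
    germ_keys = germline.keys()
    out = SampleProfile(
        tumor.sample_id,
        tumor.role,
        tumor.sex,
        (ov for ov in tumor if ov.key not in germ_keys),
    )
    logger.info(
        "subtract_germline(%s - %s): %d -> %d variants",
        tumor.sample_id, germline.sample_id, len(tumor), len(out),
    )
    return out


def filter_common(
    profile: SampleProfile, policy: FilterPolicy = FilterPolicy()
) -> tuple[SampleProfile, SampleProfile]:
    """Partition ``profile`` into (retained, removed-as-common).

    A variant is removed iff its frequency is present and >= the policy
    threshold in at least ``min_databases`` of the consulted databases.
    The two outputs are disjoint and their union is the input, so the common
    side remains available for the donor-overlap analysis.
    """
    consulted = set(policy.databases)
    seen_dbs: set[str] = set()
    retained, removed = [], []
    for ov in profile:
        seen_dbs.update(ov.variant.db_freqs)
        (removed if policy.is_common(ov.variant.db_freqs) else retained).append(ov)
    unknown = consulted - seen_dbs
    if unknown and len(profile) > 0:
        logger.warning(
            "filter_common(%s): databases %s absent from every variant",
            profile.sample_id, sorted(unknown),
        )
    mk = lambda variants: SampleProfile(
        profile.sample_id, profile.role, profile.sex, variants
    )
    return mk(retained), mk(removed)


def classify_counts(profile: SampleProfile) -> ClassCountTable:
    """Tally the profile by functional class; total equals the profile size."""
    counts = {c: 0 for c in FUNCTIONAL_CLASSES}
    for ov in profile:
        counts[ov.variant.functional_class] += 1
    return ClassCountTable(counts)
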