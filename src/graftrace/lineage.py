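"""Lineage inference: is a recipient's tumor donor-derived?

Evidence assembled per recipient lesion:

* **Donor overlap** — the fraction of the post-subtraction putative somatic
  profile whose variants are also seen in the donor tumor.  A recipient-origin
  tumor leaves an essentially clean somatic profile (near-zero overlap); a
  donor-derived tumor still carries the donor's germline in bulk, so the
  overlap is extensive.
* **Sex-chromosome discordance** — chrY variants in the profile of a female
  recipient with a male donor can only be donor DNA.
* **Shared coding variants** — coding variants shared across lesions are
  tri-classified into probably-somatic vs rare-donor-germline tiers using the
  ExAC population frequency and the donor-tumor allelic fraction, and shared
  known driver genes are counted.

The final verdict is a pure function of this evidence and explicit,
configurable thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .variants import (
    CODING_CLASSES,
    AnnotatedVariant,
    ObservedVariant,
    SampleProfile,
    VariantKey,
)

__all__ = [
    "OverlapStats",
    "SharedVariantThresholds",
    "DecisionThresholds",
    "LineageEvidence",
    "TransmissionDecision",
    "SHARED_CLASS_LABELS",
    "DEFAULT_DRIVER_GENES",
    "round_half_away",
    "overlap_with_donor",
    "count_sex_discordant",
    "intersect_profiles",
    "classify_shared_coding",
    "decide_transmission",
]

SHARED_CLASS_LABELS = (
    "probably_somatic",
    "rare_donor_germline_exac",
    "donor_het_germline_af",
    "unclassified",
)

#: cancer genes whose shared mutation counts toward the driver rule
DEFAULT_DRIVER_GENES: frozenset[str] = frozenset(
    {"BRAF", "PIK3CA", "SDHC", "DDR2", "FANCD2"}
)


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (0.5 -> 1, -0.5 -> -1)."""
    scale = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


@dataclass(frozen=True)
class OverlapStats:
    """Donor-tumor overlap of a putative somatic profile and its common subset."""

    profile_size: int
    shared_with_donor: int
    percent_shared: float            # one decimal
    common_subset_size: int
    common_shared: int
    percent_common_shared: int       # nearest integer

    def __post_init__(self) -> None:
        if not (0 <= self.shared_with_donor <= self.profile_size):
            raise ValueError("shared_with_donor outside [0, profile_size]")
        if not (0 <= self.common_shared <= self.common_subset_size):
            raise ValueError("common_shared outside [0, common_subset_size]")


@dataclass(frozen=True)
class SharedVariantThresholds:
    """Bands for the tri-classification of shared coding variants."""

    exac_somatic_max: float = 0.000094
    exac_germline_min: float = 0.0001
    exac_germline_max: float = 0.0009
    donor_af_low: float = 0.49
    donor_af_high: float = 0.51

    def __post_init__(self) -> None:
        if not (self.exac_somatic_max < self.exac_germline_min <= self.exac_germline_max):
            raise ValueError("ExAC bands must be ordered somatic_max < germline_min <= germline_max")
        if not (self.donor_af_low < self.donor_af_high):
            raise ValueError("donor AF band must be ordered low < high")


@dataclass(frozen=True)
class DecisionThresholds:
    """Thresholds for the transmission verdict (pipeline defaults, configurable)."""

    overlap_threshold: float = 80.0   # percent shared with donor => transmitted
    clean_threshold: float = 5.0      # percent shared at or below => clean profile
    chry_threshold: int = 5           # sex-discordant chrY variants => transmitted
    driver_threshold: int = 2         # shared probably-somatic drivers => transmitted
    driver_genes: frozenset[str] = DEFAULT_DRIVER_GENES


@dataclass(frozen=True)
class LineageEvidence:
    """Everything the verdict is a function of."""

    overlap: OverlapStats
    sex_discordant_count: Optional[int]      # None when not applicable
    donor_dna_flag: bool
    shared_class_counts: dict[str, int] = field(default_factory=dict)
    shared_drivers: tuple[str, ...] = ()


@dataclass(frozen=True)
class TransmissionDecision:
    verdict: str                     # transmitted | not_transmitted | indeterminate
    evidence: LineageEvidence
    thresholds: DecisionThresholds
    fired_rules: tuple[str, ...]

    def as_dict(self) -> dict:
        ov = self.evidence.overlap
        return {
            "verdict": self.verdict,
            "fired_rules": list(self.fired_rules),
            "evidence": {
                "profile_size": ov.profile_size,
                "shared_with_donor": ov.shared_with_donor,
                "percent_shared": ov.percent_shared,
                "common_subset_size": ov.common_subset_size,
                "common_shared": ov.common_shared,
                "percent_common_shared": ov.percent_common_shared,
                "sex_discordant_count": self.evidence.sex_discordant_count,
                "donor_dna_flag": self.evidence.donor_dna_flag,
                "shared_class_counts": dict(self.evidence.shared_class_counts),
                "shared_drivers": list(self.evidence.shared_drivers),
            },
            "thresholds": {
                "overlap_threshold": self.thresholds.overlap_threshold,
                "clean_threshold": self.thresholds.clean_threshold,
                "chry_threshold": self.thresholds.chry_threshold,
                "driver_threshold": self.thresholds.driver_threshold,
                "driver_genes": sorted(self.thresholds.driver_genes),
            },
        }


def overlap_with_donor(
    profile: SampleProfile,
    donor_tumor: SampleProfile,
    removed_common: Optional[SampleProfile] = None,
) -> OverlapStats:
    """Key-membership overlap of a putative somatic profile with the donor tumor.

    ``removed_common`` is the common-SNP complement produced by the filter
    (may be omitted/empty).  The full-profile percentage is reported to one
    decimal and the common-subset percentage to the nearest integer, both
    rounding half away from zero.
    """
    donor_keys = donor_tumor.keys()
    n = len(profile)
    shared = sum(1 for k in profile.keys() if k in donor_keys)
    pct = round_half_away(100.0 * shared / n, 1) if n else 0.0

    n_common = len(removed_common) if removed_common is not None else 0
    common_shared = (
        sum(1 for k in removed_common.keys() if k in donor_keys)
        if removed_common is not None
        else 0
    )
    pct_common = (
        int(round_half_away(100.0 * common_shared / n_common)) if n_common else 0
    )
    return OverlapStats(n, shared, pct, n_common, common_shared, pct_common)


def count_sex_discordant(
    profile: SampleProfile, recipient_sex: str, donor_sex: str
) -> tuple[Optional[int], bool]:
    """Count chrY variants when they are diagnostic of donor DNA.

    Returns ``(count, flag)``: the chrY count and a "donor-origin DNA
    present" flag when the recipient is female and the donor male; otherwise
    ``(None, False)`` (not applicable).
    """
    if recipient_sex == "female" and donor_sex == "male":
        count = profile.chrom_count("Y")
        return count, count > 0
    return None, False


def intersect_profiles(
    profiles: Sequence[SampleProfile], coding_only: bool = False
) -> list[VariantKey]:
    """Variant keys present in every profile, in canonical order.

    With ``coding_only`` the intersection is restricted to the six coding
    functional classes (everything but non-exonic/ncRNA).
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to intersect")

    def eligible(p: SampleProfile) -> set[VariantKey]:
        if coding_only:
            return {ov.key for ov in p if ov.variant.functional_class in CODING_CLASSES}
        return set(p.keys())

    shared = eligible(profiles[0])
    for p in profiles[1:]:
        shared &= eligible(p)
    return sorted(shared, key=lambda k: k.sort_key)


def classify_shared_coding(
    shared: Iterable[tuple[AnnotatedVariant, Optional[float]]],
    thresholds: SharedVariantThresholds = SharedVariantThresholds(),
) -> dict[str, list[AnnotatedVariant]]:
    """Tri-classify shared coding variants into somatic vs donor-germline tiers.

    Each item is ``(variant, donor_tumor_af)``; the donor AF may be None.
    Precedence (each variant gets exactly one label):

    1. ExAC frequency absent, or present and <= ``exac_somatic_max``
       -> ``probably_somatic`` (unobserved variants are rarer than any
       observed frequency);
    2. ExAC frequency in [``exac_germline_min``, ``exac_germline_max``]
       -> ``rare_donor_germline_exac``;
    3. donor-tumor AF in [``donor_af_low``, ``donor_af_high``]
       -> ``donor_het_germline_af`` (heterozygous in the donor germline);
    4. otherwise ``unclassified``.
    """
    out: dict[str, list[AnnotatedVariant]] = {c: [] for c in SHARED_CLASS_LABELS}
    for annot, donor_af in shared:
        exac = annot.db_freqs.get("ExAC")
        if exac is None or exac <= thresholds.exac_somatic_max:
            label = "probably_somatic"
        elif thresholds.exac_germline_min <= exac <= thresholds.exac_germline_max:
            label = "rare_donor_germline_exac"
        elif donor_af is not None and thresholds.donor_af_low <= donor_af <= thresholds.donor_af_high:
            label = "donor_het_germline_af"
        else:
            label = "unclassified"
        out[label].append(annot)
    return out


def shared_items_from_profiles(
    shared_keys: Iterable[VariantKey], donor_tumor: SampleProfile
) -> list[tuple[AnnotatedVariant, Optional[float]]]:
    """Pair each shared key with its donor-tumor annotation and observed AF."""
    items = []
    for key in shared_keys:
        ov = donor_tumor.get(key)
        if ov is not None:
            items.append((ov.variant, ov.af))
        else:
            items.append((AnnotatedVariant(key), None))
    return items


def decide_transmission(
    evidence: LineageEvidence,
    thresholds: DecisionThresholds = DecisionThresholds(),
) -> TransmissionDecision:
    """Turn assembled evidence into a transmission verdict.

    ``transmitted`` iff any of: extensive donor overlap (percent shared >=
    ``overlap_threshold``), sex-discordant chrY count >= ``chry_threshold``,
    or >= ``driver_threshold`` known driver genes among the shared
    probably-somatic variants.  ``not_transmitted`` iff the profile is clean
    (percent shared <= ``clean_threshold``) and no rule or flag fired.
    Anything else is ``indeterminate``.
    """
    fired: list[str] = []
    if evidence.overlap.percent_shared >= thresholds.overlap_threshold:
        fired.append("overlap")
    if (
        evidence.sex_discordant_count is not None
        and evidence.sex_discordant_count >= thresholds.chry_threshold
    ):
        fired.append("sex_discordance")
    n_drivers = sum(1 for g in evidence.shared_drivers if g in thresholds.driver_genes)
    if n_drivers >= thresholds.driver_threshold:
        fired.append("shared_drivers")

    if fired:
        verdict = "transmitted"
    elif (
        evidence.overlap.percent_shared <= thresholds.clean_threshold
        and not evidence.donor_dna_flag
    ):
        verdict = "not_transmitted"
        fired.append("clean_profile")
    else:
        verdict = "indeterminate"
    return TransmissionDecision(verdict, evidence, thresholds, tuple(fired))
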