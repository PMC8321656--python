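"""Tumor purity from a truncal driver's allelic fraction; clonality ratios.

Under a diploid, copy-neutral model a heterozygous truncal driver is present
on one of two alleles in every tumor cell, so its allelic fraction in a bulk
sample is purity / 2 and

    purity_percent = AF x 2 alleles x 100

rounded to the nearest integer percent (half away from zero) and clamped at
100 with a ``capped`` flag when AF exceeds 0.5 (which under this model can
only arise from copy-number events or sampling noise).  No CNV/LOH
correction is applied.  When a read depth is available, a 95% Wilson score
interval on the AF is propagated through the same x200 map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from statsmodels.stats.proportion import proportion_confint

from .lineage import round_half_away

__all__ = [
    "PurityEstimate",
    "ClonalityComparison",
    "estimate_purity",
    "clonal_ratio",
    "detectable",
    "LNA_DETECTION_LIMIT",
    "WES_DETECTION_LIMIT",
]

#: locked-nucleic-acid PCR assay detection limit (allelic fraction)
LNA_DETECTION_LIMIT = 0.01
#: practical whole-exome-sequencing detection limit (allelic fraction)
WES_DETECTION_LIMIT = 0.05


@dataclass(frozen=True)
class PurityEstimate:
    sample_id: Optional[str]
    gene: Optional[str]
    af: float
    purity_percent: int
    capped: bool
    ci_low: Optional[float] = None   # on the purity-percent scale
    ci_high: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "gene": self.gene,
            "af": self.af,
            "purity_percent": self.purity_percent,
            "capped": self.capped,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


@dataclass(frozen=True)
class ClonalityComparison:
    subclonal_gene: Optional[str]
    truncal_gene: Optional[str]
    af_sub: float
    af_truncal: float
    ratio: Optional[float]           # None when af_truncal == 0
    interpretation: str              # absent | minor_subclone | near_clonal | intermediate


def estimate_purity(
    af: float,
    depth: Optional[int] = None,
    sample_id: Optional[str] = None,
    gene: Optional[str] = None,
) -> PurityEstimate:
    """Purity percent = round(200 x AF), clamped to [0, 100].

    With ``depth`` given, a 95% Wilson interval on the AF (alt reads taken as
    round(af * depth)) is mapped through the same x200 transform; the
    interval is reported unclamped so a capped point estimate remains
    auditable.
    """
    if not (0.0 <= af <= 1.0):
        raise ValueError(f"allelic fraction must be in [0, 1], got {af}")
    raw = round_half_away(200.0 * af)
    capped = af > 0.5
    purity = int(min(max(raw, 0.0), 100.0))

    ci_low = ci_high = None
    if depth is not None:
        if depth <= 0:
            raise ValueError("depth must be positive when given")
        count = int(round_half_away(af * depth))
        lo, hi = proportion_confint(count, depth, alpha=0.05, method="wilson")
        ci_low, ci_high = 200.0 * lo, 200.0 * hi
    return PurityEstimate(sample_id, gene, af, purity, capped, ci_low, ci_high)


def clonal_ratio(
    af_sub: float,
    af_truncal: float,
    near_clonal_min: float = 0.85,
    minor_max: float = 0.5,
    subclonal_gene: Optional[str] = None,
    truncal_gene: Optional[str] = None,
) -> ClonalityComparison:
    """Compare a candidate subclonal driver's AF against the truncal driver's.

    The ratio af_sub / af_truncal approximates the fraction of tumor cells
    carrying the subclonal mutation.  ``absent`` when af_sub is 0;
    ``near_clonal`` when ratio >= ``near_clonal_min``; ``minor_subclone``
    when 0 < ratio <= ``minor_max``; ``intermediate`` otherwise.  The ratio
    is undefined (None) when the truncal AF is 0.
    """
    for name, v in (("af_sub", af_sub), ("af_truncal", af_truncal)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if af_truncal == 0.0:
        interp = "absent" if af_sub == 0.0 else "intermediate"
        return ClonalityComparison(subclonal_gene, truncal_gene, af_sub, af_truncal, None, interp)
    ratio = af_sub / af_truncal
    if af_sub == 0.0:
        interp = "absent"
    elif ratio >= near_clonal_min:
        interp = "near_clonal"
    elif ratio <= minor_max:
        interp = "minor_subclone"
    else:
        interp = "intermediate"
    return ClonalityComparison(subclonal_gene, truncal_gene, af_sub, af_truncal, ratio, interp)


def detectable(
    af: float,
    limit: float = LNA_DETECTION_LIMIT,
    wes_limit: float = WES_DETECTION_LIMIT,
) -> dict[str, bool]:
    """Per-assay detectability of a mutation at allelic fraction ``af``.

    The LNA-PCR assay resolves allelic fractions down to ~1%; routine WES
    variant calling is taken to require ~5%.
    """
    if not (0.0 <= af <= 1.0):
        raise ValueError(f"allelic fraction must be in [0, 1], got {af}")
    return {
        "detectable_by_lna": af >= limit,
        "detectable_by_wes": af >= wes_limit,
    }
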