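"""MLPA copy-number calling from probe peak heights.

Each MLPA sample is first intra-normalized: every probe peak is divided by
the mean peak of the panel's designated reference probes (probes lying
outside any test region), which removes sample-to-sample differences in DNA
input and amplification efficiency.  The per-probe copy-number ratio is then
the sample's intra-normalized value divided by the mean intra-normalized
value of the reference samples.  A 95% range is derived from the spread of
that reference mean (t-interval across reference samples, propagated through
the division).

Per-probe calls use fixed ratio borders: loss below 0.7, gain above 1.3,
normal at or between the borders (a ratio exactly on a border is normal).
A region verdict is the majority probe call when it reaches at least half of
the in-region probes, with ties resolved toward the abnormal call; otherwise
the region is ``mixed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variants import GraftraceError, normalize_chrom

__all__ = [
    "LOSS_BORDER",
    "GAIN_BORDER",
    "DEFAULT_REGION",
    "ProbeRatio",
    "RegionCall",
    "normalize_probes",
    "call_probe",
    "call_region",
]

LOSS_BORDER = 0.7
GAIN_BORDER = 1.3

#: CDKN2A/CDKN2B focal deletion span used as the default test region
DEFAULT_REGION: tuple[str, int, int] = ("9", 21_948_801, 22_163_300)


@dataclass(frozen=True)
class ProbeRatio:
    probe_id: str
    chrom: str
    pos: int
    gene: Optional[str]
    ratio: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    call: str                     # loss | normal | gain

    def as_dict(self) -> dict:
        return {
            "probe_id": self.probe_id,
            "chrom": self.chrom,
            "pos": self.pos,
            "gene": self.gene,
            "ratio": self.ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "call": self.call,
        }


@dataclass(frozen=True)
class RegionCall:
    chrom: str
    start: int
    end: int
    verdict: str                  # loss | normal | gain | mixed
    agreeing_fraction: float
    probe_calls: tuple[ProbeRatio, ...]

    def as_dict(self) -> dict:
        return {
            "region": f"{self.chrom}:{self.start}-{self.end}",
            "verdict": self.verdict,
            "agreeing_fraction": self.agreeing_fraction,
            "probes": [p.as_dict() for p in self.probe_calls],
        }


def call_probe(ratio: float, loss_border: float = LOSS_BORDER,
               gain_border: float = GAIN_BORDER) -> str:
    """loss iff ratio < loss_border; gain iff ratio > gain_border; else normal."""
    if ratio < 0:
        raise ValueError(f"ratio must be non-negative, got {ratio}")
    if ratio < loss_border:
        return "loss"
    if ratio > gain_border:
        return "gain"
    return "normal"


def _infer_reference_probes(table: pd.DataFrame) -> list[str]:
    mask = table["gene"].astype(str).str.upper().str.startswith("REF")
    return list(table.loc[mask, "probe_id"])


def normalize_probes(
    sample_peaks: pd.DataFrame,
    reference_samples: Sequence[pd.DataFrame],
    reference_probes: Optional[Sequence[str]] = None,
    loss_border: float = LOSS_BORDER,
    gain_border: float = GAIN_BORDER,
) -> list[ProbeRatio]:
    """Normalize one sample's peaks against reference samples and call probes.

    ``reference_probes`` names the panel's reference probes; when omitted,
    probes whose gene label starts with ``REF`` are used.  Probes missing
    from any reference sample are dropped with a warning; a zero
    reference-probe mean in any sample is an error.
    """
    import logging
    logger = logging.getLogger("graftrace.mlpa")

    if len(reference_samples) < 1:
        raise ValueError("need at least one reference sample")
    if reference_probes is None:
        reference_probes = _infer_reference_probes(sample_peaks)
    if not reference_probes:
        raise GraftraceError("no reference probes designated or inferable")

    def intra(table: pd.DataFrame) -> pd.Series:
        s = table.set_index("probe_id")["peak_height"].astype(float)
        ref_mean = s.reindex(reference_probes).mean()
        if not np.isfinite(ref_mean) or ref_mean <= 0:
            raise GraftraceError("zero or undefined reference-probe mean")
        return s / ref_mean

    sample_norm = intra(sample_peaks)
    ref_norms = [intra(r) for r in reference_samples]

    out: list[ProbeRatio] = []
    meta = sample_peaks.set_index("probe_id")
    k = len(ref_norms)
    for probe_id in sample_peaks["probe_id"]:
        ref_vals = np.array([rn.get(probe_id, np.nan) for rn in ref_norms])
        if np.isnan(ref_vals).any():
            logger.warning("probe %s missing from a reference sample; dropped", probe_id)
            continue
        ref_mean = float(ref_vals.mean())
        if ref_mean <= 0:
            raise GraftraceError(f"probe {probe_id}: non-positive reference mean")
        ratio = float(sample_norm[probe_id] / ref_mean)

        ci_low = ci_high = None
        if k >= 2:
            se = float(ref_vals.std(ddof=1)) / np.sqrt(k)
            t = stats.t.ppf(0.975, df=k - 1)
            hi_mean, lo_mean = ref_mean + t * se, ref_mean - t * se
            # dividing by a larger reference mean gives the smaller ratio
            ci_low = float(sample_norm[probe_id] / hi_mean)
            ci_high = (
                float(sample_norm[probe_id] / lo_mean) if lo_mean > 0 else np.inf
            )
        row = meta.loc[probe_id]
        chrom = normalize_chrom(row["chrom"])
        out.append(
            ProbeRatio(
                probe_id=str(probe_id),
                chrom=chrom if chrom is not None else str(row["chrom"]),
                pos=int(row["pos"]),
                gene=str(row["gene"]) if not pd.isna(row["gene"]) else None,
                ratio=ratio,
                ci_low=ci_low,
                ci_high=ci_high,
                call=call_probe(ratio, loss_border, gain_border),
            )
        )
    return out


def call_region(
    probes: Sequence[ProbeRatio],
    region: tuple[str, int, int] = DEFAULT_REGION,
    exclude_reference: bool = True,
) -> RegionCall:
    """Majority-vote region verdict over the probes inside ``region``.

    The verdict is the majority call when its fraction reaches >= 0.5 of
    in-region probes (ties between an abnormal call and ``normal`` resolve
    toward the abnormal call, favoring sensitivity in a screening context);
    otherwise ``mixed``.
    """
    chrom, start, end = normalize_chrom(region[0]), int(region[1]), int(region[2])
    if end <= start:
        raise ValueError("region end must be greater than start")
    in_region = [
        p for p in probes
        if p.chrom == chrom and start <= p.pos <= end
        and not (exclude_reference and p.gene and p.gene.upper().startswith("REF"))
    ]
    if not in_region:
        raise GraftraceError(f"no probes inside region {chrom}:{start}-{end}")

    n = len(in_region)
    counts = {c: sum(1 for p in in_region if p.call == c) for c in ("loss", "gain", "normal")}
    # abnormal calls first so an exact tie with "normal" resolves abnormal
    best = max(("loss", "gain", "normal"), key=lambda c: counts[c])
    frac = counts[best] / n
    verdict = best if frac >= 0.5 else "mixed"
    return RegionCall(chrom, start, end, verdict, frac, tuple(in_region))
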