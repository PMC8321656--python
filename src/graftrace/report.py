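"""Cohort-level reporting and end-to-end pipeline orchestration.

``run_pipeline`` executes the full decision flow for every recipient lesion:

    subtract germline -> filter common SNPs -> donor overlap -> chrY check
    -> cross-tumor coding intersection -> tri-classification -> purity
    -> MLPA region call -> transmission verdict

choosing per lesion between the two study designs: when the recipient's own
blood (germline) sample is present it is subtracted first (the
limited-material design); otherwise the lesion is only filtered against the
population databases.  Every intermediate count is persisted so each number
in the report is auditable, and the report is deterministic for fixed
inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .variants import CODING_CLASSES, FUNCTIONAL_CLASSES, SampleProfile, VariantKey
from . import variant_io
from .profiles import ClassCountTable, FilterPolicy, classify_counts, filter_common, subtract_germline
from .lineage import (
    DecisionThresholds,
    LineageEvidence,
    SharedVariantThresholds,
    TransmissionDecision,
    classify_shared_coding,
    count_sex_discordant,
    decide_transmission,
    intersect_profiles,
    overlap_with_donor,
    shared_items_from_profiles,
)
from .purity import estimate_purity
from .mlpa import DEFAULT_REGION, call_region, normalize_probes

logger = logging.getLogger("graftrace.report")

__all__ = ["CohortReport", "build_shared_unique_table", "run_pipeline"]

#: default truncal driver used for purity estimation (gene, chrom:pos:ref:alt)
DEFAULT_TRUNCAL_DRIVER = ("BRAF", "7:140453136:A:T")


def build_shared_unique_table(
    profiles: Sequence[SampleProfile], coding_only: bool = True
) -> dict:
    """Presence-pattern tally of (coding) variants across >= 2 profiles.

    Every variant in the union is assigned to exactly one bucket keyed by the
    subset of profiles containing it; per-bucket tallies are broken down by
    functional class.  Bucket totals therefore partition the union.  The two
    headline views — shared by all, unique to each — are surfaced under
    ``shared_by_all`` and ``unique``.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    ids = [p.sample_id for p in profiles]

    membership: dict[VariantKey, list[str]] = {}
    classes: dict[VariantKey, str] = {}
    for p in profiles:
        for ov in p:
            if coding_only and ov.variant.functional_class not in CODING_CLASSES:
                continue
            membership.setdefault(ov.key, []).append(p.sample_id)
            classes[ov.key] = ov.variant.functional_class

    buckets: dict[tuple[str, ...], dict[str, int]] = {}
    for key, present_in in membership.items():
        pattern = tuple(sorted(present_in))
        bucket = buckets.setdefault(pattern, {c: 0 for c in FUNCTIONAL_CLASSES})
        bucket[classes[key]] += 1

    def table(pattern: tuple[str, ...]) -> dict:
        counts = buckets.get(pattern, {c: 0 for c in FUNCTIONAL_CLASSES})
        return ClassCountTable(counts).as_dict()

    return {
        "profiles": ids,
        "union_size": len(membership),
        "shared_by_all": table(tuple(sorted(ids))),
        "unique": {sid: table((sid,)) for sid in ids},
        "patterns": {
            "&".join(pattern): ClassCountTable(counts).as_dict()
            for pattern, counts in sorted(buckets.items())
        },
    }


@dataclass
class CohortReport:
    """JSON-serializable end-to-end report for one cohort."""

    class_tables: dict            # per sample: total / common / potential-somatic
    overlap: dict                 # per lesion OverlapStats
    shared_unique: dict           # presence-pattern table over somatic profiles
    shared_classification: dict   # tri-classification of all-tumor shared coding set
    purity: dict                  # per tumor sample PurityEstimate
    mlpa: dict                    # per tumor sample RegionCall
    decisions: dict               # per lesion TransmissionDecision
    provenance: dict

    def as_dict(self) -> dict:
        return {
            "class_tables": self.class_tables,
            "overlap": self.overlap,
            "shared_unique": self.shared_unique,
            "shared_classification": self.shared_classification,
            "purity": self.purity,
            "mlpa": self.mlpa,
            "decisions": self.decisions,
            "provenance": self.provenance,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=1, sort_keys=True)

    def render_text(self) -> str:
        """Plain-text tables for terminal reading."""
        lines = ["== variant classification =="]
        header = ["class"] + list(self.class_tables)
        lines.append("\t".join(header))
        for cls in FUNCTIONAL_CLASSES + ("total",):
            row = [cls]
            for sid, tbl in self.class_tables.items():
                row.append(str(tbl["potential_somatic"].get(cls, "")))
            lines.append("\t".join(row))
        lines.append("")
        lines.append("== transmission verdicts ==")
        for sid, dec in self.decisions.items():
            lines.append(
                f"{sid}: {dec['verdict']}"
                f" (rules: {', '.join(dec['fired_rules']) or 'none'};"
                f" shared with donor: {dec['evidence']['percent_shared']}%)"
            )
        lines.append("")
        lines.append("== purity ==")
        for sid, p in self.purity.items():
            if p:
                lines.append(f"{sid}: {p['purity_percent']}% (AF {p['af']:.3f}, {p['gene']})")
        lines.append("")
        lines.append("== MLPA region calls ==")
        for sid, call in self.mlpa.items():
            if call:
                lines.append(f"{sid}: {call['region']} {call['verdict']}")
        return "\n".join(lines)


def _find_driver(profile: SampleProfile, driver: tuple[str, str]):
    gene, key_text = driver
    key = VariantKey.parse(key_text)
    ov = profile.get(key)
    if ov is not None:
        return ov
    for cand in profile:
        if cand.variant.gene == gene:
            return cand
    return None


def run_pipeline(
    samples: dict[str, SampleProfile],
    mlpa_samples: Optional[dict] = None,
    mlpa_references: Optional[dict] = None,
    policy: FilterPolicy = FilterPolicy(),
    shared_thresholds: SharedVariantThresholds = SharedVariantThresholds(),
    decision_thresholds: DecisionThresholds = DecisionThresholds(),
    truncal_driver: tuple[str, str] = DEFAULT_TRUNCAL_DRIVER,
    region: tuple[str, int, int] = DEFAULT_REGION,
    donor_sex: Optional[str] = None,
    out_dir: Optional[Path] = None,
    provenance: Optional[dict] = None,
) -> CohortReport:
    """Run the full lineage pipeline on a set of sample profiles.

    ``samples`` maps sample id to profile; roles drive the flow.  Exactly
    one ``donor_tumor`` profile is required, plus at least one recipient
    lesion (``recipient_tumor`` or ``recipient_metastasis``).  A
    ``recipient_blood`` profile is matched to lesions of the same sex...
    more precisely: blood is matched to a lesion when both were declared for
    the same individual via identical sample-id prefixes before the first
    underscore (the simulator's convention), or when only one blood sample
    exists and shares its sex with the lesion.
    """
    donors = [p for p in samples.values() if p.role == "donor_tumor"]
    if len(donors) != 1:
        raise ValueError(f"need exactly one donor_tumor sample, got {len(donors)}")
    donor_tumor = donors[0]
    if donor_sex is None:
        donor_sex = donor_tumor.sex
    lesions = [
        p for p in samples.values()
        if p.role in ("recipient_tumor", "recipient_metastasis")
    ]
    if not lesions:
        raise ValueError("need at least one recipient lesion")
    bloods = [p for p in samples.values() if p.role == "recipient_blood"]

    def blood_for(lesion: SampleProfile) -> Optional[SampleProfile]:
        prefix = lesion.sample_id.split("_")[0]
        for b in bloods:
            if b.sample_id.split("_")[0] == prefix:
                return b
        for b in bloods:
            if b.sex == lesion.sex:
                return b
        return None

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    class_tables: dict = {}
    overlap_out: dict = {}
    decisions: dict = {}
    somatic_profiles: list[SampleProfile] = []
    lesion_evidence: dict[str, dict] = {}

    # donor tumor gets the same common-SNP enrichment as everything else
    donor_retained, donor_removed = filter_common(donor_tumor, policy)
    class_tables[donor_tumor.sample_id] = {
        "total": classify_counts(donor_tumor).as_dict(),
        "common": classify_counts(donor_removed).as_dict(),
        "potential_somatic": classify_counts(donor_retained).as_dict(),
    }
    somatic_profiles.append(donor_retained)

    for lesion in lesions:
        blood = blood_for(lesion)
        if blood is not None:
            subtracted = subtract_germline(lesion, blood)
            logger.info("%s: design with germline (subtracted %s)",
                        lesion.sample_id, blood.sample_id)
        else:
            subtracted = lesion
            logger.info("%s: no germline available; filtering only", lesion.sample_id)
        retained, removed = filter_common(subtracted, policy)
        class_tables[lesion.sample_id] = {
            "total": classify_counts(lesion).as_dict(),
            "germline_removed": classify_counts(subtracted).as_dict(),
            "common": classify_counts(removed).as_dict(),
            "potential_somatic": classify_counts(retained).as_dict(),
        }
        somatic_profiles.append(retained)

        stats = overlap_with_donor(subtracted, donor_tumor, removed)
        chry, flag = count_sex_discordant(subtracted, lesion.sex, donor_sex)
        overlap_out[lesion.sample_id] = {
            "profile_size": stats.profile_size,
            "shared_with_donor": stats.shared_with_donor,
            "percent_shared": stats.percent_shared,
            "common_subset_size": stats.common_subset_size,
            "common_shared": stats.common_shared,
            "percent_common_shared": stats.percent_common_shared,
            "chry_count": chry,
            "donor_dna_flag": flag,
        }
        lesion_evidence[lesion.sample_id] = {
            "overlap": stats, "chry": chry, "flag": flag,
        }

        if out_dir is not None:
            variant_io.write_profile_tsv(retained, out_dir / f"{lesion.sample_id}.retained.tsv")
            variant_io.write_profile_tsv(removed, out_dir / f"{lesion.sample_id}.removed.tsv")

    # shared coding set across all enriched somatic profiles
    shared_classification: dict = {}
    shared_drivers: tuple[str, ...] = ()
    if len(somatic_profiles) >= 2:
        shared_keys = intersect_profiles(somatic_profiles, coding_only=True)
        items = shared_items_from_profiles(shared_keys, donor_tumor)
        partition = classify_shared_coding(items, shared_thresholds)
        shared_classification = {
            label: len(variants) for label, variants in partition.items()
        }
        shared_classification["shared_coding_total"] = len(shared_keys)
        driver_genes = sorted(
            {v.gene for v in partition["probably_somatic"]
             if v.gene and v.gene in decision_thresholds.driver_genes}
        )
        shared_drivers = tuple(driver_genes)
        shared_classification["shared_drivers"] = list(shared_drivers)
        if out_dir is not None:
            with open(out_dir / "shared_coding.json", "w") as fh:
                json.dump({label: [str(v.key) for v in vs]
                           for label, vs in partition.items()}, fh, indent=1)

    shared_unique = (
        build_shared_unique_table(somatic_profiles, coding_only=True)
        if len(somatic_profiles) >= 2 else {}
    )

    # purity per tumor sample
    purity_out: dict = {}
    for p in [donor_tumor] + lesions:
        ov = _find_driver(p, truncal_driver)
        if ov is not None and ov.af is not None:
            est = estimate_purity(ov.af, depth=ov.depth, sample_id=p.sample_id,
                                  gene=ov.variant.gene or truncal_driver[0])
            purity_out[p.sample_id] = est.as_dict()
        else:
            purity_out[p.sample_id] = None

    # MLPA region calls
    mlpa_out: dict = {}
    if mlpa_samples and mlpa_references:
        refs = list(mlpa_references.values())
        for sid, peaks in mlpa_samples.items():
            ratios = normalize_probes(peaks, refs)
            mlpa_out[sid] = call_region(ratios, region).as_dict()

    # verdicts
    class_counts_for_decision = {
        k: v for k, v in shared_classification.items()
        if k in ("probably_somatic", "rare_donor_germline_exac",
                 "donor_het_germline_af", "unclassified")
    }
    for lesion in lesions:
        ev = lesion_evidence[lesion.sample_id]
        evidence = LineageEvidence(
            overlap=ev["overlap"],
            sex_discordant_count=ev["chry"],
            donor_dna_flag=ev["flag"],
            shared_class_counts=class_counts_for_decision,
            shared_drivers=shared_drivers,
        )
        decision = decide_transmission(evidence, decision_thresholds)
        decisions[lesion.sample_id] = decision.as_dict()

    report = CohortReport(
        class_tables=class_tables,
        overlap=overlap_out,
        shared_unique=shared_unique,
        shared_classification=shared_classification,
        purity=purity_out,
        mlpa=mlpa_out,
        decisions=decisions,
        provenance=provenance or {},
    )
    if out_dir is not None:
        report.to_json(out_dir / "report.json")
        (out_dir / "report.txt").write_text(report.render_text() + "\n")
    return report
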