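"""Reading and writing the formats the pipeline touches.

Supported formats:

* single-sample VCF v4.2 (read via :mod:`cyvcf2`, written via :mod:`pysam`)
  with per-sample ``AD``/``DP`` and package INFO keys for functional class,
  gene, and per-database population frequencies;
* an annotation TSV sidecar (chrom, pos, ref, alt, functional_class, gene,
  ``<db>_af`` columns);
* a profile TSV that serializes a full :class:`SampleProfile`;
* the MLPA probe-peak TSV (probe_id, chrom, pos, gene, peak_height).

Multi-allelic VCF records are split into one observation per ALT allele.
Records on non-canonical contigs (MT, decoys, patches) are dropped and the
dropped count is logged, so the chromosome-level logic downstream (the chrY
sex-discordance check) operates on a closed universe of contigs.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .variants import (
    CANONICAL_CHROMS,
    DB_NAMES,
    FUNCTIONAL_CLASSES,
    AnnotatedVariant,
    FormatError,
    ObservedVariant,
    SampleProfile,
    VariantKey,
    normalize_chrom,
)

logger = logging.getLogger("graftrace.io")

#: default mapping from database name to the VCF INFO key carrying its AF
DEFAULT_INFO_FREQ_KEYS: dict[str, str] = {
    "1000G": "KG_AF",
    "HapMap": "HAPMAP_AF",
    "dbSNP": "DBSNP_AF",
    "ExAC": "EXAC_AF",
    "gnomAD": "GNOMAD_AF",
}

#: TSV column name per database ("1000G" -> "1000G_af", ...)
TSV_FREQ_COLUMNS: dict[str, str] = {db: f"{db}_af" for db in DB_NAMES}

_PROFILE_TSV_COLUMNS = (
    ["chrom", "pos", "ref", "alt", "functional_class", "gene"]
    + [TSV_FREQ_COLUMNS[db] for db in DB_NAMES]
    + ["depth", "alt_depth", "af"]
)

MLPA_COLUMNS = ("probe_id", "chrom", "pos", "gene", "peak_height")

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _scalar(value, index: int, n_alt: int):
    """Pick the per-ALT component of an INFO value (Number=A or scalar)."""
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        return value[index] if len(value) == n_alt else value[0]
    if isinstance(value, str) and n_alt > 1 and value.count(",") == n_alt - 1:
        return value.split(",")[index]
    return value


def read_vcf(
    path: PathLike,
    role: Optional[str] = None,
    sex: Optional[str] = None,
    info_freq_keys: Mapping[str, str] = DEFAULT_INFO_FREQ_KEYS,
    sample_id: Optional[str] = None,
) -> SampleProfile:
    """Read a single-sample VCF into a :class:`SampleProfile`.

    ``role``/``sex`` default to ``##graftrace_role=`` / ``##graftrace_sex=``
    header lines when present.  One :class:`ObservedVariant` is emitted per
    ALT allele; AF is taken from AD arithmetic, with a per-record warning and
    an undefined AF when neither AD nor DP is usable.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc

    header = vcf.raw_header
    meta = {}
    for line in header.splitlines():
        if line.startswith("##graftrace_"):
            k, _, v = line[2:].partition("=")
            meta[k] = v
    role = role or meta.get("graftrace_role", "recipient_tumor")
    sex = sex or meta.get("graftrace_sex", "unknown")
    if sample_id is None:
        sample_id = vcf.samples[0] if vcf.samples else Path(path).stem

    observed: list[ObservedVariant] = []
    dropped = 0
    no_depth = 0
    for rec in vcf:
        chrom = normalize_chrom(rec.CHROM)
        if chrom is None:
            dropped += 1
            continue
        alts = rec.ALT or []
        n_alt = len(alts)
        ad = None
        try:
            fmt_ad = rec.format("AD")
        except Exception:
            fmt_ad = None
        if fmt_ad is not None and len(fmt_ad) > 0:
            ad = [int(x) for x in fmt_ad[0] if x is not None and int(x) >= 0]
        dp = None
        try:
            fmt_dp = rec.format("DP")
        except Exception:
            fmt_dp = None
        if fmt_dp is not None and len(fmt_dp) > 0 and int(fmt_dp[0][0]) >= 0:
            dp = int(fmt_dp[0][0])

        for i, alt in enumerate(alts):
            try:
                key = VariantKey.build(chrom, rec.POS, rec.REF, alt)
            except ValueError:
                dropped += 1
                continue
            fclass = _scalar(rec.INFO.get("FCLASS"), i, n_alt) or FUNCTIONAL_CLASSES[0]
            gene = _scalar(rec.INFO.get("GENE"), i, n_alt)
            freqs = {}
            for db, key_name in info_freq_keys.items():
                val = _scalar(rec.INFO.get(key_name), i, n_alt)
                if val is not None and not (isinstance(val, float) and math.isnan(val)):
                    freqs[db] = float(val)
            annot = AnnotatedVariant(key, str(fclass), gene=gene, db_freqs=freqs)

            if ad is not None and len(ad) == n_alt + 1:
                alt_depth = ad[i + 1]
                depth = dp if dp is not None else sum(ad)
                depth = max(depth, alt_depth)
                observed.append(ObservedVariant(annot, depth, alt_depth))
            elif dp is not None:
                # DP without AD: depth known, alt support unknown -> af undefined
                no_depth += 1
                logger.warning("%s: AD missing at %s; af undefined", path, key)
                observed.append(ObservedVariant(annot, 0, 0))
            else:
                no_depth += 1
                logger.warning("%s: no AD/DP at %s; af undefined", path, key)
                observed.append(ObservedVariant(annot, 0, 0))

    if dropped:
        logger.info("%s: dropped %d records on non-canonical contigs", path, dropped)
    return SampleProfile(sample_id, role, sex, observed)


def write_vcf(profile: SampleProfile, path: PathLike,
              info_freq_keys: Mapping[str, str] = DEFAULT_INFO_FREQ_KEYS) -> None:
    """Write a profile as a single-sample VCF v4.2 (round-trips through read_vcf)."""
    import pysam

    header = pysam.VariantHeader()
    for chrom in CANONICAL_CHROMS:
        header.add_line(f"##contig=<ID={chrom}>")
    header.add_line(f"##graftrace_role={profile.role}")
    header.add_line(f"##graftrace_sex={profile.sex}")
    header.add_line('##INFO=<ID=FCLASS,Number=1,Type=String,Description="Functional class">')
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    for db, key_name in info_freq_keys.items():
        header.add_line(
            f'##INFO=<ID={key_name},Number=1,Type=Float,'
            f'Description="{db} population allele frequency">'
        )
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_sample(profile.sample_id)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for ov in profile:
            k = ov.key
            rec = out.new_record(
                contig=k.chrom, start=k.pos - 1, alleles=(k.ref, k.alt)
            )
            rec.info["FCLASS"] = ov.variant.functional_class
            if ov.variant.gene:
                rec.info["GENE"] = ov.variant.gene
            for db, key_name in info_freq_keys.items():
                f = ov.variant.db_freqs.get(db)
                if f is not None:
                    rec.info[key_name] = f
            rec.samples[profile.sample_id]["AD"] = (ov.depth - ov.alt_depth, ov.alt_depth)
            rec.samples[profile.sample_id]["DP"] = ov.depth
            out.write(rec)


# ---------------------------------------------------------------------------
# profile TSV
# ---------------------------------------------------------------------------

def profile_to_frame(profile: SampleProfile) -> pd.DataFrame:
    """Tabular view of a profile (one row per variant, canonical order)."""
    rows = []
    for ov in profile:
        k = ov.key
        row = {
            "chrom": k.chrom,
            "pos": k.pos,
            "ref": k.ref,
            "alt": k.alt,
            "functional_class": ov.variant.functional_class,
            "gene": ov.variant.gene,
            "depth": ov.depth,
            "alt_depth": ov.alt_depth,
            "af": ov.af,
        }
        for db in DB_NAMES:
            row[TSV_FREQ_COLUMNS[db]] = ov.variant.db_freqs.get(db)
        rows.append(row)
    return pd.DataFrame(rows, columns=_PROFILE_TSV_COLUMNS)


def write_profile_tsv(profile: SampleProfile, path: PathLike) -> None:
    frame = profile_to_frame(profile)
    with open(path, "w") as fh:
        fh.write(f"#sample_id={profile.sample_id}\n")
        fh.write(f"#role={profile.role}\n")
        fh.write(f"#sex={profile.sex}\n")
        frame.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_profile_tsv(path: PathLike, role: Optional[str] = None,
                     sex: Optional[str] = None,
                     sample_id: Optional[str] = None) -> SampleProfile:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#") and "=" in line:
                k, _, v = line[1:].strip().partition("=")
                meta[k] = v
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        frame = pd.read_csv(fh, sep="\t", na_values=["NA"], dtype={"chrom": str})
    sample_id = sample_id or meta.get("sample_id", Path(path).stem)
    role = role or meta.get("role", "recipient_tumor")
    sex = sex or meta.get("sex", "unknown")

    freq_loc = {db: frame.columns.get_loc(TSV_FREQ_COLUMNS[db])
                for db in DB_NAMES if TSV_FREQ_COLUMNS[db] in frame.columns}
    observed = []
    for row in frame.itertuples(index=False):
        key = VariantKey.build(row.chrom, int(row.pos), row.ref, row.alt)
        freqs = {}
        for db, loc in freq_loc.items():
            val = row[loc]
            if val is not None and not pd.isna(val):
                freqs[db] = float(val)
        gene = row.gene if isinstance(row.gene, str) else None
        annot = AnnotatedVariant(key, row.functional_class, gene=gene, db_freqs=freqs)
        depth = int(row.depth)
        observed.append(ObservedVariant(annot, depth, int(row.alt_depth)))
    return SampleProfile(sample_id, role, sex, observed)


def write_profile(profile: SampleProfile, path: PathLike, format: str = "vcf") -> None:
    """Write a profile as ``vcf`` or ``tsv``."""
    if format == "vcf":
        write_vcf(profile, path)
    elif format == "tsv":
        write_profile_tsv(profile, path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'vcf' or 'tsv'")


def read_profile(path: PathLike, **kwargs) -> SampleProfile:
    """Read a profile, dispatching on extension (.vcf / .tsv)."""
    suffix = Path(path).suffix.lower()
    if suffix in {".vcf", ".gz", ".bcf"}:
        return read_vcf(path, **kwargs)
    return read_profile_tsv(path, **kwargs)


# ---------------------------------------------------------------------------
# annotation TSV
# ---------------------------------------------------------------------------

def read_annotation_table(path: PathLike) -> list[AnnotatedVariant]:
    """Read an annotation TSV into a list of :class:`AnnotatedVariant`.

    Unknown functional-class labels and duplicate keys are hard errors naming
    the offending row; blank frequency cells mean "not observed in that
    database" and produce no entry in ``db_freqs``.
    """
    frame = pd.read_csv(path, sep="\t", na_values=["NA", ""], dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "functional_class"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")

    # positional access: pandas mangles non-identifier headers like "1000G_af"
    freq_loc = {db: frame.columns.get_loc(TSV_FREQ_COLUMNS[db])
                for db in DB_NAMES if TSV_FREQ_COLUMNS[db] in frame.columns}
    gene_loc = frame.columns.get_loc("gene") if "gene" in frame.columns else None

    out: list[AnnotatedVariant] = []
    seen: set[VariantKey] = set()
    valid = set(FUNCTIONAL_CLASSES)
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        fclass = row.functional_class
        if fclass not in valid:
            raise FormatError(
                f"{path} line {idx}: unknown functional class {fclass!r}"
            )
        key = VariantKey.build(row.chrom, int(row.pos), row.ref, row.alt)
        if key in seen:
            raise FormatError(f"{path} line {idx}: duplicate variant key {key}")
        seen.add(key)
        freqs = {}
        for db, loc in freq_loc.items():
            val = row[loc]
            if val is not None and not pd.isna(val):
                freqs[db] = float(val)
        gene = row[gene_loc] if gene_loc is not None else None
        gene = gene if isinstance(gene, str) else None
        out.append(AnnotatedVariant(key, fclass, gene=gene, db_freqs=freqs))
    return out


def attach_annotations(
    profile: SampleProfile, annotations: Iterable[AnnotatedVariant]
) -> SampleProfile:
    """Replace each observation's annotation with the sidecar's, by key."""
    by_key = {a.key: a for a in annotations}
    merged = []
    for ov in profile:
        annot = by_key.get(ov.key)
        if annot is None:
            merged.append(ov)
        else:
            merged.append(ObservedVariant(annot, ov.depth, ov.alt_depth))
    return SampleProfile(profile.sample_id, profile.role, profile.sex, merged)


# ---------------------------------------------------------------------------
# MLPA probe tables
# ---------------------------------------------------------------------------

def read_mlpa_table(path: PathLike) -> pd.DataFrame:
    """Read an MLPA peak table (probe_id, chrom, pos, gene, peak_height)."""
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str, "probe_id": str})
    missing = set(MLPA_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing MLPA columns {sorted(missing)}")
    return frame


def write_mlpa_table(frame: pd.DataFrame, path: PathLike) -> None:
    frame.to_csv(path, sep="\t", index=False, columns=list(MLPA_COLUMNS))
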