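"""Synthetic transplant-cohort simulator.

Generates everything the downstream pipeline consumes, with full ground
truth: a population frequency catalog emulating the reference databases,
donor and recipient germlines drawn from it under Hardy-Weinberg genotype
frequencies, a donor tumor with truncal and subclonal drivers and a focal
homozygous deletion, lesions rendered at chosen purities under binomial
depth sampling, and MLPA probe peak tables.

The observation model is diploid and copy-neutral except inside configured
CNV regions.  For a lesion of purity ``p`` growing in a host:

* a somatic variant carried by a clone of fraction ``c`` has expected
  allelic fraction ``p * 0.5 * c`` (heterozygous, diploid);
* a tumor-lineage germline variant (the donor's, when the lesion is
  donor-derived) is diluted to ``p * af_true``, so a male donor's hemizygous
  chrY variants appear at expected AF ``p`` in a female recipient's lesion;
* the host's own germline variants are observed at their constitutional AF
  (0.5 het / 1.0 hom) irrespective of purity;
* when a key collides (a polymorphism carried by both individuals) the
  larger expected AF wins and the collision is recorded.

Read depth is Poisson around the configured mean, alt reads are binomial,
and a variant is emitted iff at least one alt read is drawn — a minimal
caller-detection model.  The 1% LNA-PCR detection limit is carried as a
``detection_limit_af`` parameter and affects only detectability flags,
never emission.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .variants import (
    DB_NAMES,
    FUNCTIONAL_CLASSES,
    AnnotatedVariant,
    GraftraceError,
    ObservedVariant,
    SampleProfile,
    VariantKey,
)
from . import variant_io

__all__ = [
    "CloneSpec",
    "CnvSpec",
    "RecipientSpec",
    "SampleSpec",
    "MlpaSpec",
    "CohortConfig",
    "FrequencyCatalog",
    "GermlineTruth",
    "TumorTruth",
    "CohortTruth",
    "Cohort",
    "default_config",
    "simulate_catalog",
    "simulate_germline",
    "simulate_tumor_truth",
    "render_observed_sample",
    "simulate_mlpa",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]


class ConfigError(GraftraceError):
    pass


# approximate GRCh37 chromosome lengths, for drawing positions
CHROM_LENGTHS: dict[str, int] = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566, "X": 155_270_560, "Y": 59_373_566,
}
_AUTOSOMES_X = tuple(str(i) for i in range(1, 23)) + ("X",)

#: default functional-class mix, shaped like a whole-exome call set
#: (capture regions plus flanking non-exonic calls dominate)
DEFAULT_CLASS_PROBS: dict[str, float] = {
    "utr_or_unspecified_exonic": 0.0614,
    "indel": 0.0025,
    "nonsynonymous": 0.0894,
    "nonsense": 0.0007,
    "synonymous": 0.0979,
    "splice_site": 0.0008,
    "non_exonic_or_ncRNA": 0.7473,
}

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# configuration models
# ---------------------------------------------------------------------------

class CloneSpec(BaseModel):
    clone_id: str
    fraction: float = Field(gt=0.0, le=1.0)
    private_mutation_count: int = Field(default=0, ge=0)
    #: list of (gene, "chrom:pos:ref:alt") mutations to plant in this clone
    driver_mutations: list[tuple[str, str]] = Field(default_factory=list)


class CnvSpec(BaseModel):
    chrom: str
    start: int = Field(ge=1)
    end: int
    copy_state: Literal["homozygous_loss", "heterozygous_loss", "gain"]
    clone_id: str

    @model_validator(mode="after")
    def _span(self) -> "CnvSpec":
        if self.end <= self.start:
            raise ValueError("CNV end must be greater than start")
        return self

    def contains(self, key: VariantKey) -> bool:
        return key.chrom == self.chrom and self.start <= key.pos <= self.end


class RecipientSpec(BaseModel):
    recipient_id: str
    sex: Literal["male", "female", "unknown"]


class SampleSpec(BaseModel):
    sample_id: str
    role: Literal["donor_tumor", "recipient_blood", "recipient_tumor",
                  "recipient_metastasis"]
    individual: str                      # "donor" or a recipient_id
    source: Literal["donor_tumor", "recipient_self"] = "donor_tumor"
    purity: float = Field(default=1.0, ge=0.0, le=1.0)
    mean_depth: float = Field(default=200.0, gt=0.0)
    dropout: float = Field(default=0.0, ge=0.0, lt=1.0)
    #: per-sample clone-fraction overrides (clone expansion in a lesion)
    clone_fractions: dict[str, float] = Field(default_factory=dict)
    #: somatic mutations private to this lesion (acquired post-transplant)
    private_mutation_count: int = Field(default=0, ge=0)


class MlpaSpec(BaseModel):
    n_region_probes: int = Field(default=10, ge=1)
    n_reference_probes: int = Field(default=8, ge=1)
    n_reference_samples: int = Field(default=3, ge=1)
    noise_sd: float = Field(default=0.03, ge=0.0)


class CohortConfig(BaseModel):
    seed: int = 0
    n_common: int = Field(default=320_000, ge=0)
    n_rare_per_individual: int = Field(default=700, ge=0)
    chry_variants_male: int = Field(default=20, ge=0)
    donor_sex: Literal["male", "female", "unknown"] = "male"
    recipients: list[RecipientSpec] = Field(default_factory=list)
    clones: list[CloneSpec] = Field(default_factory=list)
    cnvs: list[CnvSpec] = Field(default_factory=list)
    samples: list[SampleSpec] = Field(default_factory=list)
    detection_limit_af: float = Field(default=0.01, gt=0.0, le=1.0)
    class_probs: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROBS)
    )
    mlpa: MlpaSpec = Field(default_factory=MlpaSpec)

    @field_validator("class_probs")
    @classmethod
    def _probs(cls, v: dict[str, float]) -> dict[str, float]:
        if set(v) != set(FUNCTIONAL_CLASSES):
            raise ValueError("class_probs must cover exactly the seven classes")
        total = sum(v.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"class_probs must sum to 1, got {total}")
        return v

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        if self.clones:
            if not any(c.fraction == 1.0 for c in self.clones):
                raise ValueError("one clone must be truncal (fraction 1.0)")
        clone_ids = {c.clone_id for c in self.clones}
        for cnv in self.cnvs:
            if cnv.clone_id not in clone_ids:
                raise ValueError(f"CNV carrier clone {cnv.clone_id!r} not defined")
        individuals = {"donor"} | {r.recipient_id for r in self.recipients}
        for s in self.samples:
            if s.individual not in individuals:
                raise ValueError(f"sample {s.sample_id}: unknown individual {s.individual!r}")
        return self


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    """The study-shaped cohort: male donor with a BRAF V600E truncal tumor
    carrying a CDKN2A/B homozygous deletion and a PIK3CA E545K subclone;
    a female liver recipient (blood + omentum metastasis at purity 0.97)
    and two male recipients with lesions at purity 0.78."""
    cfg = dict(
        seed=seed,
        donor_sex="male",
        recipients=[
            RecipientSpec(recipient_id="LR", sex="female"),
            RecipientSpec(recipient_id="KR", sex="male"),
            RecipientSpec(recipient_id="KPR", sex="male"),
        ],
        clones=[
            CloneSpec(
                clone_id="truncal",
                fraction=1.0,
                private_mutation_count=1200,
                driver_mutations=[("BRAF", "7:140453136:A:T")],
            ),
            CloneSpec(
                clone_id="pik3ca_subclone",
                fraction=0.04,
                private_mutation_count=300,
                driver_mutations=[("PIK3CA", "3:178936091:G:A")],
            ),
        ],
        cnvs=[
            CnvSpec(chrom="9", start=21_948_801, end=22_163_300,
                    copy_state="homozygous_loss", clone_id="truncal"),
        ],
        samples=[
            SampleSpec(sample_id="donor_tf", role="donor_tumor",
                       individual="donor", purity=0.50),
            SampleSpec(sample_id="lr_blood", role="recipient_blood",
                       individual="LR"),
            SampleSpec(sample_id="lr_om", role="recipient_metastasis",
                       individual="LR", purity=0.97,
                       clone_fractions={"pik3ca_subclone": 0.92},
                       private_mutation_count=300),
            SampleSpec(sample_id="kr_lesion", role="recipient_tumor",
                       individual="KR", purity=0.78,
                       clone_fractions={"pik3ca_subclone": 1.0},
                       private_mutation_count=300),
            SampleSpec(sample_id="kpr_lesion", role="recipient_tumor",
                       individual="KPR", purity=0.78,
                       clone_fractions={"pik3ca_subclone": 0.46},
                       private_mutation_count=300),
        ],
    )
    cfg.update(overrides)
    return CohortConfig(**cfg)


def load_config(path) -> CohortConfig:
    """Read a cohort config from YAML or JSON."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    return CohortConfig.model_validate(data)


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------

@dataclass
class FrequencyCatalog:
    """Population catalog backed by parallel arrays.

    ``base_freq`` is the latent population frequency used for genotype
    draws; ``db_freqs`` per entry are jittered, per-database views of it.
    ``tier`` is "common" (>= 0.001 in at least two databases by
    construction) or "rare" (every present frequency < 0.001).
    """

    keys: list[VariantKey]
    annots: list[AnnotatedVariant]
    base_freq: np.ndarray
    tier: np.ndarray                     # unicode array of "common"/"rare"

    def __len__(self) -> int:
        return len(self.keys)

    @property
    def common_indices(self) -> np.ndarray:
        return np.flatnonzero(self.tier == "common")

    @property
    def rare_indices(self) -> np.ndarray:
        return np.flatnonzero(self.tier == "rare")


def _draw_keys(rng: np.random.Generator, n: int, used: set,
               chroms: Sequence[str] = _AUTOSOMES_X) -> list[VariantKey]:
    """Draw n unique variant keys on the given chromosomes."""
    lengths = np.array([CHROM_LENGTHS[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    out: list[VariantKey] = []
    while len(out) < n:
        m = n - len(out)
        ci = rng.choice(len(chroms), size=m, p=weights)
        pos = (rng.random(m) * lengths[ci]).astype(np.int64) + 1
        refs = _BASES[rng.integers(0, 4, size=m)]
        alt_off = rng.integers(1, 4, size=m)
        for j in range(m):
            chrom = chroms[ci[j]]
            loc = (chrom, int(pos[j]))
            if loc in used:
                continue
            used.add(loc)
            ref = refs[j]
            alt = _BASES[(np.flatnonzero(_BASES == ref)[0] + alt_off[j]) % 4]
            out.append(VariantKey(chrom, int(pos[j]), str(ref), str(alt)))
    return out


def _draw_classes(rng: np.random.Generator, n: int,
                  class_probs: dict[str, float]) -> list[str]:
    labels = list(class_probs)
    probs = np.array([class_probs[c] for c in labels])
    probs = probs / probs.sum()
    idx = rng.choice(len(labels), size=n, p=probs)
    return [labels[i] for i in idx]


def simulate_catalog(config: CohortConfig,
                     rng: Optional[np.random.Generator] = None,
                     used_positions: Optional[set] = None) -> FrequencyCatalog:
    """Generate the population frequency catalog for a cohort.

    Common entries carry a base frequency uniform in [0.001, 0.5] and are
    present at >= 0.001 in at least two databases; rare entries are present
    in a random subset of databases (possibly none) at frequencies uniform
    in [1e-6, 9e-4].
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    used = used_positions if used_positions is not None else set()
    n_rare = config.n_rare_per_individual * (1 + len(config.recipients))

    keys: list[VariantKey] = []
    annots: list[AnnotatedVariant] = []
    base: list[float] = []
    tier: list[str] = []

    # common tier
    common_keys = _draw_keys(rng, config.n_common, used)
    classes = _draw_classes(rng, config.n_common, config.class_probs)
    f = rng.uniform(0.001, 0.5, size=config.n_common)
    present = rng.random((config.n_common, len(DB_NAMES))) < 0.9
    # guarantee the common predicate: at least two databases present
    too_few = present.sum(axis=1) < 2
    present[too_few, 0] = True
    present[too_few, 1] = True
    jitter = rng.normal(1.0, 0.1, size=(config.n_common, len(DB_NAMES)))
    vals = np.clip(f[:, None] * jitter, 0.001, 0.999)
    for i, key in enumerate(common_keys):
        freqs = {DB_NAMES[d]: float(vals[i, d])
                 for d in range(len(DB_NAMES)) if present[i, d]}
        keys.append(key)
        annots.append(AnnotatedVariant(key, classes[i], db_freqs=freqs))
        base.append(float(f[i]))
        tier.append("common")

    # rare tier
    rare_keys = _draw_keys(rng, n_rare, used)
    classes = _draw_classes(rng, n_rare, config.class_probs)
    present = rng.random((n_rare, len(DB_NAMES))) < 0.5
    vals = rng.uniform(1e-6, 9e-4, size=(n_rare, len(DB_NAMES)))
    for i, key in enumerate(rare_keys):
        freqs = {DB_NAMES[d]: float(vals[i, d])
                 for d in range(len(DB_NAMES)) if present[i, d]}
        keys.append(key)
        annots.append(AnnotatedVariant(key, classes[i], db_freqs=freqs))
        base.append(float(rng.uniform(1e-5, 5e-4)))
        tier.append("rare")

    return FrequencyCatalog(
        keys=keys,
        annots=annots,
        base_freq=np.array(base),
        tier=np.array(tier, dtype="U6"),
    )


# ---------------------------------------------------------------------------
# germline and tumor truth
# ---------------------------------------------------------------------------

@dataclass
class GermlineTruth:
    """An individual's constitutional variants with true allelic fractions."""

    individual_id: str
    sex: str
    variants: dict[VariantKey, tuple[AnnotatedVariant, float]]  # key -> (annot, af_true)
    tiers: dict[VariantKey, str]                                # common | rare

    def __len__(self) -> int:
        return len(self.variants)

    def chry_count(self) -> int:
        return sum(1 for k in self.variants if k.chrom == "Y")


def simulate_germline(
    catalog: FrequencyCatalog,
    sex: str,
    config: CohortConfig,
    rng: np.random.Generator,
    individual_id: str,
    rare_indices: Optional[np.ndarray] = None,
    used_positions: Optional[set] = None,
) -> GermlineTruth:
    """Draw one germline from the catalog under Hardy-Weinberg genotypes.

    Common-tier entries are carried hom with probability f^2 and het with
    2f(1-f); ``rare_indices`` selects this individual's private rare
    variants (het).  A male germline additionally carries
    ``config.chry_variants_male`` hemizygous chrY variants (AF 1.0);
    a female germline carries none.
    """
    variants: dict[VariantKey, tuple[AnnotatedVariant, float]] = {}
    tiers: dict[VariantKey, str] = {}

    common = catalog.common_indices
    f = catalog.base_freq[common]
    u = rng.random(len(common))
    hom = u < f * f
    het = (~hom) & (u < f * f + 2 * f * (1 - f))
    for idx in common[hom]:
        key = catalog.keys[idx]
        variants[key] = (catalog.annots[idx], 1.0)
        tiers[key] = "common"
    for idx in common[het]:
        key = catalog.keys[idx]
        variants[key] = (catalog.annots[idx], 0.5)
        tiers[key] = "common"

    if rare_indices is not None:
        for idx in rare_indices:
            key = catalog.keys[int(idx)]
            variants[key] = (catalog.annots[int(idx)], 0.5)
            tiers[key] = "rare"

    if sex == "male" and config.chry_variants_male > 0:
        used = used_positions if used_positions is not None else set()
        y_keys = _draw_keys(rng, config.chry_variants_male, used, chroms=("Y",))
        y_classes = _draw_classes(rng, len(y_keys), config.class_probs)
        for key, fclass in zip(y_keys, y_classes):
            variants[key] = (AnnotatedVariant(key, fclass), 1.0)
            tiers[key] = "rare"

    return GermlineTruth(individual_id, sex, variants, tiers)


@dataclass(frozen=True)
class SomaticVariant:
    annot: AnnotatedVariant
    clone_id: str
    clone_fraction: float

    @property
    def af_pure(self) -> float:
        """Expected AF in a purity-1.0 tumor (het, diploid): 0.5 x fraction."""
        return 0.5 * self.clone_fraction


@dataclass
class TumorTruth:
    """A tumor lineage: its germline plus clone-assigned somatic variants."""

    germline: GermlineTruth
    somatic: dict[VariantKey, SomaticVariant]
    cnvs: list[CnvSpec] = dc_field(default_factory=list)


def simulate_tumor_truth(
    germline: GermlineTruth,
    clones: Sequence[CloneSpec],
    cnvs: Sequence[CnvSpec],
    config: CohortConfig,
    rng: np.random.Generator,
    used_positions: Optional[set] = None,
) -> TumorTruth:
    """Assign somatic mutations to clones on top of a germline.

    Each clone receives its planted drivers plus ``private_mutation_count``
    random somatic variants (no database frequencies: they are novel).
    Somatic variants falling inside a homozygous-loss CNV carried by their
    own clone are removed from emission — both alleles are gone — and a
    driver explicitly planted inside its own loss is a configuration error.
    Germline variants are retained regardless of CNVs (the copy-neutral
    simplification documented in the methods note).
    """
    used = used_positions if used_positions is not None else set()
    somatic: dict[VariantKey, SomaticVariant] = {}
    hom_losses = [c for c in cnvs if c.copy_state == "homozygous_loss"]

    for clone in clones:
        for gene, key_text in clone.driver_mutations:
            key = VariantKey.parse(key_text)
            for cnv in hom_losses:
                if cnv.clone_id == clone.clone_id and cnv.contains(key):
                    raise ConfigError(
                        f"driver {gene} at {key} planted inside its own "
                        f"homozygous loss {cnv.chrom}:{cnv.start}-{cnv.end}"
                    )
            used.add((key.chrom, key.pos))
            annot = AnnotatedVariant(key, "nonsynonymous", gene=gene)
            somatic[key] = SomaticVariant(annot, clone.clone_id, clone.fraction)

        keys = _draw_keys(rng, clone.private_mutation_count, used)
        classes = _draw_classes(rng, len(keys), config.class_probs)
        for i, key in enumerate(keys):
            lost = any(
                cnv.clone_id == clone.clone_id and cnv.contains(key)
                for cnv in hom_losses
            )
            if lost:
                continue
            gene = f"GENE{rng.integers(0, 10**7):07d}" if classes[i] != "non_exonic_or_ncRNA" else None
            annot = AnnotatedVariant(key, classes[i], gene=gene)
            somatic[key] = SomaticVariant(annot, clone.clone_id, clone.fraction)

    return TumorTruth(germline, somatic, list(cnvs))


# ---------------------------------------------------------------------------
# rendering observed samples
# ---------------------------------------------------------------------------

def render_observed_sample(
    truth: TumorTruth,
    host_germline: GermlineTruth,
    purity: float,
    mean_depth: float,
    rng: np.random.Generator,
    sample_id: str,
    role: str = "recipient_tumor",
    dropout: float = 0.0,
    clone_fractions: Optional[dict[str, float]] = None,
    private_mutations: Sequence[SomaticVariant] = (),
) -> tuple[SampleProfile, dict[VariantKey, str]]:
    """Render one observed sample; returns (profile, per-variant origins).

    Expected AFs follow the module docstring's observation model.  Returns
    the per-variant origin labels actually used, with key collisions
    resolved to the larger expected AF and annotated ``...+host_germline``.
    """
    if not (0.0 <= purity <= 1.0):
        raise ValueError("purity must be in [0, 1]")
    overrides = clone_fractions or {}
    same_individual = truth.germline.individual_id == host_germline.individual_id

    eaf: dict[VariantKey, float] = {}
    origin: dict[VariantKey, str] = {}
    annots: dict[VariantKey, AnnotatedVariant] = {}

    donor_side = "donor" if truth.germline.individual_id == "donor" else truth.germline.individual_id
    for key, (annot, af_true) in truth.germline.variants.items():
        eaf[key] = af_true if same_individual else purity * af_true
        tier = truth.germline.tiers[key]
        origin[key] = f"{donor_side}_germline_{tier}" if donor_side == "donor" else "recipient_germline"
        annots[key] = annot

    for key, sv in truth.somatic.items():
        frac = overrides.get(sv.clone_id, sv.clone_fraction)
        value = purity * 0.5 * frac
        if key not in eaf or value > eaf[key]:
            if sv.clone_fraction == 1.0:
                origin[key] = "somatic_truncal"
            else:
                origin[key] = f"somatic_subclonal:{sv.clone_id}"
            eaf[key] = value
            annots[key] = sv.annot

    if not same_individual:
        for key, (annot, af_true) in host_germline.variants.items():
            if key in eaf:
                if af_true >= eaf[key]:
                    eaf[key] = af_true
                    origin[key] = origin[key] + "+host_germline"
                    annots[key] = annot
            else:
                eaf[key] = af_true
                origin[key] = "recipient_germline"
                annots[key] = annot

    for sv in private_mutations:
        key = sv.annot.key
        eaf[key] = purity * sv.af_pure
        origin[key] = "post_transplant_private"
        annots[key] = sv.annot

    keys = list(eaf)
    n = len(keys)
    afs = np.array([eaf[k] for k in keys])
    keep = np.ones(n, dtype=bool)
    if dropout > 0:
        keep = rng.random(n) >= dropout
    depths = rng.poisson(mean_depth, size=n)
    alts = rng.binomial(depths, np.clip(afs, 0.0, 1.0))
    emitted = keep & (alts >= 1)

    observed = []
    origins_out: dict[VariantKey, str] = {}
    for i in np.flatnonzero(emitted):
        key = keys[i]
        observed.append(ObservedVariant(annots[key], int(depths[i]), int(alts[i])))
        origins_out[key] = origin[key]
    profile = SampleProfile(sample_id, role, host_germline.sex, observed)
    return profile, origins_out


# ---------------------------------------------------------------------------
# MLPA simulation
# ---------------------------------------------------------------------------

def build_probe_panel(cnvs: Sequence[CnvSpec], mlpa: MlpaSpec) -> pd.DataFrame:
    """Deterministic probe layout: test probes tiling each CNV span plus
    reference probes on unrelated chromosomes."""
    rows = []
    for cnv in cnvs or [CnvSpec(chrom="9", start=21_948_801, end=22_163_300,
                                copy_state="homozygous_loss", clone_id="truncal")]:
        span = cnv.end - cnv.start
        for i in range(mlpa.n_region_probes):
            pos = cnv.start + int(round(span * (i + 0.5) / mlpa.n_region_probes))
            gene = "CDKN2A" if i < mlpa.n_region_probes / 2 else "CDKN2B"
            rows.append({
                "probe_id": f"{cnv.chrom}_{i:02d}",
                "chrom": cnv.chrom, "pos": pos, "gene": gene,
            })
    ref_chroms = ["2", "5", "7", "11", "13", "16", "18", "20"]
    for i in range(mlpa.n_reference_probes):
        chrom = ref_chroms[i % len(ref_chroms)]
        rows.append({
            "probe_id": f"REF_{i:02d}",
            "chrom": chrom,
            "pos": 10_000_000 + 1_000_000 * i,
            "gene": f"REF{i:02d}",
        })
    return pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "gene"])


def expected_probe_ratio(chrom: str, pos: int, cnvs: Sequence[CnvSpec],
                         purity: float) -> float:
    """Expected MLPA ratio at a probe: residual normal cells keep signal,
    so a homozygous loss at purity p gives 1 - p, a het loss 1 - p/2,
    a gain 1 + p/2, and 1.0 outside any CNV."""
    for cnv in cnvs:
        if cnv.chrom == chrom and cnv.start <= pos <= cnv.end:
            if cnv.copy_state == "homozygous_loss":
                return 1.0 - purity
            if cnv.copy_state == "heterozygous_loss":
                return 1.0 - purity / 2.0
            return 1.0 + purity / 2.0
    return 1.0


def simulate_mlpa(
    cnvs: Sequence[CnvSpec],
    purity: float,
    mlpa: MlpaSpec,
    rng: np.random.Generator,
    panel: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, list[pd.DataFrame]]:
    """Simulate one sample's peak table plus reference-sample peak tables.

    Peaks are scaled so that the normalized ratio of each test probe equals
    its expected ratio plus Normal(0, noise_sd) noise; every sample also
    receives a global scale factor, which intra-normalization must undo.
    """
    if panel is None:
        panel = build_probe_panel(cnvs, mlpa)
    base = 100.0

    refs = []
    for _ in range(mlpa.n_reference_samples):
        scale = rng.uniform(0.8, 1.25)
        noise = rng.normal(0.0, mlpa.noise_sd, size=len(panel))
        peaks = base * scale * np.clip(1.0 + noise, 0.01, None)
        ref = panel.copy()
        ref["peak_height"] = peaks
        refs.append(ref)

    scale = rng.uniform(0.8, 1.25)
    expected = np.array([
        expected_probe_ratio(row.chrom, row.pos, cnvs, purity)
        if not str(row.gene).startswith("REF") else 1.0
        for row in panel.itertuples(index=False)
    ])
    noise = rng.normal(0.0, mlpa.noise_sd, size=len(panel))
    # reference probes carry plain noise; test probes carry expected + noise
    is_ref = panel["gene"].astype(str).str.startswith("REF").to_numpy()
    ratios = np.where(is_ref, np.clip(1.0 + noise, 0.01, None),
                      np.clip(expected + noise, 0.0, None))
    sample = panel.copy()
    sample["peak_height"] = base * scale * ratios
    return sample, refs


# ---------------------------------------------------------------------------
# whole-cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class CohortTruth:
    """Ground truth for a simulated cohort."""

    origins: dict[str, str]                       # "chrom:pos:ref:alt" -> label
    sample_purity: dict[str, float]
    sample_origins: dict[str, dict[str, str]]     # per-sample emitted origins
    clone_fractions: dict[str, float]
    sample_clone_fractions: dict[str, dict[str, float]]
    cnvs: list[dict]
    detection_limit_af: float

    def to_json(self, path) -> None:
        payload = {
            "origins": self.origins,
            "sample_purity": self.sample_purity,
            "sample_origins": self.sample_origins,
            "clone_fractions": self.clone_fractions,
            "sample_clone_fractions": self.sample_clone_fractions,
            "cnvs": self.cnvs,
            "detection_limit_af": self.detection_limit_af,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "CohortTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            origins=d["origins"],
            sample_purity=d["sample_purity"],
            sample_origins=d["sample_origins"],
            clone_fractions=d["clone_fractions"],
            sample_clone_fractions=d["sample_clone_fractions"],
            cnvs=d["cnvs"],
            detection_limit_af=d["detection_limit_af"],
        )


@dataclass
class Cohort:
    config: CohortConfig
    samples: dict[str, SampleProfile]
    truth: CohortTruth
    mlpa_samples: dict[str, pd.DataFrame]
    mlpa_references: dict[str, pd.DataFrame]


_ORIGIN_PRIORITY = (
    "somatic_truncal", "somatic_subclonal", "post_transplant_private",
    "donor_germline_rare", "donor_germline_common", "recipient_germline",
)


def _merge_origin(existing: Optional[str], new: str) -> str:
    if existing is None or existing == new:
        return new
    def rank(label: str) -> int:
        for i, prefix in enumerate(_ORIGIN_PRIORITY):
            if label.startswith(prefix):
                return i
        return len(_ORIGIN_PRIORITY)
    return existing if rank(existing) <= rank(new) else new


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full cohort: catalog, germlines, tumors, samples, MLPA.

    Deterministic: identical config (seed included) gives identical output.
    """
    rng = np.random.default_rng(config.seed)
    used: set = set()
    catalog = simulate_catalog(config, rng, used)

    # disjoint private rare allocations per individual
    rare = catalog.rare_indices
    individuals = ["donor"] + [r.recipient_id for r in config.recipients]
    n_per = config.n_rare_per_individual
    rare_alloc = {
        ind: rare[i * n_per:(i + 1) * n_per] for i, ind in enumerate(individuals)
    }

    germlines: dict[str, GermlineTruth] = {}
    sexes = {"donor": config.donor_sex}
    sexes.update({r.recipient_id: r.sex for r in config.recipients})
    for ind in individuals:
        germlines[ind] = simulate_germline(
            catalog, sexes[ind], config, rng, ind, rare_alloc[ind], used
        )

    donor_tumor_truth = simulate_tumor_truth(
        germlines["donor"], config.clones, config.cnvs, config, rng, used
    )
    self_truths: dict[str, TumorTruth] = {}
    for spec in config.samples:
        if spec.source == "recipient_self" and spec.individual not in self_truths \
                and spec.role != "recipient_blood":
            # a recipient-origin tumor has its own mutational history: same
            # clonal architecture, fresh variants, none of the donor's drivers
            own_clones = [
                CloneSpec(
                    clone_id=c.clone_id,
                    fraction=c.fraction,
                    private_mutation_count=c.private_mutation_count,
                    driver_mutations=[],
                )
                for c in config.clones
            ]
            self_truths[spec.individual] = simulate_tumor_truth(
                germlines[spec.individual], own_clones, [], config, rng, used
            )

    samples: dict[str, SampleProfile] = {}
    sample_origins: dict[str, dict[str, str]] = {}
    global_origins: dict[str, str] = {}
    mlpa_samples: dict[str, pd.DataFrame] = {}
    mlpa_refs: dict[str, pd.DataFrame] = {}
    panel = build_probe_panel(config.cnvs, config.mlpa)

    ref_ids = ["NA12878", "NA12891", "NA12892"]
    for spec in config.samples:
        host = germlines[spec.individual]
        if spec.role == "recipient_blood":
            truth = TumorTruth(host, {}, [])
            purity = 0.0
        elif spec.source == "donor_tumor":
            truth = donor_tumor_truth
            purity = spec.purity
        else:
            truth = self_truths[spec.individual]
            purity = spec.purity

        private: list[SomaticVariant] = []
        if spec.private_mutation_count > 0:
            keys = _draw_keys(rng, spec.private_mutation_count, used)
            classes = _draw_classes(rng, len(keys), config.class_probs)
            private = [
                SomaticVariant(AnnotatedVariant(k, c), f"private_{spec.sample_id}", 1.0)
                for k, c in zip(keys, classes)
            ]

        profile, origins = render_observed_sample(
            truth, host, purity, spec.mean_depth, rng, spec.sample_id,
            role=spec.role, dropout=spec.dropout,
            clone_fractions=spec.clone_fractions, private_mutations=private,
        )
        samples[spec.sample_id] = profile
        sample_origins[spec.sample_id] = {str(k): v for k, v in origins.items()}
        for k, v in origins.items():
            base_label = v.split("+")[0]
            global_origins[str(k)] = _merge_origin(global_origins.get(str(k)), base_label)

        if spec.role != "recipient_blood":
            cnvs = truth.cnvs
            sample_peaks, refs = simulate_mlpa(cnvs, purity, config.mlpa, rng, panel)
            mlpa_samples[spec.sample_id] = sample_peaks
            if not mlpa_refs:
                for rid, ref in zip(ref_ids, refs):
                    mlpa_refs[rid] = ref

    truth = CohortTruth(
        origins=global_origins,
        sample_purity={s.sample_id: s.purity for s in config.samples
                       if s.role != "recipient_blood"},
        sample_origins=sample_origins,
        clone_fractions={c.clone_id: c.fraction for c in config.clones},
        sample_clone_fractions={s.sample_id: dict(s.clone_fractions)
                                for s in config.samples},
        cnvs=[c.model_dump() for c in config.cnvs],
        detection_limit_af=config.detection_limit_af,
    )
    return Cohort(config, samples, truth, mlpa_samples, mlpa_refs)


def write_cohort(cohort_or_config: Union[Cohort, CohortConfig], outdir) -> Cohort:
    """Write a cohort to ``outdir``: per-sample VCF + TSV, MLPA TSVs,
    truth.json and config.json.  Returns the (possibly freshly simulated)
    cohort."""
    cohort = (
        cohort_or_config
        if isinstance(cohort_or_config, Cohort)
        else simulate_cohort(cohort_or_config)
    )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sid, profile in cohort.samples.items():
        variant_io.write_vcf(profile, outdir / f"{sid}.vcf")
        variant_io.write_profile_tsv(profile, outdir / f"{sid}.tsv")
    for sid, frame in cohort.mlpa_samples.items():
        variant_io.write_mlpa_table(frame, outdir / f"mlpa_{sid}.tsv")
    for rid, frame in cohort.mlpa_references.items():
        variant_io.write_mlpa_table(frame, outdir / f"mlpa_ref_{rid}.tsv")
    cohort.truth.to_json(outdir / "truth.json")
    with open(outdir / "config.json", "w") as fh:
        fh.write(cohort.config.model_dump_json(indent=1))
    return cohort


def read_cohort(outdir) -> Cohort:
    """Re-read a cohort previously written by :func:`write_cohort`."""
    outdir = Path(outdir)
    with open(outdir / "config.json") as fh:
        config = CohortConfig.model_validate_json(fh.read())
    samples = {
        spec.sample_id: variant_io.read_vcf(outdir / f"{spec.sample_id}.vcf")
        for spec in config.samples
    }
    truth = CohortTruth.from_json(outdir / "truth.json")
    mlpa_samples = {}
    mlpa_refs = {}
    for path in sorted(outdir.glob("mlpa_*.tsv")):
        name = path.stem[len("mlpa_"):]
        if name.startswith("ref_"):
            mlpa_refs[name[len("ref_"):]] = variant_io.read_mlpa_table(path)
        else:
            mlpa_samples[name] = variant_io.read_mlpa_table(path)
    return Cohort(config, samples, truth, mlpa_samples, mlpa_refs)
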