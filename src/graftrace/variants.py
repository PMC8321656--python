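"""Core domain types: variant identity, annotation, observation, sample profiles.

Variant identity is the tuple (chrom, pos, ref, alt) after normalization:
a leading ``chr`` prefix is stripped, alleles are uppercased, and only the
canonical human chromosomes 1-22, X, Y are admitted.  Coordinates are 1-based
per VCF convention.  No indel left-normalization is attempted; inputs are
assumed caller-normalized, because variant matching across samples is pure
key equality and silent re-normalization would corrupt the set arithmetic
the whole pipeline rests on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

__all__ = [
    "CANONICAL_CHROMS",
    "CHROM_RANK",
    "FUNCTIONAL_CLASSES",
    "CODING_CLASSES",
    "ROLES",
    "SEXES",
    "DB_NAMES",
    "GraftraceError",
    "FormatError",
    "normalize_chrom",
    "VariantKey",
    "AnnotatedVariant",
    "ObservedVariant",
    "SampleProfile",
]

#: canonical chromosome labels in sort order
CANONICAL_CHROMS: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
CHROM_RANK: dict[str, int] = {c: i for i, c in enumerate(CANONICAL_CHROMS)}

#: the seven mutually exclusive functional classes used for variant counting
FUNCTIONAL_CLASSES: tuple[str, ...] = (
    "utr_or_unspecified_exonic",
    "indel",
    "nonsynonymous",
    "nonsense",
    "synonymous",
    "splice_site",
    "non_exonic_or_ncRNA",
)
_CLASS_SET = frozenset(FUNCTIONAL_CLASSES)

#: classes counted as coding for shared-variant analyses
CODING_CLASSES: frozenset[str] = frozenset(FUNCTIONAL_CLASSES[:-1])

ROLES: frozenset[str] = frozenset(
    {"donor_tumor", "recipient_blood", "recipient_tumor", "recipient_metastasis"}
)
SEXES: frozenset[str] = frozenset({"male", "female", "unknown"})

#: population databases consulted for common-polymorphism filtering
DB_NAMES: tuple[str, ...] = ("1000G", "HapMap", "dbSNP", "ExAC", "gnomAD")

_ALLELE_CHARS = frozenset("ACGTN")


class GraftraceError(Exception):
    """Base class for all package errors."""


class FormatError(GraftraceError):
    """A file or record violates the expected format."""


def normalize_chrom(label: str) -> Optional[str]:
    """Normalize a chromosome label; return None for non-canonical contigs.

    Strips a leading ``chr``/``Chr``/``CHR`` prefix and uppercases X/Y.
    MT, decoys, alt contigs etc. map to None and are dropped by readers.
    """
    c = str(label).strip()
    if c[:3].lower() == "chr":
        c = c[3:]
    c = c.upper()
    if c == "23":
        c = "X"
    elif c == "24":
        c = "Y"
    return c if c in CHROM_RANK else None


@dataclass(frozen=True, slots=True)
class VariantKey:
    """Identity of a variant: (chrom, pos, ref, alt), totally ordered.

    Ordering is chromosome 1..22, X, Y, then position, then ref, then alt.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.chrom not in CHROM_RANK:
            raise ValueError(f"non-canonical chromosome {self.chrom!r}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) is not a variant")

    @classmethod
    def build(cls, chrom: str, pos: int, ref: str, alt: str) -> "VariantKey":
        """Construct a key from raw labels, normalizing chrom and allele case."""
        norm = normalize_chrom(chrom)
        if norm is None:
            raise ValueError(f"non-canonical chromosome {chrom!r}")
        return cls(norm, int(pos), str(ref).upper(), str(alt).upper())

    @property
    def sort_key(self) -> tuple[int, int, str, str]:
        return (CHROM_RANK[self.chrom], self.pos, self.ref, self.alt)

    def __lt__(self, other: "VariantKey") -> bool:
        return self.sort_key < other.sort_key

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        """Parse ``chrom:pos:ref:alt`` (the CLI/JSON key form)."""
        parts = text.split(":")
        if len(parts) != 4:
            raise ValueError(f"expected chrom:pos:ref:alt, got {text!r}")
        return cls.build(parts[0], int(parts[1]), parts[2], parts[3])


@dataclass(frozen=True, slots=True)
class AnnotatedVariant:
    """A variant with its functional class and population frequencies.

    ``db_freqs`` maps database name -> allele frequency in [0, 1].  A database
    absent from the mapping means the variant was not observed there, which is
    deliberately distinct from frequency 0.
    """

    key: VariantKey
    functional_class: str = "utr_or_unspecified_exonic"
    gene: Optional[str] = None
    db_freqs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.functional_class not in _CLASS_SET:
            raise ValueError(
                f"unknown functional class {self.functional_class!r}; "
                f"expected one of {sorted(_CLASS_SET)}"
            )
        for db, f in self.db_freqs.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"frequency for {db} out of [0,1]: {f}")

    @property
    def is_coding(self) -> bool:
        return self.functional_class in CODING_CLASSES

    def freq(self, db: str) -> Optional[float]:
        return self.db_freqs.get(db)


@dataclass(frozen=True, slots=True)
class ObservedVariant:
    """An annotated variant as measured in one sample.

    ``af`` is alt_depth / depth; it is None (undefined) when depth is 0.
    """

    variant: AnnotatedVariant
    depth: int
    alt_depth: int
    af: Optional[float] = None

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not (0 <= self.alt_depth <= self.depth):
            raise ValueError(
                f"alt_depth {self.alt_depth} outside [0, depth={self.depth}]"
            )
        if self.depth == 0:
            if self.af is not None:
                raise ValueError("af must be undefined (None) when depth is 0")
        else:
            expected = self.alt_depth / self.depth
            if self.af is None:
                object.__setattr__(self, "af", expected)
            elif not math.isclose(self.af, expected, abs_tol=1e-9):
                raise ValueError(
                    f"af {self.af} inconsistent with {self.alt_depth}/{self.depth}"
                )

    @property
    def key(self) -> VariantKey:
        return self.variant.key


class SampleProfile:
    """A named sample and its variant set, unique and ordered by VariantKey."""

    __slots__ = ("sample_id", "role", "sex", "_by_key", "_order")

    def __init__(
        self,
        sample_id: str,
        role: str,
        sex: str = "unknown",
        variants: Iterable[ObservedVariant] = (),
    ) -> None:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}; expected one of {sorted(ROLES)}")
        if sex not in SEXES:
            raise ValueError(f"unknown sex {sex!r}")
        self.sample_id = sample_id
        self.role = role
        self.sex = sex
        by_key: dict[VariantKey, ObservedVariant] = {}
        for ov in variants:
            k = ov.key
            if k in by_key:
                raise ValueError(f"duplicate variant key {k} in sample {sample_id!r}")
            by_key[k] = ov
        self._by_key = by_key
        self._order = sorted(by_key, key=lambda k: k.sort_key)

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self) -> Iterator[ObservedVariant]:
        return (self._by_key[k] for k in self._order)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._by_key

    def get(self, key: VariantKey) -> Optional[ObservedVariant]:
        return self._by_key.get(key)

    def keys(self) -> frozenset[VariantKey]:
        return frozenset(self._by_key)

    def ordered_keys(self) -> list[VariantKey]:
        return list(self._order)

    def subset(self, keys: Iterable[VariantKey], sample_id: Optional[str] = None) -> "SampleProfile":
        """New profile restricted to ``keys`` (missing keys are ignored)."""
        wanted = set(keys)
        return SampleProfile(
            sample_id or self.sample_id,
            self.role,
            self.sex,
            (ov for ov in self if ov.key in wanted),
        )

    def chrom_count(self, chrom: str) -> int:
        return sum(1 for k in self._by_key if k.chrom == chrom)

    def __repr__(self) -> str:
        return (
            f"SampleProfile({self.sample_id!r}, role={self.role!r}, "
            f"sex={self.sex!r}, n={len(self)})"
        )
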