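"""Core record types shared by every stage of the analysis.

Coordinates are 1-based inclusive throughout (VCF convention).  Gene
symbols are matched case-insensitively after trimming.  A variant's
"novelty" is encoded purely by the absence of a dbSNP identifier; the
package never queries external databases.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional


class Group(str, enum.Enum):
    """Cohort label: CASE (post-transplant, UCKT) vs CONTROL (hemodialysis, UCHD)."""

    CASE = "CASE"
    CONTROL = "CONTROL"


class ConsequenceClass(str, enum.Enum):
    """Mutation-effect taxonomy.

    FRAMESHIFT is reserved for 1-bp differences between the alleles;
    INDEL covers longer length changes (and any-length changes outside
    the coding region, e.g. UTR deletions).
    """

    SYNONYMOUS = "SYNONYMOUS"
    MISSENSE = "MISSENSE"
    NONSENSE = "NONSENSE"
    FRAMESHIFT = "FRAMESHIFT"
    SPLICE_ACCEPTOR = "SPLICE_ACCEPTOR"
    SPLICE_DONOR = "SPLICE_DONOR"
    NONSTOP = "NONSTOP"
    INDEL = "INDEL"
    OTHER = "OTHER"


@dataclass(frozen=True)
class SampleInfo:
    """One sequenced tumor sample.

    ``patient_id`` may differ from ``sample_id`` when one patient
    contributed several tumors (e.g. samples KT80 and KT721 in the
    motivating cohort came from one patient at different surgeries).
    """

    sample_id: str
    patient_id: str
    group: Group

    @staticmethod
    def make(sample_id: str, group: Group, patient_id: Optional[str] = None) -> "SampleInfo":
        return SampleInfo(sample_id, patient_id or sample_id, group)


@dataclass
class VariantRecord:
    """One annotated somatic mutation observed in one sample.

    ``pos`` is 1-based.  ``ref`` may be empty for a pure insertion.
    Optional annotation fields default to ``None`` ("unset"); an unset
    ``dbsnp_id`` means the variant is novel (not a known polymorphism).
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: Optional[str] = None
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None
    dbsnp_id: Optional[str] = None
    pop_af: Optional[float] = None
    tri_context: Optional[str] = None
    consequence: Optional[ConsequenceClass] = None
    patient_id: Optional[str] = None
    group: Optional[Group] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.tri_context is not None:
            if len(self.tri_context) != 3:
                raise ValueError(f"tri_context must have length 3, got {self.tri_context!r}")
            if len(self.ref) == 1 and len(self.alt) == 1 and self.tri_context[1] != self.ref:
                raise ValueError(
                    f"tri_context middle base {self.tri_context[1]!r} != ref {self.ref!r} "
                    f"at {self.chrom}:{self.pos}"
                )

    @property
    def is_sbs(self) -> bool:
        """True for a single-base substitution (equal-length single-base alleles)."""
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def length_difference(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    def mutation_key(self) -> tuple:
        """Identity of the mutation itself, irrespective of sample/transcript."""
        return (self.chrom, self.pos, self.ref, self.alt)


def normalize_symbol(symbol: str) -> str:
    return symbol.strip().upper()


class GeneSet:
    """A named set of case-normalized gene symbols.

    The name is a provenance label ("driver_catalog", "reported_bladder", ...);
    membership tests are case-insensitive.
    """

    def __init__(self, name: str, symbols: Iterable[str] = ()) -> None:
        self.name = name
        self.symbols: frozenset = frozenset(normalize_symbol(s) for s in symbols if s.strip())

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.symbols))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSet):
            return NotImplemented
        return self.symbols == other.symbols

    def __hash__(self) -> int:
        return hash(self.symbols)

    def __repr__(self) -> str:
        return f"GeneSet({self.name!r}, n={len(self.symbols)})"

    def union(self, other: "GeneSet", name: Optional[str] = None) -> "GeneSet":
        return GeneSet(name or f"{self.name}|{other.name}", self.symbols | other.symbols)

    def difference(self, other: "GeneSet", name: Optional[str] = None) -> "GeneSet":
        return GeneSet(name or self.name, self.symbols - other.symbols)

    def intersection(self, other: "GeneSet", name: Optional[str] = None) -> "GeneSet":
        return GeneSet(name or self.name, self.symbols & other.symbols)


def genes_of(records: Iterable[VariantRecord], name: str = "observed") -> GeneSet:
    """Gene symbols mutated in a record list."""
    return GeneSet(name, (r.gene for r in records))


def resolve_groups(
    records: Iterable[VariantRecord], samples: Iterable[SampleInfo]
) -> list[VariantRecord]:
    """Attach group and patient labels from a sample sheet, in place.

    Raises ``KeyError`` if a record names a sample absent from the sheet:
    group resolution must be total.
    """
    index = {s.sample_id: s for s in samples}
    out = []
    for rec in records:
        info = index.get(rec.sample_id)
        if info is None:
            raise KeyError(f"sample {rec.sample_id!r} not present in the sample sheet")
        rec.group = info.group
        rec.patient_id = info.patient_id
        out.append(rec)
    return out
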