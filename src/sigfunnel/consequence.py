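"""HGVS-driven consequence classification.

The classifier maps each mutation into a nine-way taxonomy
(:class:`~sigfunnel.records.ConsequenceClass`) from its HGVS cDNA
notation, HGVS protein notation and/or raw alleles.  Splice
classification uses the canonical +-2 dinucleotide rule: a substitution
at intron offset -1/-2 hits the acceptor site, +1/+2 the donor site.
No splice-strength scoring and no codon-level recomputation from a
reference genome is attempted; annotations must arrive in the input.

The supported HGVS subset is the one seen in exome annotation output:
``c.746A>T``, ``c.41-2A>T``, ``c.528+2T>A``, ``c.*30delC``,
``c.-12C>T``, ``c.100_102del``, ``c.100dupA``, ``c.100_101insTT``,
``c.100delinsAT`` on the cDNA side; ``p.Q249L``, ``p.K57*``,
``p.*110L``, ``p.?``, ``-`` on the protein side.  Whitespace inside the
notation (as produced by some typesetters, e.g. ``c.528 + 2 T > A``) is
tolerated.
"""

from __future__ import annotations

import enum
import re
import warnings
from dataclasses import dataclass
from typing import Optional

from .records import ConsequenceClass, VariantRecord


class HgvsError(ValueError):
    """Unparseable HGVS notation; carries the raw string."""


class EditKind(str, enum.Enum):
    SUB = "SUB"
    DEL = "DEL"
    INS = "INS"
    DUP = "DUP"
    DELINS = "DELINS"


@dataclass(frozen=True)
class HgvsC:
    """Structured HGVS cDNA change.

    ``utr`` is ``None`` for coding positions, ``"5"`` for 5'UTR
    (``c.-N``) and ``"3"`` for 3'UTR (``c.*N``).  ``intron_offset`` is
    the signed offset into the intron (never 0 when present).
    """

    raw: str
    coding_pos: int
    utr: Optional[str]
    intron_offset: Optional[int]
    edit: EditKind
    ref_base: Optional[str] = None
    alt_base: Optional[str] = None
    length_change: int = 0  # |len(ref) - len(alt)| implied by the edit

    @property
    def is_coding(self) -> bool:
        return self.utr is None and self.intron_offset is None


class ProteinKind(str, enum.Enum):
    SUBSTITUTION = "SUBSTITUTION"
    STOP_GAIN = "STOP_GAIN"
    STOP_LOSS = "STOP_LOSS"
    UNKNOWN = "UNKNOWN"  # "p.?"
    NONE = "NONE"  # "-" / empty: no protein change stated


@dataclass(frozen=True)
class HgvsP:
    raw: str
    kind: ProteinKind
    ref_aa: Optional[str] = None
    pos: Optional[int] = None
    alt_aa: Optional[str] = None


_POS = r"(?P<utr>[*-])?(?P<pos>\d+)(?P<off>[+-]\d+)?"
_SUB_RE = re.compile(rf"^c\.{_POS}(?P<ref>[ACGT])>(?P<alt>[ACGT])$")
_RANGE = rf"{_POS}(?:_(?:[*-]?\d+(?:[+-]\d+)?))?"
_INDEL_RE = re.compile(
    rf"^c\.{_RANGE}(?P<op>delins|del|dup|ins)(?P<bases>[ACGT]*)$"
)
_RANGE_SPAN_RE = re.compile(r"^c\.[*-]?(\d+)(?:[+-]\d+)?_[*-]?(\d+)(?:[+-]\d+)?")


def parse_hgvs_c(text: str) -> HgvsC:
    """Parse an HGVS cDNA string into a structured edit."""
    raw = text
    compact = re.sub(r"\s+", "", text)
    if not compact.startswith("c."):
        raise HgvsError(f"not an HGVS cDNA string: {raw!r}")
    m = _SUB_RE.match(compact)
    if m:
        return HgvsC(
            raw=raw,
            coding_pos=int(m.group("pos")),
            utr={"*": "3", "-": "5"}.get(m.group("utr") or ""),
            intron_offset=int(m.group("off")) if m.group("off") else None,
            edit=EditKind.SUB,
            ref_base=m.group("ref"),
            alt_base=m.group("alt"),
        )
    m = _INDEL_RE.match(compact)
    if m:
        op = m.group("op")
        bases = m.group("bases")
        span = 1
        ms = _RANGE_SPAN_RE.match(compact)
        if ms:
            span = abs(int(ms.group(2)) - int(ms.group(1))) + 1
        edit = {
            "del": EditKind.DEL,
            "ins": EditKind.INS,
            "dup": EditKind.DUP,
            "delins": EditKind.DELINS,
        }[op]
        if edit is EditKind.DEL:
            length = len(bases) or span
        elif edit in (EditKind.INS, EditKind.DUP):
            length = len(bases) or span
        else:  # DELINS: net length change
            length = abs((len(bases) or span) - span)
        return HgvsC(
            raw=raw,
            coding_pos=int(m.group("pos")),
            utr={"*": "3", "-": "5"}.get(m.group("utr") or ""),
            intron_offset=int(m.group("off")) if m.group("off") else None,
            edit=edit,
            length_change=length,
        )
    raise HgvsError(f"unparseable HGVS cDNA string: {raw!r}")


_AA = r"(?:[A-Z]|\*|Ter|[A-Z][a-z]{2})"
_P_SUB_RE = re.compile(rf"^p\.\(?(?P<ref>{_AA})(?P<pos>\d+)(?P<alt>{_AA})\)?$")

_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*",
}


def _aa1(code: str) -> str:
    return _THREE_TO_ONE.get(code, code)


def parse_hgvs_p(text: Optional[str]) -> HgvsP:
    """Parse an HGVS protein string; ``-``/empty mean "no protein change"."""
    raw = "" if text is None else text
    compact = re.sub(r"\s+", "", raw)
    if compact in ("", "-"):
        return HgvsP(raw=raw, kind=ProteinKind.NONE)
    if compact in ("p.?", "p.(?)"):
        return HgvsP(raw=raw, kind=ProteinKind.UNKNOWN)
    m = _P_SUB_RE.match(compact)
    if m:
        ref_aa, alt_aa = _aa1(m.group("ref")), _aa1(m.group("alt"))
        pos = int(m.group("pos"))
        if alt_aa == "*" and ref_aa != "*":
            kind = ProteinKind.STOP_GAIN
        elif ref_aa == "*" and alt_aa != "*":
            kind = ProteinKind.STOP_LOSS
        else:
            kind = ProteinKind.SUBSTITUTION
        return HgvsP(raw=raw, kind=kind, ref_aa=ref_aa, pos=pos, alt_aa=alt_aa)
    raise HgvsError(f"unparseable HGVS protein string: {raw!r}")


def classify_consequence(record: VariantRecord, reclassify: bool = False) -> ConsequenceClass:
    """Classify one mutation into the nine-way taxonomy.

    A precomputed ``consequence`` on the record wins unless
    ``reclassify`` is set (inputs may come from richer annotators).
    Classification priority:

    1. intronic substitution at offset -1/-2 -> SPLICE_ACCEPTOR, +1/+2 -> SPLICE_DONOR
    2. allele length change: exactly 1 bp inside the coding region ->
       FRAMESHIFT, anything else (or any UTR/intron length change) -> INDEL
    3. protein substitution: same residue -> SYNONYMOUS, else MISSENSE
    4. stop gain -> NONSENSE
    5. stop loss -> NONSTOP
    6. no protein change stated, but a coding single-base substitution -> SYNONYMOUS
    7. otherwise OTHER (with a warning when nothing was classifiable)
    """
    if record.consequence is not None and not reclassify:
        return record.consequence

    hc: Optional[HgvsC] = None
    if record.hgvs_c:
        try:
            hc = parse_hgvs_c(record.hgvs_c)
        except HgvsError:
            hc = None
    hp: Optional[HgvsP] = None
    if record.hgvs_p is not None:
        try:
            hp = parse_hgvs_p(record.hgvs_p)
        except HgvsError:
            hp = None

    # (1) canonical +-2 splice sites
    if hc is not None and hc.intron_offset is not None and hc.edit is EditKind.SUB:
        if hc.intron_offset in (-1, -2):
            return ConsequenceClass.SPLICE_ACCEPTOR
        if hc.intron_offset in (1, 2):
            return ConsequenceClass.SPLICE_DONOR

    # (2) length changes: from the alleles when present, else from the cDNA edit
    length_change = record.length_difference if (record.ref or record.alt) else 0
    in_coding = hc.is_coding if hc is not None else True
    if hc is not None and hc.edit is not EditKind.SUB and length_change == 0:
        length_change = hc.length_change
    if length_change > 0:
        if length_change == 1 and in_coding:
            return ConsequenceClass.FRAMESHIFT
        return ConsequenceClass.INDEL

    # (3)-(5) protein-level evidence
    if hp is not None:
        if hp.kind is ProteinKind.SUBSTITUTION:
            if hp.ref_aa == hp.alt_aa:
                return ConsequenceClass.SYNONYMOUS
            return ConsequenceClass.MISSENSE
        if hp.kind is ProteinKind.STOP_GAIN:
            return ConsequenceClass.NONSENSE
        if hp.kind is ProteinKind.STOP_LOSS:
            return ConsequenceClass.NONSTOP

    # (6) a coding substitution with no stated protein change is silent
    if (
        (hp is None or hp.kind is ProteinKind.NONE)
        and hc is not None
        and hc.edit is EditKind.SUB
        and hc.is_coding
    ):
        return ConsequenceClass.SYNONYMOUS

    if hc is None and hp is None and not (record.ref and record.alt):
        warnings.warn(
            f"record {record.chrom}:{record.pos} in {record.sample_id} carries no "
            "classifiable information; classified OTHER",
            stacklevel=2,
        )
    return ConsequenceClass.OTHER


#: Classes that do not alter the protein product.
_NON_PROTEIN_AFFECTING = frozenset({ConsequenceClass.SYNONYMOUS, ConsequenceClass.OTHER})


def is_amino_acid_changing(cls: ConsequenceClass) -> bool:
    """True for classes treated as protein-affecting in the gene funnel.

    Splice, frameshift, indel (including UTR indels), nonsense, nonstop
    and missense all count; synonymous substitutions and unclassifiable
    records do not.
    """
    return cls not in _NON_PROTEIN_AFFECTING


def annotate_consequences(
    records: list[VariantRecord], reclassify: bool = False
) -> list[VariantRecord]:
    """Fill in ``consequence`` for every record (in place) and return them."""
    for rec in records:
        rec.consequence = classify_consequence(rec, reclassify=reclassify)
    return records
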