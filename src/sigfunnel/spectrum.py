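"""Six-class substitution spectra and mutation-category accounting.

Single-base substitutions are collapsed onto the six pyrimidine-reference
classes C>A, C>G, C>T, T>A, T>C, T>G (purine-reference changes are
reverse-complemented).  Group summaries come in two flavours:
``MEAN_OF_SAMPLES`` averages per-sample frequency vectors, ``POOLED``
sums counts across samples before normalizing — the two differ whenever
samples carry unequal mutation burdens.

Indels never enter the six-class spectra.  In the category table,
however, records whose alleles differ by exactly 1 bp are tallied as
FRAMESHIFT inside the substitution block, while longer length changes
make up the indel total — mirroring the layout of exome-study summary
tables that nest 1-bp frameshifts under "single-base substitution".
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .records import ConsequenceClass, Group, VariantRecord

SIX_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def complement(base: str) -> str:
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise ValueError(f"not a DNA base: {base!r}") from None


def revcomp(seq: str) -> str:
    return "".join(complement(b) for b in reversed(seq))


def sixclass_of(ref: str, alt: str) -> str:
    """Pyrimidine-reference class of a single-base substitution."""
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"non-ACGT base in substitution {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError(f"not a substitution: {ref}>{alt}")
    if ref in ("C", "T"):
        return f"{ref}>{alt}"
    return f"{complement(ref)}>{complement(alt)}"


@dataclass
class SixClassSpectrum:
    """Counts and frequencies over the six substitution classes.

    ``empty`` flags a spectrum computed from zero substitutions, whose
    frequencies are reported as zeros rather than NaN.
    """

    counts: dict = field(default_factory=lambda: {c: 0 for c in SIX_CLASSES})
    freqs: dict = field(default_factory=lambda: {c: 0.0 for c in SIX_CLASSES})
    empty: bool = False

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @staticmethod
    def from_counts(counts: dict) -> "SixClassSpectrum":
        full = {c: int(counts.get(c, 0)) for c in SIX_CLASSES}
        total = sum(full.values())
        if total == 0:
            return SixClassSpectrum(counts=full, empty=True)
        return SixClassSpectrum(
            counts=full, freqs={c: full[c] / total for c in SIX_CLASSES}
        )

    def freq_vector(self) -> np.ndarray:
        return np.array([self.freqs[c] for c in SIX_CLASSES])


def _sbs_records(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    return [r for r in records if r.is_sbs and r.ref in _COMPLEMENT and r.alt in _COMPLEMENT]


def sample_spectrum(records: Iterable[VariantRecord], sample_id: str) -> SixClassSpectrum:
    """Six-class spectrum of one sample's substitutions (indels excluded)."""
    counts = {c: 0 for c in SIX_CLASSES}
    for rec in _sbs_records(records):
        if rec.sample_id == sample_id:
            counts[sixclass_of(rec.ref, rec.alt)] += 1
    return SixClassSpectrum.from_counts(counts)


class SummaryMode(str, enum.Enum):
    MEAN_OF_SAMPLES = "MEAN_OF_SAMPLES"
    POOLED = "POOLED"


def group_spectrum_summary(
    records: Sequence[VariantRecord],
    group: Group,
    mode: SummaryMode = SummaryMode.MEAN_OF_SAMPLES,
) -> SixClassSpectrum:
    """Summarize a cohort's six-class spectrum.

    ``MEAN_OF_SAMPLES`` averages the per-sample frequency vectors (each
    sample weighs equally); ``POOLED`` sums counts over samples and
    normalizes once (each mutation weighs equally).  Counts in the
    returned spectrum are the pooled counts in both modes; only the
    frequencies differ.
    """
    mode = SummaryMode(mode)
    group = Group(group)
    in_group = [r for r in records if r.group == group]
    sample_ids = sorted({r.sample_id for r in in_group})
    if not sample_ids:
        raise ValueError(f"no records for group {group.value}")
    pooled = {c: 0 for c in SIX_CLASSES}
    per_sample = []
    for sid in sample_ids:
        spec = sample_spectrum(in_group, sid)
        per_sample.append(spec)
        for c in SIX_CLASSES:
            pooled[c] += spec.counts[c]
    out = SixClassSpectrum.from_counts(pooled)
    if mode is SummaryMode.MEAN_OF_SAMPLES:
        contributing = [s for s in per_sample if not s.empty]
        if contributing:
            mean = np.mean([s.freq_vector() for s in contributing], axis=0)
            out.freqs = {c: float(mean[i]) for i, c in enumerate(SIX_CLASSES)}
    return out


_SBS_CLASS_ORDER = (
    ConsequenceClass.SYNONYMOUS,
    ConsequenceClass.MISSENSE,
    ConsequenceClass.NONSENSE,
    ConsequenceClass.FRAMESHIFT,
    ConsequenceClass.SPLICE_ACCEPTOR,
    ConsequenceClass.SPLICE_DONOR,
    ConsequenceClass.NONSTOP,
)


@dataclass
class CategoryCounts:
    """Mutation taxonomy totals for a sample or a whole cohort."""

    counts: dict = field(default_factory=dict)
    sbs_total: int = 0
    indel_total: int = 0

    @property
    def total_somatic(self) -> int:
        return self.sbs_total + self.indel_total


def category_counts(
    records: Iterable[VariantRecord],
    group: Optional[Group] = None,
    sample_id: Optional[str] = None,
) -> CategoryCounts:
    """Tally mutations by category for a cohort or a single sample.

    Length-neutral records are tallied under their consequence class;
    records whose alleles differ by exactly 1 bp count as FRAMESHIFT
    within the substitution block; longer differences make the indel
    total.  Records must carry consequence classes (or enough HGVS to
    derive one) for the class-level rows to be meaningful.
    """
    from .consequence import classify_consequence

    counts = {cls: 0 for cls in _SBS_CLASS_ORDER}
    counts[ConsequenceClass.OTHER] = 0
    sbs_total = 0
    indel_total = 0
    for rec in records:
        if group is not None and rec.group != group:
            continue
        if sample_id is not None and rec.sample_id != sample_id:
            continue
        diff = rec.length_difference
        if diff > 1:
            indel_total += 1
            continue
        if diff == 1:
            counts[ConsequenceClass.FRAMESHIFT] += 1
            sbs_total += 1
            continue
        cls = rec.consequence or classify_consequence(rec)
        if cls in (ConsequenceClass.INDEL, ConsequenceClass.FRAMESHIFT):
            # class says indel but the alleles are length-neutral; trust the alleles
            cls = ConsequenceClass.OTHER
        counts[cls] = counts.get(cls, 0) + 1
        sbs_total += 1
    return CategoryCounts(counts=counts, sbs_total=sbs_total, indel_total=indel_total)
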