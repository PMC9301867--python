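"""SBS96 matrix construction and signature-exposure refitting.

A mutational signature is a probability distribution over the 96
trinucleotide-context substitution channels ``X[R>A]Y`` (R a pyrimidine,
X/Y the 5'/3' flanking bases).  Given a catalog P (96 x K, column
stochastic) and a sample's channel-count vector v, refitting solves

    min ||v - P w||_2   subject to   w >= 0

by non-negative least squares; the weights w are mutation counts
attributed to each signature and are reported as percentages of their
sum.  Reconstruction quality is the cosine similarity between v and Pw.

Only refitting against a known catalog is provided; de novo signature
extraction (NMF) is out of scope, as is renormalization by exome/genome
trinucleotide abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .records import VariantRecord
from .spectrum import SIX_CLASSES, complement, revcomp, sixclass_of

log = logging.getLogger(__name__)

_BASES = ("A", "C", "G", "T")

#: Canonical channel order: six classes, then 5' flank, then 3' flank.
CHANNELS: tuple = tuple(
    f"{f5}[{cls}]{f3}" for cls in SIX_CLASSES for f5 in _BASES for f3 in _BASES
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}


def channel_of(ref: str, alt: str, tri_context: str) -> str:
    """SBS96 channel of a substitution with its reference-strand 3-mer.

    The context's middle base must equal ``ref``; purine-reference
    records are reverse-complemented (context and alleles together).
    """
    if len(tri_context) != 3:
        raise ValueError(f"tri_context must be a 3-mer, got {tri_context!r}")
    if tri_context[1] != ref:
        raise ValueError(
            f"context middle base {tri_context[1]!r} does not match ref {ref!r}"
        )
    if ref in ("C", "T"):
        f5, f3 = tri_context[0], tri_context[2]
        cls = f"{ref}>{alt}"
    else:
        rc = revcomp(tri_context)
        f5, f3 = rc[0], rc[2]
        cls = f"{complement(ref)}>{complement(alt)}"
    return f"{f5}[{cls}]{f3}"


def class_of_channel(channel: str) -> str:
    return channel[2:5]


def build_sbs96_matrix(
    records: Iterable[VariantRecord],
    fasta: Optional[str] = None,
) -> pd.DataFrame:
    """Per-sample SBS96 count matrix (samples x 96).

    Context comes from each record's ``tri_context``; when absent and a
    reference FASTA is supplied, the 3-mer is looked up at
    ``chrom:pos-1..pos+1`` (pyfaidx).  Records without resolvable
    context, or whose context contradicts the reference allele, are
    dropped with a logged count.
    """
    ref_fasta = None
    if fasta is not None:
        from pyfaidx import Fasta

        ref_fasta = Fasta(fasta)
    counts: dict[str, np.ndarray] = {}
    dropped = 0
    for rec in records:
        if not rec.is_sbs:
            continue
        context = rec.tri_context
        if context is None and ref_fasta is not None:
            try:
                context = str(ref_fasta[rec.chrom][rec.pos - 2 : rec.pos + 1]).upper()
            except (KeyError, IndexError):
                context = None
        if context is None:
            dropped += 1
            continue
        try:
            ch = channel_of(rec.ref, rec.alt, context)
        except ValueError:
            dropped += 1
            continue
        row = counts.setdefault(rec.sample_id, np.zeros(96, dtype=int))
        row[_CHANNEL_INDEX[ch]] += 1
    if dropped:
        log.warning("build_sbs96_matrix: dropped %d records without usable context", dropped)
    frame = pd.DataFrame(
        {sid: counts[sid] for sid in sorted(counts)}, index=list(CHANNELS)
    ).T
    frame.index.name = "sample_id"
    return frame


class CatalogFormatError(ValueError):
    """Signature catalog fails validation."""


@dataclass
class SignatureCatalog:
    """Reference signatures: 96 x K column-stochastic probability matrix."""

    names: tuple
    probs: np.ndarray  # shape (96, K), columns sum to 1

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (96, len(self.names)):
            raise CatalogFormatError(
                f"catalog shape {self.probs.shape} does not match {len(self.names)} names"
            )
        if (self.probs < 0).any():
            raise CatalogFormatError("catalog contains negative entries")
        sums = self.probs.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-4):
            bad = [self.names[i] for i in np.where(np.abs(sums - 1.0) > 1e-4)[0]]
            raise CatalogFormatError(f"catalog columns not unit-sum: {bad}")

    def __len__(self) -> int:
        return len(self.names)

    def column(self, name: str) -> np.ndarray:
        return self.probs[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=list(CHANNELS), columns=list(self.names))


def read_signature_catalog(path: str) -> SignatureCatalog:
    """Read a COSMIC-style tab-separated catalog.

    First column holds channel labels ("A[C>A]A", ...); every remaining
    column is one signature.  Rows may arrive in any order; they are
    reindexed to the canonical channel order.  Missing channels,
    negative entries, or columns off unit sum by more than 1e-4 raise
    :class:`CatalogFormatError`.
    """
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    missing = [c for c in CHANNELS if c not in df.index]
    if missing:
        raise CatalogFormatError(f"{path}: missing channels, first {missing[0]!r} "
                                 f"({len(missing)} total)")
    extra = [c for c in df.index if c not in _CHANNEL_INDEX]
    if extra:
        raise CatalogFormatError(f"{path}: unknown channel labels {extra[:3]}")
    df = df.reindex(list(CHANNELS))
    return SignatureCatalog(names=tuple(df.columns), probs=df.to_numpy(dtype=float))


def write_signature_catalog(catalog: SignatureCatalog, path: str) -> None:
    frame = catalog.to_frame()
    frame.index.name = "Type"
    frame.to_csv(path, sep="\t")


def cosine_similarity(a: Sequence[float], b: Sequence[float]) -> float:
    """Cosine of the angle between two non-zero, non-negative vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


@dataclass
class ExposureResult:
    """Signature weights for one count vector."""

    names: tuple
    weights: np.ndarray  # attributed mutation counts, >= 0
    cosine: float

    @property
    def percents(self) -> np.ndarray:
        total = self.weights.sum()
        if total == 0:
            return np.zeros_like(self.weights)
        return 100.0 * self.weights / total

    def as_dict(self) -> dict:
        return {n: float(p) for n, p in zip(self.names, self.percents)}


def refit_exposures(
    v: Sequence[float],
    catalog: SignatureCatalog,
    prune_below: float = 0.0,
) -> ExposureResult:
    """Attribute a 96-channel count vector to catalog signatures by NNLS.

    With ``prune_below`` > 0 (percent), signatures attributed less than
    that share are removed and the fit repeated once on the survivors;
    pruned signatures report weight 0.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (96,):
        raise ValueError(f"expected a 96-vector, got shape {v.shape}")
    if (v < 0).any():
        raise ValueError("count vector has negative entries")
    if not v.any():
        raise ValueError("count vector is all zero")
    weights, _ = nnls(catalog.probs, v)
    if prune_below > 0:
        total = weights.sum()
        keep = np.where(weights > 0, 100.0 * weights / max(total, 1e-300), 0.0) >= prune_below
        if keep.any() and not keep.all():
            sub, _ = nnls(catalog.probs[:, keep], v)
            weights = np.zeros_like(weights)
            weights[np.where(keep)[0]] = sub
    recon = catalog.probs @ weights
    cos = cosine_similarity(v, recon) if recon.any() else 0.0
    return ExposureResult(names=catalog.names, weights=weights, cosine=cos)


def refit_matrix(
    matrix: pd.DataFrame, catalog: SignatureCatalog, prune_below: float = 0.0
) -> pd.DataFrame:
    """Refit every row of an SBS96 matrix; returns samples x signatures percents.

    A ``cosine`` column records each sample's reconstruction similarity.
    """
    rows = {}
    for sid, row in matrix.iterrows():
        res = refit_exposures(row.to_numpy(dtype=float), catalog, prune_below)
        rows[sid] = {**res.as_dict(), "cosine": res.cosine}
    return pd.DataFrame(rows).T
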