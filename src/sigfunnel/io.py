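"""Readers and writers for the tabular formats the pipeline touches.

Variant tables are tab-separated with a header; the canonical column
order is given by :data:`VARIANT_COLUMNS` (optional columns may be
absent).  Gene lists are plain text, one symbol per line, ``#`` comments
allowed.  A minimal slice of VCF 4.x is read through pysam.

All coordinates are 1-based inclusive.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import pysam

from .records import (
    ConsequenceClass,
    GeneSet,
    SampleInfo,
    VariantRecord,
    resolve_groups,
)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: Canonical variant-table columns. The first six are mandatory.
VARIANT_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "transcript",
    "hgvs_c",
    "hgvs_p",
    "dbsnp_id",
    "pop_af",
    "tri_context",
    "consequence",
]

MANDATORY_COLUMNS = VARIANT_COLUMNS[:6]


class VariantTableError(ValueError):
    """Malformed variant table (missing columns, bad values)."""


def _opt(value) -> Optional[str]:
    """Empty cell -> None."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    return text or None


def read_variant_table(path: PathLike, samples: Sequence[SampleInfo]) -> list[VariantRecord]:
    """Read a tab-separated variant table and resolve cohort labels.

    Every row must name a sample present in ``samples``; the returned
    records carry the resolved group and patient identifiers.  Optional
    columns that are absent (or empty) leave the corresponding fields
    unset.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise VariantTableError(f"{path}: missing mandatory columns {missing}")
    records: list[VariantRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        d = row._asdict()
        pos_text = str(d["pos"]).strip()
        try:
            pos = int(pos_text)
        except ValueError:
            raise VariantTableError(f"{path}: line {i}: non-integer pos {pos_text!r}") from None
        af_text = _opt(d.get("pop_af"))
        cons_text = _opt(d.get("consequence"))
        try:
            cons = ConsequenceClass(cons_text) if cons_text else None
        except ValueError:
            raise VariantTableError(
                f"{path}: line {i}: unknown consequence {cons_text!r}"
            ) from None
        records.append(
            VariantRecord(
                sample_id=str(d["sample_id"]).strip(),
                chrom=str(d["chrom"]).strip(),
                pos=pos,
                ref=str(d["ref"]).strip(),
                alt=str(d["alt"]).strip(),
                gene=str(d["gene"]).strip(),
                transcript=_opt(d.get("transcript")),
                hgvs_c=_opt(d.get("hgvs_c")),
                hgvs_p=_opt(d.get("hgvs_p")),
                dbsnp_id=_opt(d.get("dbsnp_id")),
                pop_af=float(af_text) if af_text else None,
                tri_context=_opt(d.get("tri_context")),
                consequence=cons,
            )
        )
    try:
        return resolve_groups(records, samples)
    except KeyError as exc:
        raise VariantTableError(f"{path}: {exc.args[0]}") from None


def write_table(records: Iterable[VariantRecord], path: PathLike) -> None:
    """Write variant records as a tab-separated table (round-trip safe).

    Unset optional fields become empty cells; ``read_variant_table``
    restores them as unset.
    """
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "gene": r.gene,
                "transcript": r.transcript or "",
                "hgvs_c": r.hgvs_c or "",
                "hgvs_p": r.hgvs_p or "",
                "dbsnp_id": r.dbsnp_id or "",
                "pop_af": "" if r.pop_af is None else repr(r.pop_af),
                "tri_context": r.tri_context or "",
                "consequence": r.consequence.value if r.consequence else "",
            }
        )
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_gene_list(path: PathLike, name: str) -> GeneSet:
    """Read a plain-text gene list (one symbol per line, ``#`` comments).

    Symbols are case-normalized and deduplicated.  An effectively empty
    file yields an empty set with a warning rather than an error.
    """
    symbols = []
    with open(path) as fh:
        for line in fh:
            text = line.split("#", 1)[0].strip()
            if text:
                symbols.append(text)
    if not symbols:
        warnings.warn(f"gene list {path} ({name}) is empty", stacklevel=2)
    return GeneSet(name, symbols)


def write_gene_list(genes: GeneSet, path: PathLike) -> None:
    with open(path, "w") as fh:
        for symbol in genes:
            fh.write(symbol + "\n")


class VcfFormatError(ValueError):
    """Malformed or unreadable VCF input."""


#: Default mapping from record fields onto VCF INFO keys.
DEFAULT_INFO_KEYS: Mapping[str, str] = {
    "gene": "GENE",
    "transcript": "TRANSCRIPT",
    "hgvs_c": "HGVSC",
    "hgvs_p": "HGVSP",
    "pop_af": "AF",
}


def read_vcf_lite(
    path: PathLike,
    sample_id: str,
    info_keys: Optional[Mapping[str, str]] = None,
) -> list[VariantRecord]:
    """Read a minimal VCF 4.x into variant records for one sample.

    Only CHROM/POS/ID/REF/ALT plus the configured INFO keys are used.
    The VCF ID field supplies the dbSNP annotation ("." means novel);
    multiallelic rows are split into one record per ALT allele, with
    per-allele INFO values (e.g. AF) split alongside.
    """
    keys = dict(DEFAULT_INFO_KEYS)
    if info_keys:
        keys.update(info_keys)
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfFormatError(f"{path}: not a readable VCF: {exc}") from None
    records: list[VariantRecord] = []
    with vcf:
        for row in vcf:
            alts = row.alts or ()
            for ai, alt in enumerate(alts):
                info = row.info

                def get(key: str, allele_index: int = ai):
                    if key not in info:
                        return None
                    value = info[key]
                    if isinstance(value, tuple):
                        # Number=A fields carry one value per ALT allele
                        if len(value) == len(alts):
                            return value[allele_index]
                        value = value[0]
                    return value

                gene = get(keys["gene"])
                af = get(keys["pop_af"])
                records.append(
                    VariantRecord(
                        sample_id=sample_id,
                        chrom=row.chrom,
                        pos=row.pos,
                        ref=row.ref or "",
                        alt=str(alt),
                        gene=str(gene) if gene is not None else "",
                        transcript=_opt(get(keys["transcript"])),
                        hgvs_c=_opt(get(keys["hgvs_c"])),
                        hgvs_p=_opt(get(keys["hgvs_p"])),
                        dbsnp_id=None if row.id in (None, ".") else row.id,
                        pop_af=float(af) if af is not None else None,
                    )
                )
    return records


def read_sample_sheet(path: PathLike) -> list[SampleInfo]:
    """Read a sample sheet (TSV: sample_id, patient_id, group)."""
    from .records import Group

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise VariantTableError(f"{path}: sample sheet lacks column {col!r}")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        sid = str(d["sample_id"]).strip()
        out.append(
            SampleInfo(
                sample_id=sid,
                patient_id=_opt(d.get("patient_id")) or sid,
                group=Group(str(d["group"]).strip().upper()),
            )
        )
    ids = [s.sample_id for s in out]
    if len(ids) != len(set(ids)):
        raise VariantTableError(f"{path}: duplicate sample_id in sample sheet")
    return out
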