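"""The gene-prioritization funnel.

Starting from two cohorts of annotated somatic mutations (case vs
control), the cascade applies, in fixed order:

1. *novel*       — drop known polymorphisms (dbSNP-annotated records) and
                   collapse per-transcript duplicates of one genomic change;
2. *drivers*     — keep only genes present in a cancer-driver catalog;
3. *unreported*  — drop genes already reported for this tumor type;
4. *unique*      — keep case genes absent from the control cohort;
5. *recurrent*   — keep genes mutated in >= N distinct samples (or patients);
6. *aa_change*   — keep genes with at least one protein-affecting mutation.

Stages 4-6 apply to the case cohort only.  The stage order cannot be
reconfigured; gene and mutation counts at every stage are recorded in a
:class:`FunnelReport`.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .consequence import classify_consequence, is_amino_acid_changing
from .records import ConsequenceClass, GeneSet, Group, VariantRecord, genes_of


class RecurrenceUnit(str, enum.Enum):
    SAMPLE = "SAMPLE"
    PATIENT = "PATIENT"


@dataclass
class FunnelConfig:
    """Funnel policy knobs; the defaults reproduce the reference pipeline.

    ``af_max_known=0`` excludes *every* dbSNP-annotated record.  A value
    in (0, 1] switches to the alternate policy of excluding only
    dbSNP-annotated records whose population allele frequency is at or
    below the threshold (rare known variants), keeping common ones.
    """

    af_max_known: float = 0.0
    recurrence_min: int = 2
    recurrence_unit: RecurrenceUnit = RecurrenceUnit.SAMPLE
    require_amino_acid_change: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.af_max_known <= 1.0:
            raise ValueError("af_max_known must lie in [0, 1]")
        if self.recurrence_min < 1:
            raise ValueError("recurrence_min must be >= 1")
        self.recurrence_unit = RecurrenceUnit(self.recurrence_unit)


@dataclass(frozen=True)
class StageCount:
    stage: str
    group: str
    mutation_count: int
    gene_count: int
    genes: tuple


@dataclass
class FunnelReport:
    """Per-stage counts plus the final gene set and its records."""

    stages: list = field(default_factory=list)
    final_genes: GeneSet = field(default_factory=lambda: GeneSet("final"))
    final_records: list = field(default_factory=list)

    def add_stage(self, stage: str, group: str, records: Sequence[VariantRecord]) -> None:
        genes = tuple(sorted({r.gene.strip().upper() for r in records}))
        self.stages.append(StageCount(stage, group, len(records), len(genes), genes))

    def stage_genes(self, stage: str, group: str) -> set:
        for s in self.stages:
            if s.stage == stage and s.group == group:
                return set(s.genes)
        raise KeyError((stage, group))

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "stage": s.stage,
                    "group": s.group,
                    "mutation_count": s.mutation_count,
                    "gene_count": s.gene_count,
                    "genes": list(s.genes),
                }
                for s in self.stages
            ],
            "final_genes": sorted(self.final_genes.symbols),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def filter_known_polymorphisms(
    records: Iterable[VariantRecord], cfg: Optional[FunnelConfig] = None
) -> list[VariantRecord]:
    """Drop known polymorphisms; non-dbSNP records always pass.

    Default policy removes every record carrying a dbSNP identifier.
    With ``af_max_known > 0`` only dbSNP-annotated records with
    ``pop_af <= af_max_known`` are removed (records lacking an AF are
    still removed, as known variants of unestablished frequency).
    """
    cfg = cfg or FunnelConfig()
    out = []
    for rec in records:
        if not rec.dbsnp_id:
            out.append(rec)
        elif cfg.af_max_known > 0 and rec.pop_af is not None and rec.pop_af > cfg.af_max_known:
            out.append(rec)
    return out


def collapse_transcripts(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Count one occurrence per genomic change per sample.

    Records are grouped by (sample_id, chrom, pos, ref, alt); the
    representative is the one with the lexicographically lowest
    transcript identifier.  Output order is deterministic (sorted by
    key).  Conflicting gene symbols within one key are kept on the
    representative (joined with ``|``) with a warning.
    """
    groups: dict[tuple, list[VariantRecord]] = {}
    for rec in records:
        groups.setdefault((rec.sample_id, rec.chrom, rec.pos, rec.ref, rec.alt), []).append(rec)
    out = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda r: r.transcript or "")
        rep = members[0]
        symbols = sorted({m.gene.strip().upper() for m in members})
        if len(symbols) > 1:
            warnings.warn(
                f"conflicting gene symbols {symbols} at {key[1]}:{key[2]} in {key[0]}",
                stacklevel=2,
            )
            rep.gene = "|".join(symbols)
        out.append(rep)
    return out


def retain_driver_genes(
    records: Iterable[VariantRecord], drivers: GeneSet
) -> tuple[list[VariantRecord], GeneSet]:
    """Keep records whose gene is in the driver catalog (set intersection)."""
    kept = [r for r in records if r.gene in drivers]
    return kept, genes_of(kept, "drivers_retained")


def exclude_reported_genes(
    records: Iterable[VariantRecord], reported: Sequence[GeneSet]
) -> tuple[list[VariantRecord], GeneSet]:
    """Drop records whose gene appears in any previously-reported list."""
    union: frozenset = frozenset().union(*(g.symbols for g in reported)) if reported else frozenset()
    kept = [r for r in records if r.gene.strip().upper() not in union]
    return kept, genes_of(kept, "unreported")


def group_unique_genes(case_genes: GeneSet, control_genes: GeneSet) -> GeneSet:
    """Case genes not seen in the control cohort."""
    return case_genes.difference(control_genes, name="case_unique")


def recurrence_filter(
    records: Iterable[VariantRecord], genes: GeneSet, cfg: Optional[FunnelConfig] = None
) -> GeneSet:
    """Keep genes mutated in >= recurrence_min distinct samples (or patients)."""
    cfg = cfg or FunnelConfig()
    units: dict[str, set] = {}
    for rec in records:
        if rec.gene not in genes:
            continue
        if cfg.recurrence_unit is RecurrenceUnit.PATIENT:
            unit = rec.patient_id or rec.sample_id
        else:
            unit = rec.sample_id
        units.setdefault(rec.gene.strip().upper(), set()).add(unit)
    return GeneSet(
        "recurrent", (g for g, u in units.items() if len(u) >= cfg.recurrence_min)
    )


def nonsynonymous_gene_filter(
    records: Iterable[VariantRecord], genes: GeneSet
) -> GeneSet:
    """Keep genes with at least one protein-affecting mutation."""
    keep = set()
    for rec in records:
        if rec.gene not in genes:
            continue
        cls = rec.consequence or classify_consequence(rec)
        if is_amino_acid_changing(cls):
            keep.add(rec.gene.strip().upper())
    return GeneSet("aa_changing", keep)


def run_funnel(
    case: Sequence[VariantRecord],
    control: Sequence[VariantRecord],
    drivers: GeneSet,
    reported: Sequence[GeneSet],
    cfg: Optional[FunnelConfig] = None,
) -> FunnelReport:
    """Run the full cascade on both cohorts and report per-stage counts."""
    cfg = cfg or FunnelConfig()
    report = FunnelReport()
    per_group: dict[str, list[VariantRecord]] = {}
    for label, records in ((Group.CASE.value, list(case)), (Group.CONTROL.value, list(control))):
        report.add_stage("input", label, records)
        novel = collapse_transcripts(filter_known_polymorphisms(records, cfg))
        report.add_stage("novel", label, novel)
        in_drivers, _ = retain_driver_genes(novel, drivers)
        report.add_stage("drivers", label, in_drivers)
        unreported, _ = exclude_reported_genes(in_drivers, reported)
        report.add_stage("unreported", label, unreported)
        per_group[label] = unreported

    case_genes = genes_of(per_group[Group.CASE.value])
    control_genes = genes_of(per_group[Group.CONTROL.value])
    unique = group_unique_genes(case_genes, control_genes)
    case_records = [r for r in per_group[Group.CASE.value] if r.gene in unique]
    report.add_stage("unique", Group.CASE.value, case_records)

    recurrent = recurrence_filter(case_records, unique, cfg)
    case_records = [r for r in case_records if r.gene in recurrent]
    report.add_stage("recurrent", Group.CASE.value, case_records)

    if cfg.require_amino_acid_change:
        final = nonsynonymous_gene_filter(case_records, recurrent)
        case_records = [r for r in case_records if r.gene in final]
        report.add_stage("aa_change", Group.CASE.value, case_records)
    else:
        final = recurrent

    report.final_genes = GeneSet("final", final.symbols)
    report.final_records = case_records
    return report
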