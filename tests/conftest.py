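"""Shared fixtures: toy cohorts, random-cohort generation, and a naive
stage-by-stage funnel oracle kept deliberately independent of the
package's implementation."""

from __future__ import annotations

import numpy as np
import pytest

from sigfunnel.records import ConsequenceClass, GeneSet, Group, SampleInfo, VariantRecord


# ----------------------------------------------------------------------
# Toy cohort: case samples S1-S3, control S4-S5; drivers {G1,G2,G3,G5},
# reported [{G5}].  Hand enumeration: the rs123 record drops, G5 is
# excluded, control contributes G3, case-unique = {G1,G2}, recurrence>=2
# keeps G1 (samples S1,S2); final set {G1}.
# ----------------------------------------------------------------------

@pytest.fixture
def toy_samples():
    case = [SampleInfo.make(f"S{i}", Group.CASE) for i in (1, 2, 3)]
    control = [SampleInfo.make(f"S{i}", Group.CONTROL) for i in (4, 5)]
    return case + control


def _toy_rec(gene, sample, pos, dbsnp=None, group=Group.CASE):
    return VariantRecord(
        sample_id=sample, chrom="chr1", pos=pos, ref="A", alt="T", gene=gene,
        dbsnp_id=dbsnp, consequence=ConsequenceClass.MISSENSE,
        patient_id=sample, group=group,
    )


@pytest.fixture
def toy_cohort():
    case = [
        _toy_rec("G1", "S1", 100),
        _toy_rec("G1", "S2", 110),
        _toy_rec("G2", "S1", 200),
        _toy_rec("G5", "S1", 500),
        _toy_rec("G1", "S3", 130, dbsnp="rs123"),
    ]
    control = [_toy_rec("G3", "S4", 300, group=Group.CONTROL)]
    drivers = GeneSet("driver_catalog", ["G1", "G2", "G3", "G5"])
    reported = [GeneSet("reported", ["G5"])]
    return case, control, drivers, reported


# ----------------------------------------------------------------------
# Random cohorts for oracle-equivalence testing
# ----------------------------------------------------------------------

_CONSEQUENCES = list(ConsequenceClass)


def random_cohort(rng: np.random.Generator, max_records: int = 30):
    """A small random two-cohort dataset plus driver/reported gene sets.

    Gene symbols are tied to positions so transcript collapsing can
    never create symbol conflicts.
    """
    genes = [f"G{i}" for i in range(rng.integers(2, 9))]
    case_samples = [f"S{i}" for i in range(rng.integers(1, 5))]
    control_samples = [f"T{i}" for i in range(rng.integers(1, 4))]

    def make(samples, group, n):
        out = []
        for _ in range(n):
            gi = int(rng.integers(len(genes)))
            rec = VariantRecord(
                sample_id=str(rng.choice(samples)),
                chrom="chr1",
                pos=1000 * (gi + 1) + int(rng.integers(5)),
                ref="A",
                alt="T",
                gene=genes[gi],
                transcript=f"NM_{rng.integers(3)}",
                dbsnp_id=f"rs{rng.integers(100)}" if rng.random() < 0.25 else None,
                pop_af=float(np.round(rng.uniform(0, 0.5), 3)) if rng.random() < 0.5 else None,
                consequence=_CONSEQUENCES[int(rng.integers(len(_CONSEQUENCES)))],
            )
            rec.patient_id = rec.sample_id
            rec.group = group
            out.append(rec)
        return out

    n_total = int(rng.integers(0, max_records + 1))
    n_case = int(rng.integers(0, n_total + 1))
    case = make(case_samples, Group.CASE, n_case)
    control = make(control_samples, Group.CONTROL, n_total - n_case)
    drivers = GeneSet("drv", rng.choice(genes, size=rng.integers(1, len(genes) + 1),
                                        replace=False).tolist())
    reported = [
        GeneSet("rep", rng.choice(genes, size=rng.integers(0, len(genes) + 1),
                                  replace=False).tolist())
    ]
    return case, control, drivers, reported


# Classes treated as protein-affecting, restated independently.
_AA_CHANGING = {
    "MISSENSE", "NONSENSE", "FRAMESHIFT", "SPLICE_ACCEPTOR",
    "SPLICE_DONOR", "NONSTOP", "INDEL",
}


def funnel_oracle(case, control, drivers, reported, recurrence_min=2,
                  unit="SAMPLE", require_aa=True, af_max=0.0):
    """Naive stage-by-stage recomputation of the funnel's final gene set."""

    def novel(records):
        kept = []
        for r in records:
            if not r.dbsnp_id:
                kept.append(r)
            elif af_max > 0 and r.pop_af is not None and r.pop_af > af_max:
                kept.append(r)
        seen, out = set(), []
        for r in kept:
            key = (r.sample_id, r.chrom, r.pos, r.ref, r.alt)
            if key not in seen:
                seen.add(key)
                out.append(r)
        return out

    reported_union = set()
    for gs in reported:
        for g in gs.symbols:
            reported_union.add(g.upper())

    def surviving(records):
        out = []
        for r in records:
            g = r.gene.upper()
            if g in {d.upper() for d in drivers.symbols} and g not in reported_union:
                out.append(r)
        return out

    case_kept = surviving(novel(case))
    control_kept = surviving(novel(control))
    case_genes = {r.gene.upper() for r in case_kept}
    control_genes = {r.gene.upper() for r in control_kept}
    unique = case_genes - control_genes

    final = set()
    for g in unique:
        recs = [r for r in case_kept if r.gene.upper() == g]
        if unit == "PATIENT":
            units = {r.patient_id or r.sample_id for r in recs}
        else:
            units = {r.sample_id for r in recs}
        if len(units) < recurrence_min:
            continue
        if require_aa and not any(
            r.consequence is not None and r.consequence.value in _AA_CHANGING for r in recs
        ):
            continue
        final.add(g)
    return final
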