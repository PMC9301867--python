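"""Synthetic two-cohort datasets with known ground truth.

The generator emulates the statistical structure the analysis assumes:
two cohorts of per-sample mutation lists whose substitutions are drawn
from a mixture of reference signatures (an aristolochic-acid-like,
T>A-dominant exposure for both urothelial cohorts), a configurable
fraction of dbSNP-tagged common polymorphisms, recurrent driver
mutations planted in a chosen number of case samples, and
"already-reported" genes mutated in both cohorts.  A manifest records
every planted fact so each downstream stage can be tested against the
truth that generated its input.

Also packaged here is the printed 28-mutation table of the motivating
study (:func:`table4_fixture`): the genetic characteristics of the 14
case-specific genes, encoded verbatim, which serves as an in-paper
end-to-end fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .consequence import is_amino_acid_changing
from .records import ConsequenceClass, Group, SampleInfo, VariantRecord, GeneSet
from .signatures import CHANNELS, SignatureCatalog, class_of_channel
from .spectrum import revcomp


# --------------------------------------------------------------------------
# Synthetic signature catalog
# --------------------------------------------------------------------------

def synthetic_catalog() -> SignatureCatalog:
    """Three deterministic reference signatures for tests and simulations.

    * ``SBS22like`` — T>A dominant with a 5'-C / 3'-G context preference,
      mimicking the aristolochic-acid signature;
    * ``SBS5like``  — broad, flat-ish profile with a mild C>T / T>C tilt;
    * ``SBS1like``  — C>T concentrated at NpCpG contexts, the
      deamination-clock shape.

    The three columns are linearly independent by construction.
    """
    f5w = {"A": 1.0, "C": 4.0, "G": 1.0, "T": 2.0}
    f3w = {"A": 1.0, "C": 1.0, "G": 3.0, "T": 1.0}
    sbs22 = np.full(96, 0.15 / 80)
    for i, ch in enumerate(CHANNELS):
        if class_of_channel(ch) == "T>A":
            sbs22[i] = f5w[ch[0]] * f3w[ch[6]]
    ta = [i for i, ch in enumerate(CHANNELS) if class_of_channel(ch) == "T>A"]
    sbs22[ta] = 0.85 * sbs22[ta] / sbs22[ta].sum()

    sbs5 = np.ones(96)
    for i, ch in enumerate(CHANNELS):
        if class_of_channel(ch) in ("C>T", "T>C"):
            sbs5[i] = 2.0
    sbs5 /= sbs5.sum()

    sbs1 = np.full(96, 0.24 / 92)
    ncg = [i for i, ch in enumerate(CHANNELS) if class_of_channel(ch) == "C>T" and ch[6] == "G"]
    sbs1[ncg] = 0.76 / len(ncg)

    probs = np.column_stack([sbs22, sbs5, sbs1])
    probs /= probs.sum(axis=0)
    return SignatureCatalog(names=("SBS22like", "SBS5like", "SBS1like"), probs=probs)


# --------------------------------------------------------------------------
# Sampling mutations from a signature mixture
# --------------------------------------------------------------------------

def sample_mutations_from_signatures(
    catalog: SignatureCatalog,
    mix: Sequence[float],
    n: int,
    rng: np.random.Generator,
    sample_id: str = "S",
    chrom: str = "chr1",
    start_pos: int = 1,
    gene_pool: Optional[Sequence[str]] = None,
) -> tuple[np.ndarray, list[VariantRecord]]:
    """Draw ``n`` substitutions i.i.d. from the channel distribution P @ mix.

    Each drawn channel is materialized as a :class:`VariantRecord` with
    mutually consistent ref/alt/tri_context on a fabricated coordinate
    (sequential positions from ``start_pos``).  The reference strand of
    each record is chosen deterministically so that purine- and
    pyrimidine-reference representations both occur (odd positions are
    stored on the purine strand), exercising strand normalization
    downstream.  Returns the 96-channel count vector and the records.
    """
    mix = np.asarray(mix, dtype=float)
    if mix.shape != (len(catalog),) or (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError(f"invalid mixture {mix!r} for a {len(catalog)}-signature catalog")
    if n < 0:
        raise ValueError("n must be >= 0")
    p = catalog.probs @ mix
    counts = rng.multinomial(n, p)
    channel_ids = np.repeat(np.arange(96), counts)
    rng.shuffle(channel_ids)
    records: list[VariantRecord] = []
    pool = list(gene_pool) if gene_pool else None
    gene_picks = rng.integers(0, len(pool), size=n) if pool else None
    for i, ci in enumerate(channel_ids):
        ch = CHANNELS[ci]
        f5, ref, alt, f3 = ch[0], ch[2], ch[4], ch[6]
        context = f5 + ref + f3
        pos = start_pos + i
        if pos % 2 == 1:  # store on the purine-reference strand
            context = revcomp(context)
            ref = revcomp(ref)
            alt = revcomp(alt)
        records.append(
            VariantRecord(
                sample_id=sample_id,
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                gene=pool[gene_picks[i]] if pool else "BACKGROUND",
                tri_context=context,
            )
        )
    return counts, records


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

#: Per-class probabilities used to annotate background substitutions,
#: proportional to the case cohort's printed substitution-class counts.
_BACKGROUND_CONSEQUENCES = (
    (ConsequenceClass.SYNONYMOUS, 0.1089),
    (ConsequenceClass.MISSENSE, 0.7705),
    (ConsequenceClass.NONSENSE, 0.0522),
    (ConsequenceClass.SPLICE_ACCEPTOR, 0.0498),
    (ConsequenceClass.SPLICE_DONOR, 0.0166),
    (ConsequenceClass.NONSTOP, 0.0020),
)


@dataclass
class SimConfig:
    """Study conditions for one synthetic two-cohort dataset.

    Defaults follow the motivating cohort: 7 case and 5 control samples,
    ~2,500 somatic mutations per exome, an SBS22-dominant aetiology in
    both groups (84/10/6 vs 81/11/8 percent over the three synthetic
    signatures), and 18% of background records tagged as known dbSNP
    polymorphisms.
    """

    n_case: int = 7
    n_control: int = 5
    mutations_per_sample: float = 2500.0
    signature_mix_case: tuple = (0.84, 0.10, 0.06)
    signature_mix_control: tuple = (0.81, 0.11, 0.08)
    planted_drivers: tuple = (
        ("DRVA", 3, ConsequenceClass.MISSENSE),
        ("DRVB", 2, ConsequenceClass.NONSENSE),
        ("DRVC", 1, ConsequenceClass.MISSENSE),
    )
    planted_reported_genes: tuple = ("RPT1", "RPT2")
    dbsnp_fraction: float = 0.18
    seed: int = 0

    def __post_init__(self) -> None:
        for mix in (self.signature_mix_case, self.signature_mix_control):
            if abs(sum(mix) - 1.0) > 1e-9 or any(w < 0 for w in mix):
                raise ValueError(f"signature mixture {mix} must be non-negative and sum to 1")
        genes = [g for g, _, _ in self.planted_drivers]
        if len(genes) != len(set(genes)):
            raise ValueError("planted driver genes must be distinct")
        if set(genes) & set(self.planted_reported_genes):
            raise ValueError("planted drivers and reported genes must be disjoint")
        for gene, k, _ in self.planted_drivers:
            if not 0 <= k <= self.n_case:
                raise ValueError(f"planted driver {gene}: n_case_samples {k} > n_case")
        if not 0.0 <= self.dbsnp_fraction <= 1.0:
            raise ValueError("dbsnp_fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Manifest of everything the generator planted."""

    true_channel_counts: dict = field(default_factory=dict)  # sample -> 96-vector
    planted: dict = field(default_factory=dict)  # gene -> (samples tuple, consequence)
    drivers: GeneSet = field(default_factory=lambda: GeneSet("driver_catalog"))
    reported: GeneSet = field(default_factory=lambda: GeneSet("reported"))
    expected_final: set = field(default_factory=set)
    samples: list = field(default_factory=list)


def _planted_record(
    gene: str, gene_index: int, sample: SampleInfo, occurrence: int,
    consequence: ConsequenceClass,
) -> VariantRecord:
    """Materialize one planted mutation with HGVS consistent with its class."""
    pos = 1_000_000 * (gene_index + 1) + occurrence
    ref, alt = "A", "T"
    hgvs_c: Optional[str] = f"c.{100 + occurrence}A>T"
    hgvs_p: Optional[str] = None
    if consequence is ConsequenceClass.MISSENSE:
        hgvs_p = f"p.K{34 + occurrence}L"
    elif consequence is ConsequenceClass.SYNONYMOUS:
        hgvs_p = "-"
    elif consequence is ConsequenceClass.NONSENSE:
        hgvs_p = f"p.K{34 + occurrence}*"
    elif consequence is ConsequenceClass.NONSTOP:
        hgvs_p = f"p.*{300 + occurrence}L"
    elif consequence is ConsequenceClass.SPLICE_ACCEPTOR:
        hgvs_c, hgvs_p = f"c.{100 + occurrence}-2A>T", "p.?"
    elif consequence is ConsequenceClass.SPLICE_DONOR:
        hgvs_c, hgvs_p = f"c.{100 + occurrence}+2A>T", "p.?"
    elif consequence is ConsequenceClass.FRAMESHIFT:
        ref, alt = "AT", "A"
        hgvs_c, hgvs_p = f"c.{100 + occurrence}delT", "p.?"
    elif consequence is ConsequenceClass.INDEL:
        ref, alt = "ATT", "A"
        hgvs_c, hgvs_p = f"c.{100 + occurrence}_{101 + occurrence}del", "p.?"
    else:  # OTHER
        hgvs_c, hgvs_p = None, None
    return VariantRecord(
        sample_id=sample.sample_id,
        chrom="chr20",
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        hgvs_c=hgvs_c,
        hgvs_p=hgvs_p,
        consequence=consequence,
        patient_id=sample.patient_id,
        group=sample.group,
    )


def generate_cohort(
    cfg: SimConfig, catalog: Optional[SignatureCatalog] = None
) -> tuple[list[VariantRecord], list[VariantRecord], GroundTruth]:
    """Generate case and control record lists plus the ground-truth manifest.

    The manifest's ``expected_final`` is the gene set the default funnel
    (recurrence >= 2 distinct samples, protein-affecting mutation
    required) must recover: planted drivers reaching enough case samples
    with a protein-affecting consequence.  Deterministic under a fixed
    ``cfg.seed``.
    """
    catalog = catalog or synthetic_catalog()
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth()

    case_samples = [
        SampleInfo.make(f"CA{i:02d}", Group.CASE) for i in range(cfg.n_case)
    ]
    control_samples = [
        SampleInfo.make(f"CO{i:02d}", Group.CONTROL) for i in range(cfg.n_control)
    ]
    truth.samples = case_samples + control_samples

    background_pool = [f"BG{i:03d}" for i in range(200)]
    cons_classes = [c for c, _ in _BACKGROUND_CONSEQUENCES]
    cons_probs = np.array([p for _, p in _BACKGROUND_CONSEQUENCES])
    cons_probs = cons_probs / cons_probs.sum()
    rs_counter = 0

    def make_group(samples: list, mix: Sequence[float]) -> list[VariantRecord]:
        nonlocal rs_counter
        out: list[VariantRecord] = []
        for info in samples:
            n = int(rng.poisson(cfg.mutations_per_sample))
            vec, records = sample_mutations_from_signatures(
                catalog, mix, n, rng, sample_id=info.sample_id,
                gene_pool=background_pool,
            )
            truth.true_channel_counts[info.sample_id] = vec
            draws = rng.choice(len(cons_classes), size=n, p=cons_probs)
            known = rng.random(n) < cfg.dbsnp_fraction
            afs = np.round(rng.uniform(0.05, 0.5, size=n), 3)
            for i, rec in enumerate(records):
                rec.consequence = cons_classes[draws[i]]
                rec.patient_id = info.patient_id
                rec.group = info.group
                if known[i]:
                    rs_counter += 1
                    rec.dbsnp_id = f"rs{900000 + rs_counter}"
                    rec.pop_af = float(afs[i])
            out.extend(records)
        return out

    case = make_group(case_samples, cfg.signature_mix_case)
    control = make_group(control_samples, cfg.signature_mix_control)

    for gi, (gene, k, consequence) in enumerate(cfg.planted_drivers):
        chosen = [case_samples[int(j)] for j in rng.choice(cfg.n_case, size=k, replace=False)]
        for occ, info in enumerate(chosen):
            case.append(_planted_record(gene, gi, info, occ, consequence))
        truth.planted[gene] = (tuple(s.sample_id for s in chosen), consequence)
        if k >= 2 and is_amino_acid_changing(consequence):
            truth.expected_final.add(gene)

    offset = len(cfg.planted_drivers)
    for gi, gene in enumerate(cfg.planted_reported_genes):
        if case_samples:
            case.append(
                _planted_record(gene, offset + gi, case_samples[0], 0, ConsequenceClass.MISSENSE)
            )
        if control_samples:
            control.append(
                _planted_record(gene, offset + gi, control_samples[0], 1, ConsequenceClass.MISSENSE)
            )

    truth.drivers = GeneSet(
        "driver_catalog",
        [g for g, _, _ in cfg.planted_drivers] + list(cfg.planted_reported_genes),
    )
    truth.reported = GeneSet("reported", cfg.planted_reported_genes)
    return case, control, truth


# --------------------------------------------------------------------------
# In-paper fixture: the printed 28-mutation table
# --------------------------------------------------------------------------

#: (gene, chrom, [(samples, position, hgvs_c, hgvs_p), ...]) — encoded verbatim
#: from the published table of case-specific genes with nonsynonymous mutations.
_TABLE4 = (
    ("CARD11", "7", (
        (("KT80",), 2_979_501, "c.746A>T", "p.Q249L"),
        (("KT80",), 2_959_246, "c.2270G>T", "p.G757V"),
        (("KT721",), 2_979_984, "c.298G>A", "p.E100K"),
    )),
    ("FNBP1", "9", (
        (("KT720",), 94_012_949, "c.1118A>T", "p.E373V"),
        (("KT721",), 132_686_175, "c.1279A>T", "p.R427*"),
    )),
    ("GNAQ", "9", (
        (("KT80", "KT721"), 80_537_229, "c.169A>T", "p.K57*"),
        (("KT79",), 80_537_135, "c.263A>T", "p.Q88L"),
    )),
    ("HOXD13", "2", (
        (("KT79", "KT722"), 176_957_650, "c.32G>C", "p.G11A"),
    )),
    ("IKZF1", "7", (
        (("KT80",), 50_450_403, "c.326C>G", "p.S109C"),
        (("KT81",), 50_367_232, "c.41-2A>T", "p.?"),
    )),
    ("MAX", "14", (
        (("KT79", "KT81"), 65_472_892, "c.*30delC", "p.?"),
    )),
    ("MLLT10", "10", (
        (("KT720",), 21_903_809, "c.559A>T", "p.N187Y"),
        (("KT80", "KT721"), 21_959_631, "c.1049A>T", "p.Q350L"),
        (("KT81",), 21_875_221, "c.241-2A>T", "p.?"),
    )),
    ("NTRK3", "15", (
        (("KT80", "KT721"), 88_799_202, "c.183T>A", "p.D61E"),
        (("KT79",), 88_727_498, "c.281T>A", "p.L94H"),
    )),
    ("SEPTIN6", "X", (
        (("KT80", "KT721"), 118_763_455, "c.1106A>T", "p.D369V"),
        (("KT81",), 118_786_815, "c.528+2T>A", "p.?"),
    )),
    ("SEPTIN9", "17", (
        (("KT79", "KT720"), 75_471_875, "c.275A>T", "p.E92V"),
    )),
    ("SH3GL1", "19", (
        (("KT81",), 4_362_684, "c.634C>T", "p.R212W"),
        (("KT79",), 4_361_737, "c.823G>C", "p.G275R"),
    )),
    ("SLC34A2", "4", (
        (("KT80", "KT721"), 25_674_846, "c.1183G>A", "p.A395T"),
        (("KT17",), 25_677_770, "c.1469A>T", "p.H490L"),
    )),
    ("TAL1", "1", (
        (("KT720",), 47_691_377, "c.184G>C", "p.G62R"),
        (("KT720", "KT722"), 47_685_603, "c.785T>G", "p.V262G"),
        (("KT720",), 47_685_597, "c.791C>G", "p.A264G"),
    )),
    ("TRAF7", "16", (
        (("KT79",), 2_222_207, "c.491A>T", "p.D164V"),
        (("KT722",), 2_221_345, "c.429C>T", "-"),
    )),
)

_CASE_SAMPLE_IDS = ("KT17", "KT79", "KT80", "KT81", "KT720", "KT721", "KT722")
_CONTROL_SAMPLE_IDS = ("KT73", "KT77", "KT78", "KT595", "KT596")


def table1_samples() -> list[SampleInfo]:
    """The 12-sample sheet of the motivating study.

    Seven case samples from six patients (KT80 and KT721 came from one
    patient at different surgeries) and five control samples.
    """
    out = []
    for sid in _CASE_SAMPLE_IDS:
        patient = "KT80_KT721" if sid in ("KT80", "KT721") else sid
        out.append(SampleInfo(sid, patient, Group.CASE))
    for sid in _CONTROL_SAMPLE_IDS:
        out.append(SampleInfo(sid, sid, Group.CONTROL))
    return out


def _alleles_from_hgvs_c(hgvs_c: str) -> tuple[str, str]:
    """Coding-strand-naive alleles for the fixture (genomic strand unknown)."""
    from .consequence import EditKind, parse_hgvs_c

    hc = parse_hgvs_c(hgvs_c)
    if hc.edit is EditKind.SUB:
        return hc.ref_base, hc.alt_base
    if hc.edit is EditKind.DEL:
        return "C" * max(hc.length_change, 1), ""
    raise ValueError(f"fixture cannot derive alleles for {hgvs_c!r}")


def table4_fixture() -> list[VariantRecord]:
    """The published 28-mutation table as per-sample variant records.

    Mutations printed with two sample IDs expand to one record per
    sample (37 records in all; 28 distinct mutations over 14 genes).
    Alleles are taken from the cDNA notation as printed, since the table
    gives no genomic strand.
    """
    sheet = {s.sample_id: s for s in table1_samples()}
    records = []
    for gene, chrom, mutations in _TABLE4:
        for samples, pos, hgvs_c, hgvs_p in mutations:
            ref, alt = _alleles_from_hgvs_c(hgvs_c)
            for sid in samples:
                info = sheet[sid]
                records.append(
                    VariantRecord(
                        sample_id=sid,
                        chrom=chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        gene=gene,
                        hgvs_c=hgvs_c,
                        hgvs_p=hgvs_p,
                        patient_id=info.patient_id,
                        group=info.group,
                    )
                )
    return records
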