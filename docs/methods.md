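# Methods

## Scope and model

`sigfunnel` operates downstream of alignment, variant calling and
annotation: its inputs are per-sample lists of annotated somatic
mutations (gene symbol, HGVS cDNA/protein notation, dbSNP status,
optional population allele frequency and trinucleotide context), gene
lists, a signature catalog, and CNV calls. It performs no read-level
processing, no transcript-model annotation, and no effect prediction;
annotations are taken as given.

The analysis has four parts: a gene-prioritization funnel over a case
and a control cohort, consequence classification from HGVS notation,
mutational-spectrum/signature attribution, and CNV recurrence selection.

## Consequence classification

Each mutation maps to exactly one of nine classes — synonymous,
missense, nonsense, frameshift, splice acceptor, splice donor,
stop-loss (nonstop), indel, other — using a fixed priority:

1. a substitution at intron offset −1/−2 of the cDNA notation is a
   splice-acceptor change, +1/+2 a splice-donor change (the canonical
   ±2 dinucleotide rule). Maximum-entropy splice-strength scoring is
   deliberately not reimplemented: on annotated exome output the ±2
   rule reproduces every splice call we have needed, and a weaker site
   cannot be judged without the reference sequence;
2. alleles of unequal length: a difference of exactly 1 bp inside the
   coding region is a frameshift; any longer difference, or any length
   change in a UTR or intron, is an indel;
3. protein substitutions decide synonymous vs missense; stop-gain is
   nonsense; stop-loss is nonstop;
4. a coding single-base substitution whose protein column is printed as
   "-" (no protein change) is classified synonymous;
5. anything unclassifiable is `OTHER`, with a warning — never a crash.

`p.?` alone is *not* evidence of a splice effect: annotation pipelines
print it for splice-site and UTR mutations alike, so the cDNA offset
decides. A `consequence` column already present in the input wins over
re-derivation unless reclassification is requested, since upstream
annotators may know more (e.g. actual transcript models) than the HGVS
string conveys.

For the funnel's protein-effect stage, every class except synonymous
and `OTHER` counts as protein-affecting. UTR indels are included: they
change the transcript even when the printed protein effect is unknown,
and excluding them would discard genes whose only recorded lesion is a
UTR deletion.

## The funnel

Stages run in a fixed order (novel → drivers → unreported → unique →
recurrent → protein effect); the configuration can change thresholds
but not the order, so every report is comparable. Gene symbols are
case-normalized before set operations because the driver and reported
lists come from heterogeneous sources. Two policy points deserve note:

* **Known-polymorphism policy.** The default removes every
  dbSNP-annotated record. An alternative reading — remove only known
  variants that are *rare* (pop. AF ≤ 5%), keeping common ones — is
  available via `af_max_known`; under that mode dbSNP records without a
  recorded AF are still removed, as known variants of unestablished
  frequency. The two policies genuinely differ and the default is the
  stricter, more common practice for somatic filtering.
* **Recurrence unit.** Recurrence counts distinct *samples* by default.
  When one patient contributes several tumors, sample-level counting
  can promote a gene mutated twice in the same person; patient-level
  counting (`recurrence_unit=PATIENT`) uses `patient_id` instead. Both
  are provided because cohort tables in this field list genes recurrent
  only across same-patient samples.

Transcript collapsing keys on (sample, chromosome, position, ref, alt)
— stricter than "same genomic location", because two different
substitutions at one position are distinct mutations. The
representative record is the lexicographically lowest transcript
identifier, a deterministic tie-break with no biological content.

Stage order note: because stages 3–6 are all gene-level set
operations, excluding reported genes before or after the cohort overlap
yields the same final set; the fixed order matters only for the
intermediate counts reported per stage.

## Spectra

Six-class spectra use the pyrimidine-reference convention
(purine-reference substitutions are reverse-complemented). Indels never
enter six-class or SBS96 spectra, even though summary tables in this
field sometimes nest 1-bp frameshifts under "single-base substitution":
a substitution-class key cannot represent a length change. The category
table (`category_counts`) mirrors that nesting instead — records whose
alleles differ by exactly 1 bp are tallied as frameshift inside the
substitution block, longer differences as indels — so its totals line
up with published summary-table layouts.

Cohort summaries come in two modes because both appear in practice:
`MEAN_OF_SAMPLES` (average of per-sample frequency vectors; every
sample weighs equally; samples with zero substitutions are excluded
from the mean rather than contributing an undefined vector) and
`POOLED` (sum counts, normalize once; every mutation weighs equally).
They agree exactly when all samples carry equal substitution totals and
can differ arbitrarily otherwise.

## Signature refitting

The SBS96 matrix builder takes the trinucleotide context from the
record (or a reference FASTA); a context whose middle base contradicts
the reference allele rejects the record with a warning rather than
silently miscounting. Channel order is fixed: the six classes in
alphabetical order, then the 5' flank, then the 3' flank; catalogs read
from disk are reindexed to this order, so input row order is
irrelevant. Catalog validation rejects missing channels, negative
entries, and columns off unit sum by more than 1e-4.

Exposures solve non-negative least squares on *counts*, not
frequencies, so high-burden samples are weighted naturally and the
fitted weights are interpretable as attributed mutation counts.
Percentages are weight shares. `prune_below` optionally removes
signatures attributed less than a given percentage and refits once on
the survivors — a deliberately simple sparsity step; no model selection
of the kind de novo extraction tools perform is attempted, and de novo
extraction itself (NMF) is out of scope because the quantity of
interest is the attribution against known signatures. No
exome/genome trinucleotide-abundance renormalization is applied; the
catalog must be on the same context scale as the data.

Degenerate inputs are errors by design: an all-zero count vector and a
zero vector in the cosine are refused rather than returning NaN.

## CNV selection

Events are matched across cohorts by exact (chromosome, start) key
only — no interval-overlap logic — matching the convention of
selecting recurrent events "by start site". A key is recurrent when it
occurs in ≥ `min_samples` distinct samples of a cohort; case-specific
keys are case-recurrent keys absent from the control *recurrent* set
(the default), or from all control events (`against_all_control`).

## The synthetic generator

The generator produces what the analysis assumes and nothing more:

* per-sample background substitutions drawn i.i.d. from a signature
  mixture over a packaged three-signature catalog (an
  aristolochic-acid-like T>A-dominant column, a flat SBS5-like column,
  and a deamination-clock SBS1-like column, all deterministic and
  linearly independent), materialized with mutually consistent
  ref/alt/context — odd positions are stored on the purine strand so
  strand normalization is exercised;
* consequence labels for background records drawn from proportions
  matching published exome summary tables (≈75% missense, ≈11%
  synonymous, the rest nonsense/splice/nonstop);
* a configurable fraction of background records tagged with synthetic
  rs-identifiers and common allele frequencies;
* planted driver mutations with a requested consequence class in a
  requested number of case samples, at per-gene coordinate ranges
  disjoint from the background so transcript collapsing can never merge
  them; planted "already-reported" genes mutated once in each cohort.

Defaults mirror the motivating study's conditions: 7 case and 5 control
samples, ~2,500 mutations per exome, signature mixtures (0.84, 0.10,
0.06) and (0.81, 0.11, 0.08), and an 18% known-polymorphism fraction.
The manifest records per-sample true channel counts, the planted map,
and the gene set the default funnel must recover (planted drivers in ≥2
samples with a protein-affecting class).

What the generator does **not** emulate — and hence what passing tests
do not establish about real data: mutational hotspots and
gene-length/coverage bias, FFPE and sequencing artifacts, germline
contamination beyond the dbSNP flag, multi-transcript annotation,
inter-sample correlation within a patient, and real genomic
coordinates. Tests on synthetic cohorts validate the *logic* of the
pipeline, not the biology of any particular cohort.

The packaged 28-mutation table of the motivating study (14 genes, seven
case samples, two of them from one patient) provides one fixed,
non-synthetic end-to-end fixture: replaying it through the classifier
and the protein-effect filter must leave exactly 14 genes.

## Problem sizes and numerical choices

The test suite runs the funnel/oracle equivalence on 200 random cohorts
of ≤ 30 records, the generator/funnel manifest property on 100 random
configurations of 2–6 case samples at 20–80 mutations per sample, and
mixture recovery at 2,000 mutations per sample over 20 seeds — sizes at
which the checked properties are already sharp while the suite stays
fast. All randomness is seeded; reports serialize deterministically
(sorted keys, sorted gene sets), so identical inputs yield byte-identical
outputs.

## Known limitations

* HGVS parsing covers the substitution/del/ins/dup/delins subset seen
  in exome annotation output, not the full nomenclature (no inversions,
  alleles, or mosaic notation).
* Consequence classification cannot recover information absent from the
  input: without a reference genome, a printed "-" protein column on a
  coding substitution is taken at face value as synonymous.
* Frequency-based known-variant filtering needs a populated `pop_af`
  column; the package never queries external databases.
* Signature refitting is only as identifiable as the catalog: strongly
  collinear signature columns trade weight with little change to the
  reconstruction cosine.
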