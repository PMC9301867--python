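"""Synthetic-cohort generator: determinism, manifests, closure with the
refitter, and the packaged in-paper mutation table."""

import numpy as np
import pytest

from sigfunnel.consequence import annotate_consequences
from sigfunnel.funnel import run_funnel
from sigfunnel.records import ConsequenceClass, Group
from sigfunnel.signatures import refit_exposures
from sigfunnel.simulate import (
    SimConfig,
    generate_cohort,
    sample_mutations_from_signatures,
    synthetic_catalog,
    table1_samples,
    table4_fixture,
)


class TestSyntheticCatalog:
    def test_valid_and_linearly_independent(self):
        cat = synthetic_catalog()
        assert cat.names == ("SBS22like", "SBS5like", "SBS1like")
        np.testing.assert_allclose(cat.probs.sum(axis=0), 1.0, atol=1e-9)
        assert np.linalg.matrix_rank(cat.probs) == 3

    def test_shapes_mirror_their_namesakes(self):
        from sigfunnel.signatures import CHANNELS, class_of_channel

        cat = synthetic_catalog()
        ta = [i for i, ch in enumerate(CHANNELS) if class_of_channel(ch) == "T>A"]
        assert cat.column("SBS22like")[ta].sum() > 0.8
        ncg = [i for i, ch in enumerate(CHANNELS)
               if class_of_channel(ch) == "C>T" and ch[6] == "G"]
        assert cat.column("SBS1like")[ncg].sum() > 0.7


class TestSampleMutations:
    def test_zero_draws_empty(self):
        cat = synthetic_catalog()
        vec, recs = sample_mutations_from_signatures(
            cat, (1, 0, 0), 0, np.random.default_rng(0))
        assert vec.sum() == 0 and recs == []

    def test_degenerate_distribution_hits_one_channel(self):
        from sigfunnel.signatures import CHANNELS, SignatureCatalog, channel_of

        probs = np.zeros((96, 1))
        probs[5, 0] = 1.0
        cat = SignatureCatalog(names=("point",), probs=probs)
        vec, recs = sample_mutations_from_signatures(
            cat, (1.0,), 50, np.random.default_rng(1))
        assert vec[5] == 50
        for r in recs:
            assert channel_of(r.ref, r.alt, r.tri_context) == CHANNELS[5]

    def test_records_consistent_with_channel_vector(self):
        cat = synthetic_catalog()
        vec, recs = sample_mutations_from_signatures(
            cat, (0.6, 0.3, 0.1), 500, np.random.default_rng(2))
        assert vec.sum() == len(recs) == 500
        for r in recs:
            assert r.tri_context[1] == r.ref  # strand-consistent context

    def test_invalid_mix_rejected(self):
        cat = synthetic_catalog()
        with pytest.raises(ValueError):
            sample_mutations_from_signatures(cat, (0.5, 0.5), 10, np.random.default_rng(0))
        with pytest.raises(ValueError):
            sample_mutations_from_signatures(cat, (2.0, -1.0, 0.0), 10,
                                             np.random.default_rng(0))

    def test_refit_recovers_mixture_within_3_points(self):
        cat = synthetic_catalog()
        two = (0.7, 0.3, 0.0)
        for seed in range(10):
            vec, _ = sample_mutations_from_signatures(
                cat, two, 5000, np.random.default_rng(seed))
            res = refit_exposures(vec, cat)
            assert abs(res.percents[0] - 70.0) <= 3.0, seed
            assert abs(res.percents[1] - 30.0) <= 3.0, seed


class TestGenerateCohort:
    def test_same_seed_byte_identical(self):
        cfg = SimConfig(n_case=3, n_control=2, mutations_per_sample=50, seed=4)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        assert a[0] == b[0] and a[1] == b[1]
        assert {k: v.tolist() for k, v in a[2].true_channel_counts.items()} == {
            k: v.tolist() for k, v in b[2].true_channel_counts.items()}

    def test_planted_driver_recovered_by_funnel(self):
        cfg = SimConfig(n_case=4, n_control=3, mutations_per_sample=80,
                        planted_drivers=(("GENEX", 3, ConsequenceClass.MISSENSE),),
                        seed=5)
        case, control, truth = generate_cohort(cfg)
        report = run_funnel(case, control, truth.drivers, [truth.reported])
        assert report.final_genes.symbols == frozenset({"GENEX"})
        assert truth.expected_final == {"GENEX"}

    def test_all_dbsnp_background_leaves_only_planted(self):
        cfg = SimConfig(n_case=3, n_control=2, mutations_per_sample=40,
                        planted_drivers=(), planted_reported_genes=(),
                        dbsnp_fraction=1.0, seed=6)
        case, control, truth = generate_cohort(cfg)
        assert all(r.dbsnp_id for r in case + control)
        from sigfunnel.records import GeneSet

        report = run_funnel(case, control, GeneSet("d", ["UNUSED"]), [])
        assert len(report.final_genes) == 0

    def test_synonymous_or_singleton_plantings_excluded_from_expectation(self):
        cfg = SimConfig(n_case=4, n_control=2, mutations_per_sample=30,
                        planted_drivers=(("SYNG", 3, ConsequenceClass.SYNONYMOUS),
                                         ("ONCE", 1, ConsequenceClass.MISSENSE),
                                         ("GOOD", 2, ConsequenceClass.SPLICE_DONOR)),
                        seed=7)
        case, control, truth = generate_cohort(cfg)
        assert truth.expected_final == {"GOOD"}
        report = run_funnel(case, control, truth.drivers, [truth.reported])
        assert report.final_genes.symbols == frozenset({"GOOD"})

    def test_channel_counts_cover_background(self):
        cfg = SimConfig(n_case=2, n_control=1, mutations_per_sample=60,
                        planted_drivers=(), planted_reported_genes=(), seed=8)
        case, control, truth = generate_cohort(cfg)
        by_sample = {}
        for r in case + control:
            by_sample[r.sample_id] = by_sample.get(r.sample_id, 0) + 1
        for sid, vec in truth.true_channel_counts.items():
            assert vec.sum() == by_sample.get(sid, 0)

    def test_refitter_closure_converges_with_n(self):
        """Exposure error against the configured mixture shrinks as n grows."""
        cat = synthetic_catalog()
        mix = np.array([0.84, 0.10, 0.06])
        errors = []
        for n in (500, 2000, 8000):
            errs = []
            for seed in range(3):
                vec, _ = sample_mutations_from_signatures(
                    cat, mix, n, np.random.default_rng(100 + seed))
                res = refit_exposures(vec, cat)
                errs.append(np.abs(res.percents / 100 - mix).sum())
            errors.append(np.mean(errs))
        assert errors[-1] < errors[0]
        assert errors[-1] < 0.05

    def test_random_configs_manifest_matches_funnel(self):
        rng = np.random.default_rng(123)
        classes = list(ConsequenceClass)
        for _ in range(25):
            n_case = int(rng.integers(2, 6))
            drivers = tuple(
                (f"DRV{j}", int(rng.integers(0, n_case + 1)),
                 classes[int(rng.integers(len(classes)))])
                for j in range(rng.integers(0, 4))
            )
            cfg = SimConfig(
                n_case=n_case,
                n_control=int(rng.integers(1, 4)),
                mutations_per_sample=float(rng.integers(20, 60)),
                planted_drivers=drivers,
                planted_reported_genes=("RPT1",) if rng.random() < 0.5 else (),
                dbsnp_fraction=float(rng.uniform(0, 0.3)),
                seed=int(rng.integers(2**31)),
            )
            case, control, truth = generate_cohort(cfg)
            report = run_funnel(case, control, truth.drivers, [truth.reported])
            assert report.final_genes.symbols == frozenset(truth.expected_final)


class TestTable4Fixture:
    def test_size_and_shape(self):
        records = table4_fixture()
        assert len(records) == 37  # one record per (mutation, sample) pair
        assert len({(r.gene, r.pos, r.hgvs_c) for r in records}) == 28
        assert len({r.gene for r in records}) == 14

    def test_gnaq_rows_match_print(self):
        records = [r for r in table4_fixture() if r.gene == "GNAQ"]
        assert {r.sample_id for r in records} == {"KT80", "KT721", "KT79"}
        assert {r.hgvs_c for r in records} == {"c.169A>T", "c.263A>T"}
        assert {r.hgvs_p for r in records} == {"p.K57*", "p.Q88L"}

    def test_hoxd13_position(self):
        records = [r for r in table4_fixture() if r.gene == "HOXD13"]
        assert all(r.chrom == "2" and r.pos == 176_957_650 for r in records)
        assert {r.sample_id for r in records} == {"KT79", "KT722"}

    def test_one_patient_two_samples_mapping(self):
        sheet = {s.sample_id: s for s in table1_samples()}
        assert sheet["KT80"].patient_id == sheet["KT721"].patient_id
        assert len({s.patient_id for s in table1_samples() if s.group is Group.CASE}) == 6
        assert sum(s.group is Group.CONTROL for s in table1_samples()) == 5
        for rec in table4_fixture():
            assert rec.group is Group.CASE
            assert rec.patient_id == sheet[rec.sample_id].patient_id

    def test_fixture_classifies_cleanly(self):
        records = annotate_consequences(table4_fixture())
        assert all(r.consequence is not ConsequenceClass.OTHER for r in records)
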