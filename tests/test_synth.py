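import numpy as np
import pytest
from scipy import stats

from its_profiler import synth
from its_profiler.composition import composition_report
from its_profiler.folding import structure_report
from its_profiler.motifs import scan_all
from its_profiler.phylogeny import p_distance


class TestGenerateTemplates:
    def test_seeded_bit_reproducibility(self):
        a = synth.generate_templates(synth.SyntheticSpec(seed=42))
        b = synth.generate_templates(synth.SyntheticSpec(seed=42))
        assert [(r.id, r.sequence) for r in a.records] == \
               [(r.id, r.sequence) for r in b.records]

    def test_zero_divergence_identical_leaves(self):
        lineage = synth.Lineage("root", 0.0, [
            synth.Lineage("x", 0.0), synth.Lineage("y", 0.0)])
        tset = synth.generate_templates(synth.SyntheticSpec(seed=1, lineage=lineage))
        assert tset.records[0].sequence == tset.records[1].sequence

    def test_pairwise_divergence_within_binomial_ci(self):
        p = 0.05
        lineage = synth.Lineage("root", 0.0, [
            synth.Lineage("x", p), synth.Lineage("y", p)])
        tset = synth.generate_templates(synth.SyntheticSpec(seed=2, lineage=lineage))
        s, e = tset.annotation.its1
        a = tset.records[0].subregion(s, e)
        b = tset.records[1].subregion(s, e)
        observed = p_distance(a, b)
        # two branches; a site differs unless both kept or mutated alike
        n = e - s + 1
        p_expected = 2 * p * (1 - p) + p * p * (2 / 3)
        lo, hi = stats.binom.interval(0.999, n, p_expected)
        assert lo / n <= observed <= hi / n

    def test_templates_functional_by_construction(self, template_set):
        ann = template_set.annotation
        for rec in template_set.records:
            r58s = rec.subregion(*ann.r58s)
            its2 = rec.subregion(*ann.its2)
            assert all(m.n_mismatches == 0 for m in scan_all(r58s).values())
            rep = structure_report(its2, r58s)
            assert rep.overall_its2_ok and rep.overall_58s_ok

    def test_lengths_match_spec(self, template_set):
        ann = template_set.annotation
        assert ann.length("ITS1") == 220
        assert ann.length("5.8S") == 155
        assert ann.length("ITS2") == 210

    def test_invalid_divergence_rejected(self):
        with pytest.raises(ValueError):
            synth.SyntheticSpec(seed=1, lineage=synth.Lineage("root", 0.0, [
                synth.Lineage("x", 0.8)]))


class TestPseudogenize:
    def test_identity_when_no_defects(self, template_set):
        rec = template_set.records[0]
        psi = synth.pseudogenize(rec, template_set.annotation,
                                 synth.PseudogenizeParams())
        assert psi.record.sequence == rec.sequence
        assert psi.truth["defects"] == []

    def test_41nt_deletion_total_length(self, template_set):
        rec = template_set.records[0]
        assert template_set.annotation.length("total") == 585
        psi = synth.pseudogenize(
            rec, template_set.annotation,
            synth.PseudogenizeParams(its1_deletion=synth.CLASSIC_DELETION))
        assert psi.annotation.length("total") == 544
        assert len(psi.record.sequence) == len(rec.sequence) - 41

    def test_motif_hit_closed_loop(self, template_set):
        """Injected M1 hits at 11 and 16 are reported at exactly [11, 16]."""
        psi = synth.pseudogenize(
            template_set.records[0], template_set.annotation,
            synth.PseudogenizeParams(motif_hits=[("M1", 11, "T"), ("M1", 16, "T")]))
        r58s = psi.record.subregion(*psi.annotation.r58s)
        rep = scan_all(r58s)["M1"]
        assert rep.mismatch_positions == [11, 16]
        assert rep.mismatch_bases == ["T", "T"]

    def test_helix_break_flips_target(self, template_set):
        psi = synth.pseudogenize(
            template_set.records[0], template_set.annotation,
            synth.PseudogenizeParams(break_helices=["B6"]))
        rep = structure_report(
            psi.record.subregion(*psi.annotation.its2),
            psi.record.subregion(*psi.annotation.r58s))
        assert rep.r58s_constraints["B6"] is False
        assert all(rep.r58s_constraints[h] for h in ("B4", "B5", "B7", "B8a", "B8b"))

    def test_cpg_deamination_lowers_gc(self, template_set):
        rec = template_set.records[0]
        psi = synth.pseudogenize(rec, template_set.annotation,
                                 synth.PseudogenizeParams(cpg_rate=0.8),
                                 rng=np.random.default_rng(3))
        assert psi.truth["cpg_deaminated"] > 0
        comp0 = composition_report(rec, template_set.annotation)
        comp1 = composition_report(psi.record, psi.annotation)
        assert comp1.gc["total"] < comp0.gc["total"]

    def test_unknown_motif_request_errors(self, template_set):
        broken = synth.pseudogenize(
            template_set.records[0], template_set.annotation,
            synth.PseudogenizeParams(motif_hits=[("M1", 11, "T")]))
        with pytest.raises(ValueError, match="not present"):
            synth.pseudogenize(broken.record, broken.annotation,
                               synth.PseudogenizeParams(motif_hits=[("M1", 12, "A")]))


class TestSimulateClones:
    def test_zero_error_identical(self, template_set):
        clones, truth = synth.simulate_clones([template_set.records[0]], 10, 0.0,
                                              seed=4)
        assert all(c.sequence == template_set.records[0].sequence for c in clones)
        assert set(truth.values()) == {template_set.records[0].id}

    def test_error_count_within_binomial_ci(self, template_set):
        rec = template_set.records[0]
        rate = 0.005
        clones, _ = synth.simulate_clones([rec], 300, rate, seed=5)
        total_errors = sum(
            sum(a != b for a, b in zip(c.sequence, rec.sequence)) for c in clones)
        n = len(rec.sequence) * 300
        lo, hi = stats.binom.interval(0.999, n, rate)
        assert lo <= total_errors <= hi

    def test_bad_weights(self, template_set):
        with pytest.raises(ValueError, match="sum to 1"):
            synth.simulate_clones(template_set.records[:2], 10, 0.001,
                                  mixture_weights=[0.5, 0.2], seed=1)

    def test_counts_respected(self, template_set):
        clones, truth = synth.simulate_clones(
            template_set.records[:2], 15, 0.0, counts=[8, 7], seed=6)
        ids = list(truth.values())
        assert ids.count(template_set.records[0].id) == 8
        assert ids.count(template_set.records[1].id) == 7

    def test_error_rate_ceiling(self, template_set):
        with pytest.raises(ValueError):
            synth.simulate_clones([template_set.records[0]], 5, 0.05, seed=1)


class TestSimulateReads:
    def test_single_full_length_read(self, template_set):
        contig = template_set.records[0]
        reads, placements = synth.simulate_reads(
            contig, coverage=1, read_len=len(contig.sequence), seed=7)
        assert len(reads) == 1
        assert placements[0].start == 1

    def test_zero_error_exact_substrings(self, template_set):
        contig = template_set.records[0]
        reads, placements = synth.simulate_reads(contig, coverage=5, read_len=80,
                                                 error_rate=0.0, seed=8)
        from its_profiler.coverage import reverse_complement

        for read, pl in zip(reads, placements):
            sub = contig.sequence[pl.start - 1 : pl.end]
            expected = sub if pl.strand == "+" else reverse_complement(sub)
            assert read.sequence == expected

    def test_bad_coverage(self, template_set):
        with pytest.raises(ValueError):
            synth.simulate_reads(template_set.records[0], coverage=0, read_len=50)

    def test_read_longer_than_contig(self, template_set):
        with pytest.raises(ValueError):
            synth.simulate_reads(template_set.records[0], coverage=1,
                                 read_len=10_000)


class TestBenchmark:
    def test_reproducible(self):
        a = synth.pseudogene_benchmark(seed=9, n_functional=5, n_pseudogene=5)
        b = synth.pseudogene_benchmark(seed=9, n_functional=5, n_pseudogene=5)
        assert [(r.id, r.sequence) for r, _, _ in a] == \
               [(r.id, r.sequence) for r, _, _ in b]

    def test_labels_balanced(self):
        bench = synth.pseudogene_benchmark(seed=10, n_functional=7, n_pseudogene=9)
        labels = [is_psi for _, _, is_psi in bench]
        assert labels.count(False) == 7
        assert labels.count(True) == 9
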