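"""Whole-genome SNP comparison: anchors, chains, calls, windows, the
acquisition contrast, and codon-level effect annotation."""
import itertools
import math

import numpy as np
import pytest

from islekit.genome import Feature, Genome, revcomp
from islekit.snp import (
    SnpRecord,
    acquisition_contrast_test,
    anchor_chain_align,
    annotate_coding_effect,
    call_snps,
    chain_anchors,
    find_anchors,
    label_snp_regions,
    read_vcf,
    region_snp_frequency,
    window_snp_histogram,
    write_vcf,
)


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestAnchorChain:
    def test_identical_sequences_one_full_block_no_snps(self):
        rng = np.random.default_rng(0)
        seq = _random_seq(rng, 20_000)
        smap = anchor_chain_align(seq, seq)
        assert len(smap.blocks) == 1
        b = smap.blocks[0]
        assert (b.ref_start, b.ref_end) == (0, 20_000)
        assert smap.unaligned_ref == []
        assert call_snps(smap) == []

    def test_planted_substitutions_called_exactly(self):
        rng = np.random.default_rng(1)
        ref = _random_seq(rng, 30_000)
        qry = list(ref)
        planted = {}
        for pos in rng.choice(30_000, size=10, replace=False):
            old = qry[pos]
            new = "ACGT"[("ACGT".index(old) + 1) % 4]
            qry[pos] = new
            planted[int(pos)] = (old, new)
        smap = anchor_chain_align(ref, "".join(qry))
        snps = call_snps(smap)
        assert {(s.position): (s.ref_base, s.alt_base) for s in snps} == planted

    def test_n_columns_skipped(self):
        ref = "ACGT" * 2_000
        qry = ref[:5_000] + "N" + ref[5_001:]
        smap = anchor_chain_align(ref, qry)
        assert call_snps(smap) == []

    def test_chain_weight_matches_exponential_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            n = 12
            anchors = [
                (int(r), int(q), int(l))
                for r, q, l in zip(
                    rng.integers(0, 500, n), rng.integers(0, 500, n), rng.integers(5, 30, n)
                )
            ]
            _, weight = chain_anchors(anchors)
            best = 0
            for mask in range(1 << n):
                subset = [anchors[i] for i in range(n) if mask >> i & 1]
                subset.sort()
                ok = all(
                    a[0] + a[2] <= b[0] and a[1] + a[2] <= b[1]
                    for a, b in zip(subset, subset[1:])
                )
                if ok:
                    best = max(best, sum(a[2] for a in subset))
            assert weight == best

    def test_anchors_are_unique_maximal_matches(self):
        ref = "AAACGTACGTGGGTTTACGTACGAACCC"
        qry = ref
        anchors = find_anchors(ref, qry, min_anchor=8)
        # self-comparison: everything merges into one full-length anchor
        assert anchors == [(0, 0, len(ref))]

    def test_unrelated_sequences_flagged_unaligned(self):
        rng = np.random.default_rng(3)
        ref = _random_seq(rng, 2_000)
        qry = _random_seq(rng, 2_000)
        smap = anchor_chain_align(ref, qry, min_anchor=20, max_gap=100)
        covered = smap.aligned_ref_length() + sum(e - s for s, e in smap.unaligned_ref)
        assert covered == 2_000


class TestWindowsAndFrequencies:
    def _snps(self, positions):
        return [SnpRecord("c", p, "A", "G") for p in positions]

    def test_window_counting_example(self):
        track = window_snp_histogram(self._snps([10, 400, 700]), (0, 1_000), 500)
        assert track.counts == [2, 1]

    def test_empty_snps_all_zero(self):
        track = window_snp_histogram([], (0, 1_000), 500)
        assert track.counts == [0, 0]

    def test_last_partial_window_keeps_true_length(self):
        track = window_snp_histogram([], (0, 1_250), 500)
        assert track.effective_lengths == [500, 500, 250]

    def test_window_counts_partition_all_snps(self, small_cohort):
        from islekit.snp import anchor_chain_align, call_snps

        t = small_cohort.truth
        ref, qry = t.contrast_pair
        smap = anchor_chain_align(
            small_cohort.genomes[ref], small_cohort.genomes[qry]
        )
        snps = call_snps(smap)
        glen = len(small_cohort.genomes[ref].contigs["chr"])
        track = window_snp_histogram(snps, (0, glen), 500, smap)
        assert sum(track.counts) == len(snps)

    def test_frequency_arithmetic(self):
        rng = np.random.default_rng(7)
        seq = _random_seq(rng, 1_000)
        smap = anchor_chain_align(seq, seq)
        snps = self._snps([10, 100, 200, 300, 400])
        count, denom, freq = region_snp_frequency(snps, (0, 1_000), smap)
        assert (count, denom, freq) == (5, 1_000, 0.005)

    def test_aligned_vs_total_denominator(self):
        # Half the region unaligned: aligned denominator doubles the rate.
        rng = np.random.default_rng(4)
        left = _random_seq(rng, 1_000)
        ref = left + _random_seq(rng, 1_000)
        qry = left  # second half missing from the query
        smap = anchor_chain_align(ref, qry, max_gap=100)
        snps = self._snps([10, 100, 200, 300, 400])
        _, n_aln, f_aln = region_snp_frequency(snps, (0, 2_000), smap, "aligned")
        _, n_tot, f_tot = region_snp_frequency(snps, (0, 2_000), smap, "total")
        assert n_tot == 2_000 and f_tot == 0.0025
        assert n_aln == pytest.approx(1_000, abs=30)
        assert f_aln == pytest.approx(0.005, rel=0.05)

    def test_zero_denominator_is_an_error(self):
        smap = anchor_chain_align("ACGT" * 100, "ACGT" * 100)
        with pytest.raises(ValueError):
            region_snp_frequency([], (0, 0), smap)

    def test_vcf_roundtrip(self, tmp_path):
        snps = [SnpRecord("c", 5, "A", "G", "island"), SnpRecord("c", 9, "T", "C")]
        write_vcf(tmp_path / "x.vcf", snps, "ref", "qry")
        assert read_vcf(tmp_path / "x.vcf") == snps


def binom_tail_oracle(k: int, n: int, p: float) -> float:
    """Brute-force summation of the binomial lower tail."""
    total = 0.0
    logp, log1p = math.log(p), math.log1p(-p)
    for i in range(k + 1):
        total += math.exp(
            math.lgamma(n + 1) - math.lgamma(i + 1) - math.lgamma(n - i + 1)
            + i * logp + (n - i) * log1p
        )
    return total


class TestContrast:
    def test_zero_island_snps_at_one_percent_backbone(self):
        r = acquisition_contrast_test((0, 1_000), (100, 10_000))
        assert r.p_value == pytest.approx(0.99**1_000, rel=1e-9)
        assert r.p_value == pytest.approx(4.3171e-5, rel=1e-3)
        assert r.call == "recent_independent"

    def test_equal_rates_called_ancestral_vertical(self):
        r = acquisition_contrast_test((100, 10_000), (1_000, 100_000))
        assert r.ratio == pytest.approx(1.0)
        assert r.call == "ancestral_vertical"

    def test_tail_matches_brute_force_summation(self):
        cases = [(0, 50, 0.02), (3, 200, 0.01), (10, 1_000, 0.02), (25, 1_000, 0.03)]
        for k, n, p in cases:
            got = acquisition_contrast_test((k, n), (int(p * 1e6), 1_000_000))
            assert abs(got.p_value - binom_tail_oracle(k, n, p)) < 1e-12

    def test_p_value_monotone_in_island_count(self):
        ps = [
            acquisition_contrast_test((k, 1_000), (200, 10_000)).p_value
            for k in range(0, 40, 4)
        ]
        assert ps == sorted(ps)

    def test_zero_backbone_rate_is_an_error(self):
        with pytest.raises(ValueError):
            acquisition_contrast_test((0, 100), (0, 1_000))


def _gene_with_codon(codon: str, residue_1based: int, n_codons: int = 800):
    """A CDS carrying `codon` at the given residue, on the + strand."""
    filler = "GCT"  # Ala
    codons = ["ATG"] + [filler] * (n_codons - 2) + ["TAA"]
    codons[residue_1based - 1] = codon
    seq = "".join(codons)
    g = Genome("g", {"c": seq}, [Feature("gene", "CDS", "c", 0, len(seq), "+")])
    return g


class TestCodingEffects:
    def test_ile_to_leu_at_431_formats_as_I431L(self):
        g = _gene_with_codon("ATT", 431)
        pos = 430 * 3  # first base of codon 431
        snp = SnpRecord("c", pos, "A", "C")  # ATT -> CTT = Leu
        eff = annotate_coding_effect(snp, g.get_feature("gene"), g)
        assert eff.classification == "nonsynonymous"
        assert eff.substitution == "I431L"

    def test_synonymous_ala_codon(self):
        g = _gene_with_codon("GCT", 10)
        snp = SnpRecord("c", 9 * 3 + 2, "T", "C")  # GCT -> GCC
        eff = annotate_coding_effect(snp, g.get_feature("gene"), g)
        assert eff.classification == "synonymous"

    def test_internal_stop_is_nonsense(self):
        g = _gene_with_codon("TAT", 50)
        snp = SnpRecord("c", 49 * 3 + 2, "T", "A")  # TAT -> TAA
        eff = annotate_coding_effect(snp, g.get_feature("gene"), g)
        assert eff.classification == "nonsense"

    def test_start_codon_loss(self):
        g = _gene_with_codon("GCT", 10)
        snp = SnpRecord("c", 0, "A", "C")  # ATG -> CTG (not a start)
        eff = annotate_coding_effect(snp, g.get_feature("gene"), g)
        assert eff.classification == "start_loss"

    def test_reverse_strand_annotation(self):
        fwd = _gene_with_codon("ATT", 5, n_codons=20)
        seq = fwd.contigs["c"]
        g = Genome(
            "g", {"c": revcomp(seq)},
            [Feature("gene", "CDS", "c", 0, len(seq), "-")],
        )
        # The + strand base at revcomp position of codon-5 first base:
        pos = len(seq) - 1 - (4 * 3)  # complement of 'A' of ATT
        snp = SnpRecord("c", pos, "T", "G")  # revcomp: A->C, ATT->CTT
        eff = annotate_coding_effect(snp, g.get_feature("gene"), g)
        assert eff.classification == "nonsynonymous"
        assert eff.substitution == "I5L"

    def test_unphased_cds_length_is_an_error(self):
        g = Genome("g", {"c": "ATGAAAT"}, [Feature("gene", "CDS", "c", 0, 7, "+")])
        snp = SnpRecord("c", 4, "A", "G")
        with pytest.raises(ValueError, match="divisible"):
            annotate_coding_effect(snp, g.get_feature("gene"), g)


class TestRegionLabels:
    def test_partition_of_all_snps(self):
        snps = [SnpRecord("c", p, "A", "G") for p in (5, 150, 600, 900)]
        label_snp_regions(snps, [(100, 700)])
        assert [s.region for s in snps] == ["backbone", "island", "island", "backbone"]
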