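"""Upstream extraction, core-motif scan, consensus, and variants."""

import numpy as np
import pytest

from phagemine.genome import GeneFeature, SequenceRecord, reverse_complement
from phagemine.promoters import (
    BAC_CORE_FULL,
    PromoterHit,
    SubstitutionSpec,
    apply_substitutions,
    build_consensus,
    coord_to_index,
    enumerate_variants,
    extract_upstream,
    index_to_coord,
    scan_core_motif,
)

PLANTED = "TAATTAACCCACACTATAGGGACA"


def make_hit(window, span=(18, 6)):
    return PromoterHit("c", 100, "+", window, "g", 50, span)


class TestCoordinates:
    @pytest.mark.parametrize("coord,index", [(-18, 0), (-1, 17), (1, 18), (6, 23)])
    def test_round_trip(self, coord, index):
        assert coord_to_index(coord, 18) == index
        assert index_to_coord(index, 18) == coord

    def test_position_zero_rejected(self):
        with pytest.raises(ValueError):
            coord_to_index(0, 18)


class TestExtractUpstream:
    def test_plus_strand_coordinates(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        contig = SequenceRecord("c", seq)
        gene = GeneFeature("c", 201, 800, "+", "cds", "g")
        up, truncated = extract_upstream(contig, gene, 100)
        assert up == seq[100:200] and not truncated

    def test_minus_strand_reverse_complement(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        contig = SequenceRecord("c", seq)
        gene = GeneFeature("c", 1, 600, "-", "cds", "g")
        up, truncated = extract_upstream(contig, gene, 100)
        assert up == reverse_complement(seq[600:700]) and not truncated

    def test_contig_start_truncates_with_flag(self):
        contig = SequenceRecord("c", "A" * 800)
        gene = GeneFeature("c", 50, 700, "+", "cds", "g")
        up, truncated = extract_upstream(contig, gene, 100)
        assert len(up) == 49 and truncated


class TestScanCoreMotif:
    def test_full_core_on_printed_t7_promoter(self):
        """The full core CACTATAG spans -7..+1: the implied +1 is the final
        G of the core, 18 nt into the printed T7 promoter string."""
        t7 = "TAATACGACTCACTATAGGGAGA"
        prefix = "G" * 30
        gene_start = len(prefix) + len(t7) + 11
        contig = SequenceRecord("c", prefix + t7 + "G" * 10 + "ATGAAATAA" + "G" * 20)
        genes = [GeneFeature("c", gene_start, gene_start + 8, "+", "cds", "g")]
        hits = scan_core_motif(contig, genes, core=BAC_CORE_FULL)
        assert len(hits) == 1
        hit = hits[0]
        assert hit.strand == "+"
        assert hit.plus_one == len(prefix) + 18  # final G of CACTATAG
        # the window carries the full core ending at +1
        assert hit.window_seq[coord_to_index(-7, 18) : coord_to_index(1, 18) + 1] == BAC_CORE_FULL

    def test_core_inside_annotated_cds_is_not_a_hit(self):
        seq = "G" * 20 + "CACTA" + "G" * 30 + "ATGAAATAA" + "G" * 10
        contig = SequenceRecord("c", seq)
        cds_over_core = GeneFeature("c", 10, 40, "+", "cds", "blocker")
        target = GeneFeature("c", 56, 64, "+", "cds", "g")
        assert scan_core_motif(contig, [cds_over_core, target]) == []
        # without the blocking CDS the same core is a hit
        assert len(scan_core_motif(contig, [target])) == 1

    def test_planted_instances_recovered_exactly(self, planted_contig):
        contig, genes, truth = planted_contig
        hits = scan_core_motif(contig, genes)
        assert len(hits) == len(truth.planted_promoters) == 14
        got = {(h.plus_one, h.strand, h.window_seq) for h in hits}
        want = {
            (p["plus_one"], p["strand"], p["window_seq"])
            for p in truth.planted_promoters
        }
        assert got == want

    def test_every_window_carries_core_at_minus7_minus3(self, planted_contig):
        contig, genes, _ = planted_contig
        for hit in scan_core_motif(contig, genes):
            lo, hi = coord_to_index(-7, 18), coord_to_index(-3, 18)
            assert hit.window_seq[lo : hi + 1] == "CACTA"

    def test_invariant_under_contig_reverse_complement(self, planted_contig):
        contig, genes, _ = planted_contig
        n = len(contig.seq)
        flipped = SequenceRecord(contig.id, reverse_complement(contig.seq))
        flipped_genes = [
            GeneFeature(
                g.contig_id,
                n - g.end + 1,
                n - g.start + 1,
                "-" if g.strand == "+" else "+",
                g.kind,
                g.id,
            )
            for g in genes
        ]
        fwd = scan_core_motif(contig, genes)
        rev = scan_core_motif(flipped, flipped_genes)
        assert len(fwd) == len(rev)
        assert sorted(h.window_seq for h in fwd) == sorted(h.window_seq for h in rev)

    def test_no_hits_yields_empty_list(self):
        contig = SequenceRecord("c", "G" * 200)
        assert scan_core_motif(contig, [GeneFeature("c", 100, 150, "+", "cds", "g")]) == []


class TestBuildConsensus:
    def test_identical_windows(self):
        cons = build_consensus([make_hit(PLANTED)] * 5)
        assert cons.consensus_seq == PLANTED
        assert cons.ambiguous_columns == ()
        assert cons.n_hits == 5

    def test_two_to_one_majority(self):
        variant = "A" + PLANTED[1:]
        cons = build_consensus([make_hit(PLANTED), make_hit(PLANTED), make_hit(variant)])
        assert cons.consensus_seq == PLANTED

    def test_tie_recorded_and_broken_by_precedence(self):
        variant = "G" + PLANTED[1:]  # column 0: T vs G, 1:1
        with pytest.warns(UserWarning, match="ties"):
            cons = build_consensus([make_hit(PLANTED), make_hit(variant)])
        assert 0 in cons.ambiguous_columns
        assert cons.consensus_seq[0] == "G"  # G precedes T in A>C>G>T order

    def test_counts_sum_to_n_hits(self, planted_contig):
        contig, genes, _ = planted_contig
        hits = scan_core_motif(contig, genes)
        cons = build_consensus(hits)
        assert all(sum(c.values()) == cons.n_hits for c in cons.counts)

    def test_noisy_planted_promoter_recovered(self, planted_contig):
        """14 windows at per-position noise 0.1 still vote the planted
        24-mer back in (seed-fixed)."""
        contig, genes, truth = planted_contig
        assert truth.noise_rate == 0.1
        cons = build_consensus(scan_core_motif(contig, genes))
        assert cons.consensus_seq == PLANTED

    def test_empty_and_mixed_spans_rejected(self):
        with pytest.raises(ValueError):
            build_consensus([])
        with pytest.raises(ValueError):
            build_consensus([make_hit(PLANTED), make_hit("A" * 23, span=(17, 6))])


class TestApplySubstitutions:
    def test_empty_list_is_identity(self):
        assert apply_substitutions(PLANTED, []) == PLANTED

    def test_plus5_G_on_1575_3_promoter_gives_t7_like_tss(self):
        out = apply_substitutions(PLANTED, [SubstitutionSpec(5, "G")])
        tss = out[coord_to_index(1, 18) : coord_to_index(6, 18) + 1]
        assert tss == "GGGAGA"

    def test_inverse_substitution_restores_input(self):
        fwd = SubstitutionSpec(5, "G")
        back = SubstitutionSpec(5, PLANTED[coord_to_index(5, 18)])
        out = apply_substitutions(apply_substitutions(PLANTED, [fwd]), [back])
        assert out == PLANTED

    def test_position_zero_and_out_of_span_rejected(self):
        with pytest.raises(ValueError):
            SubstitutionSpec(0, "A")
        with pytest.raises(ValueError):
            apply_substitutions(PLANTED, [SubstitutionSpec(7, "A")])

    def test_same_base_substitution_warns(self):
        base = PLANTED[coord_to_index(5, 18)]
        with pytest.warns(UserWarning):
            apply_substitutions(PLANTED, [SubstitutionSpec(5, base)])


class TestEnumerateVariants:
    def test_uniform_hits_give_no_variants(self):
        hits = [make_hit(PLANTED)] * 4
        cons = build_consensus(hits)
        assert enumerate_variants(cons, hits) == []

    def test_single_substitution_variant_with_support(self):
        changed = apply_substitutions(PLANTED, [SubstitutionSpec(5, "G")])
        hits = [make_hit(PLANTED)] * 3 + [make_hit(changed)]
        cons = build_consensus(hits)
        variants = enumerate_variants(cons, hits)
        assert variants[0][1] == (SubstitutionSpec(5, "G"),)
        assert variants[0][2] == 1
        assert variants[0][0] == changed

    def test_double_substitution_appears(self):
        """Substitutions seen together at two TSS positions in several hits
        yield the double variant among the enumerated set."""
        double = apply_substitutions(
            PLANTED, [SubstitutionSpec(3, "A"), SubstitutionSpec(5, "G")]
        )
        hits = [make_hit(PLANTED)] * 5 + [make_hit(double)] * 3
        cons = build_consensus(hits)
        variants = enumerate_variants(cons, hits, max_variants=8)
        subs_sets = [v[1] for v in variants]
        assert (SubstitutionSpec(3, "A"), SubstitutionSpec(5, "G")) in subs_sets
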