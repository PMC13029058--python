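"""Candidate filters, deduplication, block ranking, catalytic residues."""

import pytest

from phagemine.genome import SequenceRecord
from phagemine.mining import (
    CATALYTIC_RESIDUES_T7,
    CandidateRecord,
    MiningConfig,
    apply_mining_filters,
    build_candidates,
    check_catalytic_residues,
    classify_orfs,
    deduplicate,
    drop_unclonable,
    rank_into_blocks,
    retained,
)
from phagemine.simulate import generate_candidate_fixture, make_seed_rnap


def make_candidate(**kw):
    defaults = dict(
        id="c1",
        contig_id="t1",
        protein="M" + "A" * 700,
        aa_length=701,
        identity_to_reference=55.0,
        best_reference="ref",
        has_capsid_partner=True,
    )
    defaults.update(kw)
    return CandidateRecord(**defaults)


class TestClassifyOrfs:
    def test_identical_orf_is_rnap_like_at_100(self, seed_rnap, seed_capsid):
        from phagemine.genome import GeneFeature, OrfRecord

        orf = OrfRecord(
            GeneFeature("c", 1, 3 * (len(seed_rnap.seq) + 1), "+", "cds", "o1"),
            seed_rnap.seq,
            len(seed_rnap.seq),
        )
        out = classify_orfs([orf], [seed_rnap], [seed_capsid])
        assert out[0].kind == "rnap_like" and out[0].identity == 100.0

    def test_unrelated_orf_is_other(self, seed_rnap, seed_capsid):
        from phagemine.genome import GeneFeature, OrfRecord

        orf = OrfRecord(
            GeneFeature("c", 1, 3 * 121, "+", "cds", "o2"), "M" + "PG" * 60, 121
        )
        out = classify_orfs([orf], [seed_rnap], [seed_capsid])
        assert out[0].kind == "other"

    def test_planted_contig_yields_one_rnap_and_one_capsid(
        self, planted_contig, seed_rnap, seed_capsid
    ):
        from phagemine.genome import find_orfs, longest_orfs

        contig, genes, truth = planted_contig
        orfs = longest_orfs(find_orfs(contig, min_aa_length=100))
        out = classify_orfs(orfs, [seed_rnap], [seed_capsid])
        kinds = [c.kind for c in out]
        assert kinds.count("rnap_like") == 1 and kinds.count("capsid_like") == 1
        rnap = next(c for c in out if c.kind == "rnap_like")
        assert rnap.identity == pytest.approx(
            truth.planted_rnap["realized_identity"], abs=3
        )

    def test_empty_reference_set_rejected(self, seed_rnap):
        with pytest.raises(ValueError):
            classify_orfs([], [], [seed_rnap])


class TestMiningFilters:
    def test_length_boundary_is_strict(self):
        short = make_candidate(aa_length=599)
        boundary = make_candidate(aa_length=600)
        kept = make_candidate(aa_length=601)
        out = apply_mining_filters([short, boundary, kept], [])
        assert out[0].excluded_reason == "too_short"
        assert out[1].excluded_reason == "too_short"  # "greater than 600" is strict
        assert out[2].excluded_reason is None

    def test_full_length_known_match_is_not_novel(self):
        cand = make_candidate()
        known = [SequenceRecord("k", cand.protein, "protein")]
        out = apply_mining_filters([cand], known)
        assert out[0].excluded_reason == "not_novel" and not out[0].is_novel

    def test_partial_perfect_match_does_not_disqualify(self):
        cand = make_candidate()
        known = [SequenceRecord("k", cand.protein[:300], "protein")]
        assert apply_mining_filters([cand], known)[0].excluded_reason is None

    def test_precedence_order_assigns_exactly_one_reason(self):
        cand = make_candidate(has_capsid_partner=False, aa_length=100,
                              identity_to_reference=5.0)
        out = apply_mining_filters([cand], [])
        assert out[0].excluded_reason == "no_capsid"  # first gate wins

    def test_empty_input_gives_empty_output(self):
        assert apply_mining_filters([], []) == []


class TestDeduplicate:
    def test_identical_pair_keeps_first(self):
        a = make_candidate(id="a")
        b = make_candidate(id="b")
        out = deduplicate([a, b], 98.0)
        assert out[0].excluded_reason is None
        assert out[1].excluded_reason == "duplicate"

    def test_idempotent(self):
        cands, _ = generate_candidate_fixture(20, 3, 0, seed=5)
        once = deduplicate(cands, 98.0)
        reasons_once = [c.excluded_reason for c in once]
        twice = deduplicate(once, 98.0)
        assert [c.excluded_reason for c in twice] == reasons_once

    def test_funnel_counts_74_64_53(self):
        cands, _ = generate_candidate_fixture(74, 10, 11, seed=1)
        cands = deduplicate(cands, 98.0)
        assert len(retained(cands)) == 64
        cands = drop_unclonable(cands)
        assert len(retained(cands)) == 53


class TestRankIntoBlocks:
    def test_one_candidate_per_default_block(self):
        cands = [
            make_candidate(id=f"c{i}", identity_to_reference=ident)
            for i, ident in enumerate([35, 45, 55, 65, 75])
        ]
        out = rank_into_blocks(cands, MiningConfig(n_select_total=5))
        assert [c.block for c in out] == [1, 2, 3, 4, 5]
        assert all(c.selected for c in out)

    def test_identity_at_window_edge_is_a_bug_signal(self):
        cand = make_candidate(identity_to_reference=80.0)
        with pytest.raises(ValueError):
            rank_into_blocks([cand], MiningConfig())

    def test_round_robin_selection_takes_five_per_block(self):
        cands = []
        for b in range(5):
            for i in range(10):
                cands.append(
                    make_candidate(
                        id=f"b{b}i{i}",
                        identity_to_reference=30 + 10 * b + i * 0.5,
                    )
                )
        out = rank_into_blocks(cands, MiningConfig(n_select_total=25))
        per_block = {b: 0 for b in range(1, 6)}
        for c in out:
            if c.selected:
                per_block[c.block] += 1
        assert per_block == {1: 5, 2: 5, 3: 5, 4: 5, 5: 5}

    def test_blocks_partition_the_window(self):
        cands = [
            make_candidate(id=f"c{i}", identity_to_reference=ident)
            for i, ident in enumerate([30.0, 39.999, 40.0, 49.9, 50.0, 79.999])
        ]
        out = rank_into_blocks(cands, MiningConfig())
        assert [c.block for c in out] == [1, 1, 2, 2, 3, 5]


class TestCatalyticResidues:
    def test_reference_against_itself_conserves_all_seven(self, seed_rnap):
        report = check_catalytic_residues(seed_rnap.seq, seed_rnap.seq)
        assert report.n_conserved == 7
        assert len(report.residue_map) == 7

    def test_single_substitution_drops_one(self, seed_rnap):
        mutated = list(seed_rnap.seq)
        assert mutated[536] == "D"
        mutated[536] = "A"  # the catalytic Asp at position 537
        report = check_catalytic_residues("".join(mutated), seed_rnap.seq)
        assert report.n_conserved == 6
        entry = next(e for e in report.residue_map if e[0] == 537)
        assert entry[4] is False and entry[3] == "A"

    def test_nterminal_extension_absorbed_by_alignment(self, seed_rnap):
        extended = "MGSSHHHHHH" + seed_rnap.seq
        report = check_catalytic_residues(extended, seed_rnap.seq)
        assert report.n_conserved == 7
        entry = next(e for e in report.residue_map if e[0] == 472)
        assert entry[2] == 482  # candidate position shifted by the tag

    def test_position_beyond_reference_rejected(self):
        with pytest.raises(ValueError):
            check_catalytic_residues("MKV" * 100, "MKV" * 10, [(300, "K")])


class TestBuildCandidates:
    def test_capsid_partner_flag_is_per_contig(self, planted_contig, seed_rnap, seed_capsid):
        from phagemine.genome import find_orfs, longest_orfs

        contig, genes, truth = planted_contig
        orfs = longest_orfs(find_orfs(contig, min_aa_length=100))
        cands = build_candidates(classify_orfs(orfs, [seed_rnap], [seed_capsid]))
        assert len(cands) == 1 and cands[0].has_capsid_partner
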