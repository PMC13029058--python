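"""Candidate selection for phage single-subunit RNA polymerases (ssRNAPs).

The mining funnel: ORFs are labelled against ssRNAP and capsid reference
proteins; candidates then pass, in fixed precedence order, a capsid
co-occurrence gate, a minimum-length gate (full-length polymerases are
>600 aa), an identity window to the reference (30-80 %, enriching for novel
but recognisable homologs), and a novelty gate (no full-length 100 % match
in a known-protein collection). Near-duplicates (>98 % pairwise identity)
are collapsed to one representative, and survivors are ranked into
equal-width identity blocks from which the final set is drawn round-robin.

A conservation report for the seven catalytic residues of the T7-type
active site (K472, D537, K627, K631, M635, Y639, D812 in T7 numbering) is
produced by mapping reference positions through a global alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .align import align, percent_identity
from .genome import OrfRecord, SequenceRecord

#: (position in the T7 reference, expected residue). The active-site set is
#: configuration, not hard-coded, because published descriptions of residue
#: 627 disagree (Lys vs Arg); the Lys reading is the default.
CATALYTIC_RESIDUES_T7: tuple[tuple[int, str], ...] = (
    (472, "K"),
    (537, "D"),
    (627, "K"),
    (631, "K"),
    (635, "M"),
    (639, "Y"),
    (812, "D"),
)

EXCLUSION_REASONS = (
    "no_capsid",
    "too_short",
    "identity_out_of_window",
    "not_novel",
    "duplicate",
    "unclonable",
)


@dataclass
class MiningConfig:
    min_aa_length: int = 600  # retained iff aa_length > this (strict)
    identity_window: tuple[float, float] = (30.0, 80.0)  # half-open [low, high)
    dedup_threshold: float = 98.0  # duplicates share identity > this
    novelty_threshold: float = 100.0
    n_blocks: int = 5
    n_select_total: int = 74
    call_min_identity: float = 30.0  # local-identity floor for rnap/capsid calls
    call_min_coverage: float = 0.5  # fraction of the reference that must align

    def __post_init__(self) -> None:
        low, high = self.identity_window
        if not (0 < low < high <= 100):
            raise ValueError(f"invalid identity window {self.identity_window}")
        if not (self.dedup_threshold < self.novelty_threshold <= 100):
            raise ValueError("dedup_threshold must be < novelty_threshold <= 100")


@dataclass
class CandidateRecord:
    id: str
    contig_id: str
    protein: str
    aa_length: int
    identity_to_reference: float
    best_reference: str
    has_capsid_partner: bool
    is_novel: bool = True
    unclonable: bool = False
    excluded_reason: Optional[str] = None
    block: Optional[int] = None
    selected: bool = False


@dataclass(frozen=True)
class ClassifiedOrf:
    orf: OrfRecord
    kind: str  # rnap_like | capsid_like | other
    identity: float
    best_reference: str


@dataclass(frozen=True)
class CatalyticResidueReport:
    #: (ref position, expected residue, candidate position or None,
    #:  candidate residue or None, conserved)
    residue_map: tuple[tuple[int, str, Optional[int], Optional[str], bool], ...]

    @property
    def n_conserved(self) -> int:
        return sum(1 for entry in self.residue_map if entry[4])


def _best_local_hit(
    protein: str, refs: Sequence[SequenceRecord]
) -> tuple[float, float, str]:
    """Best (identity, reference coverage, reference id) over a reference set."""
    best = (0.0, 0.0, "")
    for ref in refs:
        aln = align(protein, ref.seq, mode="local")
        ident = percent_identity(aln)
        coverage = len(aln.aligned_b.replace("-", "")) / len(ref.seq)
        if (ident, coverage) > (best[0], best[1]):
            best = (ident, coverage, ref.id)
    return best


def classify_orfs(
    orfs: Iterable[OrfRecord],
    rnap_refs: Sequence[SequenceRecord],
    capsid_refs: Sequence[SequenceRecord],
    config: MiningConfig | None = None,
) -> list[ClassifiedOrf]:
    """Label ORFs rnap_like / capsid_like / other by best local identity."""
    config = config or MiningConfig()
    if not rnap_refs or not capsid_refs:
        raise ValueError("reference sets must be non-empty")
    out = []
    for orf in orfs:
        r_ident, r_cov, r_ref = _best_local_hit(orf.aa_seq, rnap_refs)
        c_ident, c_cov, c_ref = _best_local_hit(orf.aa_seq, capsid_refs)
        r_ok = r_ident >= config.call_min_identity and r_cov >= config.call_min_coverage
        c_ok = c_ident >= config.call_min_identity and c_cov >= config.call_min_coverage
        if r_ok and (not c_ok or r_ident >= c_ident):
            out.append(ClassifiedOrf(orf, "rnap_like", r_ident, r_ref))
        elif c_ok:
            out.append(ClassifiedOrf(orf, "capsid_like", c_ident, c_ref))
        else:
            best = max(r_ident, c_ident)
            out.append(ClassifiedOrf(orf, "other", best, r_ref if r_ident >= c_ident else c_ref))
    return out


def build_candidates(classified: Iterable[ClassifiedOrf]) -> list[CandidateRecord]:
    """Turn rnap_like ORFs into candidates, noting per-contig capsid partners."""
    classified = list(classified)
    contigs_with_capsid = {c.orf.feature.contig_id for c in classified if c.kind == "capsid_like"}
    candidates = []
    for c in classified:
        if c.kind != "rnap_like":
            continue
        f = c.orf.feature
        candidates.append(
            CandidateRecord(
                id=f.id,
                contig_id=f.contig_id,
                protein=c.orf.aa_seq,
                aa_length=c.orf.aa_length,
                identity_to_reference=c.identity,
                best_reference=c.best_reference,
                has_capsid_partner=f.contig_id in contigs_with_capsid,
            )
        )
    return candidates


def apply_mining_filters(
    candidates: Iterable[CandidateRecord],
    known_proteins: Sequence[SequenceRecord],
    config: MiningConfig | None = None,
) -> list[CandidateRecord]:
    """Assign exclusion reasons in the fixed precedence order
    no_capsid -> too_short -> identity_out_of_window -> not_novel."""
    config = config or MiningConfig()
    low, high = config.identity_window
    # Full-length 100% global identity with equal lengths is equivalent to
    # exact string equality, so the novelty gate is a set lookup.
    known = {rec.seq for rec in known_proteins}
    out = []
    for cand in candidates:
        cand.is_novel = cand.protein not in known
        if not cand.has_capsid_partner:
            cand.excluded_reason = "no_capsid"
        elif cand.aa_length <= config.min_aa_length:
            cand.excluded_reason = "too_short"
        elif not (low <= cand.identity_to_reference < high):
            cand.excluded_reason = "identity_out_of_window"
        elif not cand.is_novel:
            cand.excluded_reason = "not_novel"
        else:
            cand.excluded_reason = None
        out.append(cand)
    return out


def deduplicate(
    candidates: Iterable[CandidateRecord], threshold: float = 98.0
) -> list[CandidateRecord]:
    """Greedy single-linkage grouping at > threshold pairwise identity.

    The first group member by input order is kept; the rest are excluded as
    ``duplicate``. Already-excluded candidates are passed through untouched,
    which makes the operation idempotent. A length-ratio prefilter skips
    pairs that provably cannot reach the threshold (identity over aligned
    columns is at most 100 * shorter/longer).
    """
    if not (0 < threshold <= 100):
        raise ValueError("threshold must be in (0, 100]")
    cands = list(candidates)
    active = [i for i, c in enumerate(cands) if c.excluded_reason is None]
    parent = {i: i for i in active}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for ai in range(len(active)):
        for bi in range(ai + 1, len(active)):
            i, j = active[ai], active[bi]
            la, lb = len(cands[i].protein), len(cands[j].protein)
            if 100.0 * min(la, lb) / max(la, lb) <= threshold:
                continue
            if find(i) == find(j):
                continue
            aln = align(cands[i].protein, cands[j].protein, mode="global")
            if percent_identity(aln) > threshold:
                parent[find(j)] = find(i)
    seen_groups: set[int] = set()
    for i in active:
        g = find(i)
        if g in seen_groups:
            cands[i].excluded_reason = "duplicate"
        else:
            seen_groups.add(g)
    return cands


def retained(candidates: Iterable[CandidateRecord]) -> list[CandidateRecord]:
    return [c for c in candidates if c.excluded_reason is None]


def drop_unclonable(candidates: Iterable[CandidateRecord]) -> list[CandidateRecord]:
    """Exclude candidates flagged as failing cloning (input exclusion list)."""
    out = []
    for c in candidates:
        if c.excluded_reason is None and c.unclonable:
            c.excluded_reason = "unclonable"
        out.append(c)
    return out


def rank_into_blocks(
    candidates: Iterable[CandidateRecord], config: MiningConfig | None = None
) -> list[CandidateRecord]:
    """Partition the identity window into equal-width half-open blocks,
    rank within each block (identity desc, then length, then id), and flag
    the selected set by round-robin over blocks up to ``n_select_total``."""
    config = config or MiningConfig()
    low, high = config.identity_window
    width = (high - low) / config.n_blocks
    cands = list(candidates)
    pool = retained(cands)
    blocks: dict[int, list[CandidateRecord]] = {b: [] for b in range(1, config.n_blocks + 1)}
    for c in pool:
        if not (low <= c.identity_to_reference < high):
            raise ValueError(
                f"candidate {c.id!r} identity {c.identity_to_reference} outside "
                f"window [{low}, {high}) — upstream filter bug"
            )
        b = min(int((c.identity_to_reference - low) // width) + 1, config.n_blocks)
        c.block = b
        blocks[b].append(c)
    for b in blocks:
        blocks[b].sort(key=lambda c: (-c.identity_to_reference, -c.aa_length, c.id))
    n_left = config.n_select_total
    rank = 0
    while n_left > 0 and any(rank < len(blocks[b]) for b in blocks):
        for b in sorted(blocks):
            if n_left == 0:
                break
            if rank < len(blocks[b]):
                blocks[b][rank].selected = True
                n_left -= 1
        rank += 1
    return cands


def check_catalytic_residues(
    candidate: str,
    reference: str,
    positions: Sequence[tuple[int, str]] = CATALYTIC_RESIDUES_T7,
) -> CatalyticResidueReport:
    """Map reference catalytic positions through a global alignment and
    report whether the candidate carries the expected residue at each."""
    for pos, _ in positions:
        if pos > len(reference):
            raise ValueError(f"position {pos} beyond reference length {len(reference)}")
    aln = align(candidate, reference, mode="global")
    wanted = {pos: res for pos, res in positions}
    found: dict[int, tuple[Optional[int], Optional[str]]] = {}
    cand_i = ref_i = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != "-":
            cand_i += 1
        if y != "-":
            ref_i += 1
            if ref_i in wanted:
                found[ref_i] = (cand_i, x) if x != "-" else (None, None)
    entries = []
    for pos, res in positions:
        cand_pos, cand_res = found.get(pos, (None, None))
        entries.append((pos, res, cand_pos, cand_res, cand_res == res))
    return CatalyticResidueReport(tuple(entries))
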