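"""Promoter discovery around the phage promoter core motif.

Phage T7/T3/SP6-type promoters share a near-identical core, CACTATAG,
spanning positions -7 to +1 in transcription-centric coordinates (no
position 0; +1 is the first transcribed base, the final G of the full
core). The discovery scan searches both strands for the conserved short
core CACTA at positions -7..-3, keeps matches whose implied +1 lies within
a bounded distance upstream of an annotated gene start (and whose core is
not inside a coding sequence), extracts fixed windows around each match,
builds a per-column majority consensus, and enumerates substitution
variants that occur naturally among the hits.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .genome import GeneFeature, SequenceRecord, reverse_complement

BAC_CORE_FULL = "CACTATAG"  # positions -7..+1
BAC_CORE_SHORT = "CACTA"  # positions -7..-3
#: offset (in transcription orientation) from the first core base (-7) to +1
PLUS_ONE_OFFSET = 7
DEFAULT_WINDOW_SPAN = (18, 6)  # -18..+6, a 24-nt window
BASE_PRECEDENCE = "ACGT"  # consensus tie-break order


def coord_to_index(coord: int, upstream_len: int) -> int:
    """Map a promoter coordinate (no zero) to a 0-based window index."""
    if coord == 0:
        raise ValueError("promoter coordinates have no position 0")
    return coord + upstream_len if coord < 0 else coord + upstream_len - 1


def index_to_coord(index: int, upstream_len: int) -> int:
    return index - upstream_len if index < upstream_len else index - upstream_len + 1


@dataclass(frozen=True)
class PromoterHit:
    contig_id: str
    plus_one: int  # forward-strand 1-based position of promoter coordinate +1
    strand: str
    window_seq: str  # read in transcription orientation; N-padded at contig ends
    downstream_gene_id: str
    distance_to_gene: int
    window_span: tuple[int, int] = DEFAULT_WINDOW_SPAN


@dataclass(frozen=True)
class PromoterConsensus:
    counts: tuple[dict, ...]  # per-column base counts
    consensus_seq: str
    n_hits: int
    ambiguous_columns: tuple[int, ...]
    window_span: tuple[int, int] = DEFAULT_WINDOW_SPAN


@dataclass(frozen=True)
class SubstitutionSpec:
    position: int  # promoter coordinate, no zero
    base: str

    def __post_init__(self) -> None:
        if self.position == 0:
            raise ValueError("substitution position 0 does not exist")
        if self.base not in "ACGT":
            raise ValueError(f"substitution base must be A/C/G/T, got {self.base!r}")

    def __str__(self) -> str:
        return f"{self.position:+d}:{self.base}"


def extract_upstream(
    contig: SequenceRecord,
    gene: GeneFeature,
    length: int = 100,
    orientation_aware: bool = True,
) -> tuple[str, bool]:
    """The region immediately upstream of a gene, read toward the gene.

    Returns ``(sequence, truncated)``; the flag is set when the contig end
    shortens the region.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    n = len(contig.seq)
    if gene.end > n:
        raise ValueError(f"gene {gene.id!r} extends past contig end")
    if gene.strand == "+" or not orientation_aware:
        lo = max(1, gene.start - length)
        seq = contig.seq[lo - 1 : gene.start - 1]
        return seq, len(seq) < length
    hi = min(n, gene.end + length)
    seq = reverse_complement(contig.seq[gene.end : hi])
    return seq, len(seq) < length


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def scan_core_motif(
    contig: SequenceRecord,
    genes: Sequence[GeneFeature],
    core: str = BAC_CORE_SHORT,
    max_upstream: int = 150,
    window_span: tuple[int, int] = DEFAULT_WINDOW_SPAN,
    same_strand: bool = True,
) -> list[PromoterHit]:
    """Exact-match scan of both strands for the promoter core.

    A core match (anchored with its first base at coordinate -7) is a hit
    iff the implied +1 lies 0..max_upstream nt upstream of some annotated
    gene start (same strand unless ``same_strand=False``) and the core does
    not overlap any annotated coding feature. Windows are extracted in
    transcription orientation and N-padded where the contig ends.
    """
    if not core:
        raise ValueError("core motif must be non-empty")
    up, down = window_span
    n = len(contig.seq)
    hits = []
    for strand in "+-":
        s = contig.seq if strand == "+" else reverse_complement(contig.seq)
        for j in _find_all(s, core):
            p1_t = j + 1 + PLUS_ONE_OFFSET  # +1 in transcription coords (1-based)
            if p1_t > n:
                continue
            if strand == "+":
                plus_one = p1_t
                core_lo, core_hi = j + 1, j + len(core)
            else:
                plus_one = n - p1_t + 1
                core_lo, core_hi = n - (j + len(core)) + 1, n - j
            if any(g.overlaps(core_lo, core_hi) for g in genes):
                continue
            best: Optional[tuple[GeneFeature, int]] = None
            for g in genes:
                if same_strand and g.strand != strand:
                    continue
                d = g.start - plus_one if g.strand == "+" else plus_one - g.end
                if 0 <= d <= max_upstream and (best is None or d < best[1]):
                    best = (g, d)
            if best is None:
                continue
            lo_t, hi_t = p1_t - up, p1_t + down - 1
            window = "".join(
                s[t - 1] if 1 <= t <= n else "N" for t in range(lo_t, hi_t + 1)
            )
            hits.append(
                PromoterHit(
                    contig_id=contig.id,
                    plus_one=plus_one,
                    strand=strand,
                    window_seq=window,
                    downstream_gene_id=best[0].id,
                    distance_to_gene=best[1],
                    window_span=window_span,
                )
            )
    hits.sort(key=lambda h: (h.plus_one, h.strand))
    return hits


def build_consensus(hits: Sequence[PromoterHit]) -> PromoterConsensus:
    """Per-column majority consensus over pre-anchored hit windows.

    Ties are recorded in ``ambiguous_columns`` and broken by the fixed base
    precedence A > C > G > T (with a warning).
    """
    if not hits:
        raise ValueError("cannot build a consensus from zero hits")
    spans = {h.window_span for h in hits}
    if len(spans) != 1:
        raise ValueError(f"mixed window spans: {sorted(spans)}")
    width = len(hits[0].window_seq)
    counts = []
    consensus = []
    ambiguous = []
    for col in range(width):
        counter = Counter(h.window_seq[col] for h in hits)
        counts.append(dict(counter))
        scored = {b: counter.get(b, 0) for b in BASE_PRECEDENCE}
        top = max(scored.values())
        winners = [b for b in BASE_PRECEDENCE if scored[b] == top]
        if len(winners) > 1:
            ambiguous.append(col)
        consensus.append(winners[0])
    if ambiguous:
        warnings.warn(
            f"consensus ties at columns {ambiguous}, broken by base precedence "
            f"{BASE_PRECEDENCE}",
            stacklevel=2,
        )
    return PromoterConsensus(
        counts=tuple(counts),
        consensus_seq="".join(consensus),
        n_hits=len(hits),
        ambiguous_columns=tuple(ambiguous),
        window_span=hits[0].window_span,
    )


def apply_substitutions(
    window_seq: str,
    subs: Iterable[SubstitutionSpec],
    upstream_len: int = DEFAULT_WINDOW_SPAN[0],
) -> str:
    """Replace bases at promoter coordinates; other positions unchanged."""
    seq = list(window_seq)
    for sub in subs:
        idx = coord_to_index(sub.position, upstream_len)
        if not (0 <= idx < len(seq)):
            raise ValueError(f"position {sub.position:+d} outside the window span")
        if seq[idx] == sub.base:
            warnings.warn(
                f"substitution {sub} matches the base already present", stacklevel=2
            )
        seq[idx] = sub.base
    return "".join(seq)


def enumerate_variants(
    consensus: PromoterConsensus,
    hits: Sequence[PromoterHit],
    max_variants: int = 8,
    max_substitutions: int = 3,
) -> list[tuple[str, tuple[SubstitutionSpec, ...], int]]:
    """Consensus variants built from naturally occurring substitutions.

    Candidate substitutions are bases observed in >=1 hit that differ from
    the consensus at that column; variants carry 1..max_substitutions of
    them at distinct columns, ranked by total support (hits carrying each
    substitution), with a deterministic coordinate-then-base tie-break.
    """
    up, _ = consensus.window_span
    observed: list[tuple[SubstitutionSpec, int]] = []
    for col, counter in enumerate(consensus.counts):
        coord = index_to_coord(col, up)
        for base in BASE_PRECEDENCE:
            if base == consensus.consensus_seq[col]:
                continue
            support = counter.get(base, 0)
            if support > 0:
                observed.append((SubstitutionSpec(coord, base), support))
    # cap the combination space deterministically on very diverse hit sets
    if len(observed) > 15:
        observed.sort(key=lambda t: (-t[1], coord_to_index(t[0].position, up), t[0].base))
        observed = observed[:15]
    variants = []
    for k in range(1, max_substitutions + 1):
        for combo in itertools.combinations(observed, k):
            cols = {coord_to_index(s.position, up) for s, _ in combo}
            if len(cols) != k:
                continue
            subs = tuple(
                sorted((s for s, _ in combo), key=lambda s: coord_to_index(s.position, up))
            )
            support = sum(n for _, n in combo)
            seq = apply_substitutions(consensus.consensus_seq, subs, up)
            variants.append((seq, subs, support))
    variants.sort(
        key=lambda v: (
            -v[2],
            len(v[1]),
            tuple((coord_to_index(s.position, up), s.base) for s in v[1]),
        )
    )
    return variants[:max_variants]
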