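"""Promoter anatomy: core anchoring, named regions, region-wise comparison.

The T7-class promoter (positions -17..+6) splits into a recognition region
(-17..-5) containing the AT-rich motif (ATM, -17..-13) and the specificity
loop binding motif (SLBM, -12..-5), and an initiation region (-4..+6)
containing the unwinding region (-4..-1) and the transcription start site
(TSS, +1..+6). The shared core CACTATAG spans -7..+1; anchoring a promoter
string on that core fixes its coordinate register, after which regions can
be excised and compared positionwise between promoters.

24-bp promoters anchored this way receive span -18..+6 (one extra 5' base
relative to the 23-bp T7 promoter); under this register the SLBM identity
between the T7 and the mined 1575-3 promoter is 50 %.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from .align import ungapped_window_identity
from .promoters import BAC_CORE_FULL, BAC_CORE_SHORT

# Published promoter sequences (T7 and the two mined polymerases).
T7_PROMOTER = "TAATACGACTCACTATAGGGAGA"
PROMOTER_1575_3 = "TAATTAACCCACACTATAGGGACA"
PROMOTER_2049_6 = "TATTTACTGGACACTATAGGAGGA"

#: named promoter regions as inclusive coordinate intervals (no position 0)
PROMOTER_REGIONS: dict[str, tuple[int, int]] = {
    "recognition": (-17, -5),
    "ATM": (-17, -13),
    "SLBM": (-12, -5),
    "initiation": (-4, 6),
    "unwinding": (-4, -1),
    "TSS": (1, 6),
    "bac_core": (-7, 1),
}
CONSERVED_POSITIONS = (1, -1, -3, -4)


def _coords_in(lo: int, hi: int) -> list[int]:
    return [c for c in range(lo, hi + 1) if c != 0]


@dataclass(frozen=True)
class AnchoredPromoter:
    seq: str
    span: tuple[int, int]  # (min coordinate, max coordinate), no zero
    core_found: bool
    core_span: tuple[int, int]

    @property
    def plus_one_index(self) -> int:
        """0-based index of coordinate +1 in ``seq``."""
        return -self.span[0]

    def index_of(self, coord: int) -> int:
        if coord == 0:
            raise ValueError("promoter coordinates have no position 0")
        m = self.plus_one_index
        return m + coord if coord < 0 else m + coord - 1

    def covers(self, lo: int, hi: int) -> bool:
        return self.span[0] <= lo and hi <= self.span[1]

    def subsequence(self, lo: int, hi: int) -> str:
        if not self.covers(lo, hi):
            raise ValueError(
                f"region {lo}..{hi} not covered by promoter span {self.span}"
            )
        return "".join(self.seq[self.index_of(c)] for c in _coords_in(lo, hi))

    def base_at(self, coord: int) -> str:
        return self.subsequence(coord, coord)


@dataclass(frozen=True)
class PromoterRegionMap:
    regions: dict  # name -> {"interval", "seq" or None, "covered"}
    conserved_bases: dict  # coordinate -> base or None


def anchor_promoter(
    seq: str, core: str = BAC_CORE_FULL, max_mismatch: int = 0
) -> AnchoredPromoter:
    """Fix the coordinate register of a promoter string on the core motif.

    The rightmost full-core match is used and +1 is assigned to its final
    base. ``max_mismatch`` allows relaxed anchoring for non-canonical
    promoters, but mismatches are never allowed within the conserved
    CACTA positions (-7..-3).
    """
    seq = seq.upper()
    if not (8 <= len(seq) <= 60):
        raise ValueError(f"promoter length {len(seq)} outside the supported 8..60")
    matches = []
    for k in range(len(seq) - len(core) + 1):
        window = seq[k : k + len(core)]
        mism = [i for i in range(len(core)) if window[i] != core[i]]
        if any(i < len(BAC_CORE_SHORT) for i in mism):
            continue
        if len(mism) <= max_mismatch:
            matches.append(k)
    if not matches:
        raise ValueError(f"core {core!r} not found in promoter {seq!r}")
    if len(matches) > 1:
        warnings.warn(
            f"{len(matches)} core matches; anchoring on the rightmost", stacklevel=2
        )
    k = matches[-1]
    m = k + len(core) - 1  # index of coordinate +1
    span = (-m, len(seq) - m)
    return AnchoredPromoter(seq=seq, span=span, core_found=True, core_span=(1 - len(core), 1))


def region_identity(a: AnchoredPromoter, b: AnchoredPromoter, region: str) -> float:
    """Positionwise identity of a named region between two promoters."""
    if region not in PROMOTER_REGIONS:
        raise KeyError(f"unknown region {region!r}; known: {sorted(PROMOTER_REGIONS)}")
    lo, hi = PROMOTER_REGIONS[region]
    return ungapped_window_identity(a.subsequence(lo, hi), b.subsequence(lo, hi))


def annotate_regions(p: AnchoredPromoter) -> PromoterRegionMap:
    """Report every named region covered by the promoter's span."""
    regions = {}
    for name, (lo, hi) in PROMOTER_REGIONS.items():
        covered = p.covers(lo, hi)
        regions[name] = {
            "interval": (lo, hi),
            "covered": covered,
            "seq": p.subsequence(lo, hi) if covered else None,
        }
    conserved = {
        c: (p.base_at(c) if p.covers(c, c) else None) for c in CONSERVED_POSITIONS
    }
    return PromoterRegionMap(regions=regions, conserved_bases=conserved)
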