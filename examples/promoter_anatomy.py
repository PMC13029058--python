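"""Compare the published promoters region by region.

Anchors the T7 promoter and the two mined promoters (1575-3, 2049-6) on the
shared core CACTATAG (-7..+1), prints the named regions, and computes
region-wise identities. The specificity loop binding motif (SLBM, -12..-5)
is the main determinant of promoter specificity: 50 % SLBM identity between
T7 and 1575-3 already means substantial divergence.
"""

from phagemine import (
    PROMOTER_1575_3,
    PROMOTER_2049_6,
    PROMOTER_REGIONS,
    T7_PROMOTER,
    anchor_promoter,
    annotate_regions,
    region_identity,
)

t7 = anchor_promoter(T7_PROMOTER)
p1575 = anchor_promoter(PROMOTER_1575_3)
p2049 = anchor_promoter(PROMOTER_2049_6)

print(f"T7      span {t7.span[0]}..{t7.span[1]:+d} ({len(t7.seq)} nt)")
print(f"1575-3  span {p1575.span[0]}..{p1575.span[1]:+d} ({len(p1575.seq)} nt)")
print(f"2049-6  span {p2049.span[0]}..{p2049.span[1]:+d} ({len(p2049.seq)} nt)")

regions = annotate_regions(t7).regions
print("\nT7 promoter regions:")
for name, info in regions.items():
    lo, hi = info["interval"]
    print(f"  {name:12s} {lo:+d}..{hi:+d}  {info['seq']}")

print("\nregion identities vs T7:")
for name in PROMOTER_REGIONS:
    a = region_identity(t7, p1575, name)
    b = region_identity(t7, p2049, name)
    print(f"  {name:12s} 1575-3: {a:5.1f} %   2049-6: {b:5.1f} %")
print(
    "\nbac_core is 100 % by construction (both promoters carry CACTATAG); "
    "the SLBM identities quantify how far the recognition elements diverge."
)
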