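"""Discover promoters on a synthetic contig via the bac-core scan.

Fourteen promoter instances (a fixed 24-mer with 10 % per-position noise
outside the conserved CACTA core) are planted upstream of genes; the scan
must recover exactly those, the consensus must vote the planted 24-mer
back in, and the variant enumeration lists naturally occurring
substitutions ranked by how many hits carry them.
"""

from phagemine import build_consensus, enumerate_variants, scan_core_motif
from phagemine.simulate import DEFAULT_PLANTED_PROMOTER, generate_phage_contig

contig, genes, truth = generate_phage_contig(seed=3)
hits = scan_core_motif(contig, genes, core="CACTA", max_upstream=150)
print(f"core scan: {len(hits)} hits (planted: {len(truth.planted_promoters)})")
for h in hits[:3]:
    print(
        f"  +1 at {h.plus_one} ({h.strand}), {h.distance_to_gene} nt upstream "
        f"of {h.downstream_gene_id}: {h.window_seq}"
    )

consensus = build_consensus(hits)
print(f"consensus (promoter 1): {consensus.consensus_seq}")
print(f"equals the planted 24-mer: {consensus.consensus_seq == DEFAULT_PLANTED_PROMOTER}")

variants = enumerate_variants(consensus, hits, max_variants=7)
print("variants 2-8 (substitutions seen among the hits, by support):")
for i, (seq, subs, support) in enumerate(variants, start=2):
    notation = ",".join(str(s) for s in subs)
    print(f"  promoter {i}: {seq}  [{notation}] carried by {support} hit(s)")
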