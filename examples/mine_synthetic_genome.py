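"""Mine a synthetic phage contig for a single-subunit RNA polymerase.

Generates a contig with a planted ssRNAP gene (55 % target identity to the
synthetic seed protein) plus a capsid gene, runs ORF detection, reference
classification, the mining filters, and block ranking, and prints where the
planted polymerase lands.
"""

from phagemine import (
    MiningConfig,
    apply_mining_filters,
    build_candidates,
    check_catalytic_residues,
    classify_orfs,
    find_orfs,
    longest_orfs,
    rank_into_blocks,
)
from phagemine.simulate import generate_phage_contig, make_seed_capsid, make_seed_rnap

contig, genes, truth = generate_phage_contig(seed=3)
print(f"contig: {len(contig)} nt, {len(genes)} planted genes")

orfs = longest_orfs(find_orfs(contig, min_aa_length=100))
print(f"ORFs >= 100 aa (longest per stop): {len(orfs)}")

seed_rnap, seed_capsid = make_seed_rnap(), make_seed_capsid()
classified = classify_orfs(orfs, [seed_rnap], [seed_capsid])
candidates = build_candidates(classified)
candidates = apply_mining_filters(candidates, known_proteins=[])
candidates = rank_into_blocks(candidates, MiningConfig(n_select_total=5))

for c in candidates:
    print(
        f"candidate {c.id}: {c.aa_length} aa, "
        f"{c.identity_to_reference:.1f} % identity to {c.best_reference}, "
        f"capsid partner={c.has_capsid_partner}, block={c.block}"
    )
    report = check_catalytic_residues(c.protein, seed_rnap.seq)
    print(f"  catalytic residues conserved: {report.n_conserved}/7")

print(
    f"truth: planted polymerase realized identity "
    f"{truth.planted_rnap['realized_identity']:.1f} % "
    "(the block above must contain it)"
)
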