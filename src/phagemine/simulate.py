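"""Synthetic phage genomes and fixtures with planted ground truth.

Everything the discovery pipeline consumes can be simulated here with known
truth: contigs carrying one planted ssRNAP gene at a target identity to a
seed protein and one capsid-like gene; promoter instances (a fixed 24-mer
with per-position substitution noise outside the conserved CACTA core)
placed in valid intergenic positions upstream of genes; candidate-set
fixtures with a controlled number of near-duplicate pairs and clone-failure
flags; and IVT measurement tables with known true values under
multiplicative noise.

The seed reference proteins are synthetic: random amino-acid strings with
the seven catalytic residues planted at the published T7 positions. No real
polymerase or capsid sequence is embedded. All generators are deterministic
under a fixed seed, and contig generation self-checks its own truth (the
core scan must recover exactly the planted instances) before returning.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .align import align, percent_identity
from .genome import GeneFeature, SequenceRecord, reverse_complement
from .mining import CATALYTIC_RESIDUES_T7, CandidateRecord
from .promoters import DEFAULT_WINDOW_SPAN, scan_core_motif

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: the fixed 24-mer planted as the "true" promoter (span -18..+6)
DEFAULT_PLANTED_PROMOTER = "TAATTAACCCACACTATAGGGACA"
#: window indices of the conserved CACTA core (-7..-3); never noised
_CORE_INDICES = frozenset(range(11, 16))
#: motifs excluded from background DNA so no spurious core survives the scan
_FORBIDDEN = ("CACTA", "TAGTG")


@dataclass
class TruthRecord:
    planted_rnap: dict  # {"start","end","strand","realized_identity"}
    planted_capsid: dict  # {"start","end","strand"}
    planted_promoters: list  # [{"plus_one","strand","window_seq"}]
    noise_rate: float
    seed: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    aas = rng.choice(list(AMINO_ACIDS), size=length - 1)
    return "M" + "".join(aas)


def make_seed_rnap(
    length: int = 883,
    seed: int = 0,
    catalytic: Sequence[tuple[int, str]] = CATALYTIC_RESIDUES_T7,
) -> SequenceRecord:
    """A synthetic ssRNAP seed protein: random residues with the seven
    catalytic amino acids planted at the published T7 positions."""
    if length < max(pos for pos, _ in catalytic):
        raise ValueError("seed protein too short for the catalytic positions")
    rng = np.random.default_rng(seed)
    prot = list(_random_protein(rng, length))
    for pos, res in catalytic:
        prot[pos - 1] = res
    return SequenceRecord("seed_rnap_synthetic", "".join(prot), "protein")


def make_seed_capsid(length: int = 420, seed: int = 1) -> SequenceRecord:
    """A synthetic capsid-like seed protein (random)."""
    rng = np.random.default_rng(seed)
    return SequenceRecord("seed_capsid_synthetic", _random_protein(rng, length), "protein")


def _mutate(
    rng: np.random.Generator,
    protein: str,
    n_sub: int,
    protected: frozenset[int],
) -> str:
    positions = [i for i in range(len(protein)) if i not in protected]
    if n_sub > len(positions):
        raise ValueError("identity target unreachable given protected positions")
    chosen = rng.choice(len(positions), size=n_sub, replace=False)
    prot = list(protein)
    for ci in chosen:
        i = positions[int(ci)]
        options = [a for a in AMINO_ACIDS if a != prot[i]]
        prot[i] = options[int(rng.integers(len(options)))]
    return "".join(prot)


def mutate_to_identity(
    protein: str,
    target_identity: float,
    seed: int | np.random.Generator = 0,
    protect_positions: Sequence[int] = (),
) -> tuple[str, float]:
    """Substitute residues (no indels) until the global-alignment identity
    is within +/-2 percentage points of the target.

    ``protect_positions`` are 1-based residue positions left untouched
    (e.g. catalytic residues). Deterministic given the seed.
    """
    if not (0 < target_identity <= 1):
        raise ValueError("target identity must be in (0, 1]")
    if len(protein) < 50:
        raise ValueError("protein too short to mutate reliably (< 50 aa)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    protected = frozenset(p - 1 for p in protect_positions)
    n_sub = int(round(len(protein) * (1 - target_identity)))
    for _ in range(10):
        mutated = _mutate(rng, protein, n_sub, protected)
        aln = align(mutated, protein, mode="global")
        realized = percent_identity(aln)
        if abs(realized - 100 * target_identity) <= 2:
            return mutated, realized
        n_sub += 1 if realized > 100 * target_identity else -1
    raise RuntimeError("failed to reach the identity target")


_BY_RESIDUE: dict[int, dict[str, list[str]]] = {}


def _codon_table(genetic_code: int) -> dict[str, list[str]]:
    if genetic_code not in _BY_RESIDUE:
        table = CodonTable.unambiguous_dna_by_id[genetic_code]
        by_res: dict[str, list[str]] = {}
        for codon, aa in sorted(table.forward_table.items()):
            by_res.setdefault(aa, []).append(codon)
        by_res["*"] = sorted(table.stop_codons)
        _BY_RESIDUE[genetic_code] = by_res
    return _BY_RESIDUE[genetic_code]


def back_translate(
    protein: str, rng: np.random.Generator, genetic_code: int = 11
) -> str:
    """Uniform synonymous codon choice per residue; a stop codon is appended.
    The first residue must be M so the ORF finder sees an ATG start."""
    by_res = _codon_table(genetic_code)
    codons = []
    for aa in protein:
        options = by_res[aa]
        codons.append(options[int(rng.integers(len(options)))])
    codons.append(by_res["*"][int(rng.integers(len(by_res["*"])))])
    return "".join(codons)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    """Background DNA free of the core motif on either strand."""
    for _ in range(200):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        if not any(m in seq for m in _FORBIDDEN):
            return seq
    raise RuntimeError(f"could not sample motif-free background of length {length}")


def _noisy_window(
    rng: np.random.Generator, window: str, noise_rate: float
) -> str:
    out = list(window)
    for i in range(len(out)):
        if i in _CORE_INDICES:
            continue  # the core is the conserved element; noise sits outside it
        if rng.random() < noise_rate:
            options = [b for b in "ACGT" if b != out[i]]
            out[i] = options[int(rng.integers(3))]
    return "".join(out)


@dataclass
class ContigConfig:
    rnap_identity: float = 0.55
    capsid_identity: float = 0.70
    n_promoters: int = 14
    noise_rate: float = 0.1
    promoter_seq: str = DEFAULT_PLANTED_PROMOTER
    n_decoy_cores_in_cds: int = 2  # planted CACTA decoys inside coding sequence
    #: keep the seven catalytic residues intact in the planted polymerase,
    #: mirroring that mined full-length ssRNAPs all carry the catalytic set
    protect_catalytic: bool = True


def generate_phage_contig(
    config: ContigConfig | None = None,
    seed: int = 0,
    seed_rnap: SequenceRecord | None = None,
    seed_capsid: SequenceRecord | None = None,
) -> tuple[SequenceRecord, list[GeneFeature], TruthRecord]:
    """A synthetic phage contig with planted genes and promoters.

    Layout: an ssRNAP gene on the minus strand, then ``n_promoters``
    [spacer, promoter window, gap, gene] cassettes on the plus strand; the
    first cassette gene is the capsid, the rest are anonymous CDS. Decoy
    core motifs are planted inside the capsid coding sequence (they must be
    rejected by the scan's CDS constraint). Background DNA is
    rejection-sampled so no spurious core instance satisfies the scan
    constraints, and the emitted truth is self-checked against
    :func:`phagemine.promoters.scan_core_motif` before returning.
    """
    config = config or ContigConfig()
    seed_rnap = seed_rnap or make_seed_rnap()
    seed_capsid = seed_capsid or make_seed_capsid()
    up, down = DEFAULT_WINDOW_SPAN
    for attempt in range(25):
        rng = np.random.default_rng([int(seed), attempt])
        protect = (
            [pos for pos, _ in CATALYTIC_RESIDUES_T7] if config.protect_catalytic else []
        )
        rnap_prot, realized = mutate_to_identity(
            seed_rnap.seq, config.rnap_identity, rng, protect_positions=protect
        )
        capsid_prot, _ = mutate_to_identity(seed_capsid.seq, config.capsid_identity, rng)
        parts: list[str] = []
        pos = 1  # 1-based position of the next emitted base
        genes: list[GeneFeature] = []
        promoters: list[dict] = []

        def emit(s: str) -> int:
            nonlocal pos
            start = pos
            parts.append(s)
            pos += len(s)
            return start

        emit(_random_dna(rng, 60))
        rnap_cds = back_translate(rnap_prot, rng)
        start = emit(reverse_complement(rnap_cds))
        rnap_feat = GeneFeature(
            "synthetic_contig", start, start + len(rnap_cds) - 1, "-", "rnap_like", "gene_rnap"
        )
        genes.append(rnap_feat)
        emit(_random_dna(rng, 250))
        for i in range(config.n_promoters):
            emit(_random_dna(rng, int(rng.integers(40, 120))))
            window = _noisy_window(rng, config.promoter_seq, config.noise_rate)
            w0 = emit(window)
            plus_one = w0 + up  # +1 sits at window index `up`
            emit(_random_dna(rng, int(rng.integers(20, 100))))
            if i == 0:
                cds = back_translate(capsid_prot, rng)
                kind, gid = "capsid_like", "gene_capsid"
                if config.n_decoy_cores_in_cds:
                    # overwrite two codons mid-gene with a decoy core; the
                    # codon-aligned CACTAT (His,Tyr) never creates a stop
                    cds_l = list(cds)
                    for d in range(config.n_decoy_cores_in_cds):
                        at = 90 + 120 * d
                        cds_l[at : at + 6] = "CACTAT"
                    cds = "".join(cds_l)
            else:
                filler = _random_protein(rng, 100)
                cds = back_translate(filler, rng)
                kind, gid = "cds", f"gene_{i:02d}"
            gstart = emit(cds)
            genes.append(
                GeneFeature("synthetic_contig", gstart, gstart + len(cds) - 1, "+", kind, gid)
            )
            promoters.append(
                {"plus_one": plus_one, "strand": "+", "window_seq": window}
            )
        emit(_random_dna(rng, 60))
        contig = SequenceRecord("synthetic_contig", "".join(parts), "dna")
        truth = TruthRecord(
            planted_rnap={
                "start": rnap_feat.start,
                "end": rnap_feat.end,
                "strand": "-",
                "realized_identity": realized,
                "protein": rnap_prot,
            },
            planted_capsid={
                "start": genes[1].start,
                "end": genes[1].end,
                "strand": "+",
            },
            planted_promoters=promoters,
            noise_rate=config.noise_rate,
            seed=int(seed),
        )
        # self-check: the scan must recover exactly the planted instances
        hits = scan_core_motif(contig, genes)
        got = {(h.plus_one, h.strand, h.window_seq) for h in hits}
        want = {(p["plus_one"], p["strand"], p["window_seq"]) for p in promoters}
        if got == want:
            return contig, genes, truth
    raise RuntimeError("infeasible contig geometry: self-check kept failing")


def generate_candidate_fixture(
    n_total: int,
    n_duplicate_pairs: int,
    n_unclonable: int,
    seed: int = 0,
    protein_length_range: tuple[int, int] = (180, 260),
) -> tuple[list[CandidateRecord], dict]:
    """A candidate set with exactly ``n_duplicate_pairs`` disjoint >98 %
    identity pairs and ``n_unclonable`` clone-failure flags.

    Unique candidates are independent random proteins (pairwise identity
    far below 90 %); each duplicate partner is its parent mutated at <2 % of
    positions. Clone-failure flags are placed on deduplication
    representatives (the first group member in input order), matching how a
    laboratory exclusion list refers to the retained unique sequences.
    """
    n_groups = n_total - n_duplicate_pairs
    if 2 * n_duplicate_pairs > n_total:
        raise ValueError("too many duplicate pairs for n_total")
    if n_unclonable > n_groups:
        raise ValueError("more unclonable flags than unique candidates")
    rng = np.random.default_rng(seed)
    lo, hi = protein_length_range
    entries: list[tuple[int, str]] = []  # (group, protein)
    for g in range(n_groups):
        length = int(rng.integers(lo, hi + 1))
        parent = _random_protein(rng, length)
        entries.append((g, parent))
        if g < n_duplicate_pairs:
            n_sub = max(1, math.ceil(0.01 * length))  # < 2% of positions
            entries.append((g, _mutate(rng, parent, n_sub, frozenset())))
    order = rng.permutation(len(entries))
    unclonable_groups = set(
        int(g) for g in rng.choice(n_groups, size=n_unclonable, replace=False)
    )
    candidates = []
    first_seen: set[int] = set()
    truth_groups = []
    for rank, idx in enumerate(order):
        group, prot = entries[int(idx)]
        is_rep = group not in first_seen
        first_seen.add(group)
        candidates.append(
            CandidateRecord(
                id=f"cand_{rank:03d}",
                contig_id=f"contig_{rank:03d}",
                protein=prot,
                aa_length=len(prot),
                identity_to_reference=float(rng.uniform(30, 80)),
                best_reference="seed_rnap_synthetic",
                has_capsid_partner=True,
                unclonable=is_rep and group in unclonable_groups,
            )
        )
        truth_groups.append(group)
    truth = {
        "n_total": n_total,
        "n_duplicate_pairs": n_duplicate_pairs,
        "n_unclonable": n_unclonable,
        "groups": truth_groups,
        "unclonable_ids": [c.id for c in candidates if c.unclonable],
        "seed": int(seed),
    }
    return candidates, truth


def generate_ivt_measurements(
    true_values: pd.DataFrame,
    cv: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy IVT measurement tables around known true values.

    ``true_values`` needs columns enzyme, template, yield_mg_per_ml,
    dsrna_pct (NaN allowed). Noise is mean-preserving multiplicative
    log-normal with coefficient of variation ``cv``; replicate means
    therefore recover the truths. cv=0 reproduces the truths exactly.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1 + cv**2)) if cv > 0 else 0.0
    rows = []
    for _, row in true_values.iterrows():
        for rep in range(1, n_replicates + 1):
            rec = dict(row)
            rec["replicate"] = rep
            for col in ("yield_mg_per_ml", "dsrna_pct"):
                val = row.get(col)
                if val is None or pd.isna(val):
                    continue
                factor = (
                    math.exp(rng.normal(-(sigma**2) / 2, sigma)) if sigma > 0 else 1.0
                )
                rec[col] = float(val) * factor
            rows.append(rec)
    return pd.DataFrame(rows)
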