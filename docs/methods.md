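# Methods

`phagemine` is a desk-scale reimplementation of a genome-mining workflow for
phage single-subunit RNA polymerases (ssRNAPs, the T7/T3/SP6-like family)
and their promoters, together with the analytics used to characterize such
enzymes in vitro (dsRNA by-product content, fold-reductions, normalized
aptamer fluorescence). The original discovery ran against a petabyte-scale
metagenomic store that is not publicly available; this package therefore
pairs the full algorithmic pipeline with a synthetic-genome generator that
plants known ground truth, so every stage can be validated by recovery
rather than by re-running the original search.

## The mining model

The biological premise: a phage genome that encodes its own ssRNAP
transcribes its late genes — capsid proteins foremost — from promoters
recognized by that polymerase. A contig is therefore a credible source of a
new polymerase/promoter pair when it carries **both** an ssRNAP-like gene
and a capsid-like gene, and the promoter is expected within a bounded
window upstream of the capsid gene.

The funnel, in fixed order:

1. **ORF detection.** All complete ORFs (start codon to in-frame stop, six
   frames, both strands) with bacterial start codons ATG/GTG/TTG (code
   table 11). Nested ORFs sharing a stop are all reported; candidate
   building keeps the longest per (contig, strand, stop). Coordinates are
   GFF3-style (1-based, inclusive, forward strand, stop codon included).
2. **Classification.** Each ORF is labelled `rnap_like` / `capsid_like` /
   `other` by best local alignment (BLOSUM62, affine gaps) against the two
   reference sets, requiring ≥30 % identity over ≥50 % of the reference
   length. The identity and best reference are recorded.
3. **Filters**, in precedence order `no_capsid → too_short →
   identity_out_of_window → not_novel`, so every excluded candidate has
   exactly one reason. Full-length polymerases must exceed 600 aa (strict
   inequality: 601+ retained). The identity window is half-open
   [30, 80) %, enriching for homologs that are recognizable but not
   already-characterized enzymes. Novelty = absence of a full-length 100 %
   match in a known-protein collection; since equal-length 100 % global
   identity is exact string equality, this gate is a set lookup.
4. **Deduplication.** Single-linkage grouping at >98 % pairwise identity;
   the first member in input order represents each group. A length-ratio
   prefilter (identity over aligned columns can never exceed
   100·shorter/longer) skips provably sub-threshold pairs; it is a bound,
   not a heuristic. The operation ignores already-excluded records and is
   idempotent.
5. **Clone-failure exclusion.** Laboratory unclonability is not predictable
   from sequence; it enters as an input exclusion list applied after
   deduplication.
6. **Block ranking.** The identity window is split into `n_blocks` (5)
   equal-width half-open blocks — [30,40) … [70,80) at defaults — and the
   selected set is drawn round-robin from block tops (identity descending;
   ties broken by longer protein, then id), so every identity stratum is
   represented.

A conservation report maps the seven catalytic residues of the T7-type
active site (K472, D537, K627, K631, M635, Y639, D812 in T7 numbering)
through a global alignment. The residue set is configuration, not
hard-coded, because published descriptions of position 627 disagree (Lys
vs Arg); the Lys reading is the default.

## Percent identity

One definition serves all filters: 100 × matches / aligned columns (gaps
count against identity), computed on the optimal affine-gap alignment
(BLOSUM62, gap open 11, extend 1 in the BLAST convention where a length-k
gap costs 11 + k). A `shorter_seq` denominator is available but not used
by defaults. The aligner is `Bio.Align.PairwiseAligner`; its first optimal
alignment is deterministic across runs, which is the property downstream
contracts need — we do not impose a bespoke traceback tie-break of our
own. The test suite checks scores against an independently written Gotoh
DP oracle, exhaustively for all sequence pairs up to length 3 over a
4-letter alphabet and on seeded samples up to length 6.

## Promoter coordinates and the core scan

Transcription-centric coordinates with no position 0; +1 is the first
transcribed base, defined as the final G of the full core CACTATAG
(−7..+1). The discovery scan uses the shorter conserved core CACTA at
−7..−3, so +1 sits 7 positions after the core's first base. A core match
is a hit iff the implied +1 lies 0–150 nt upstream of an annotated gene
start on the same strand (a flag relaxes the strand restriction) and the
core itself does not overlap any annotated coding feature — the
"not in a coding sequence" constraint attaches to the matching region, not
the whole window. Windows default to 24 nt spanning −18..+6, because the
experimentally selected promoters are 24-mers while the T7 promoter is a
23-mer (−17..+6); the extra base sits 5′ of the ATM. This register
reproduces the published SLBM identity of 50 % between the T7 and 1575-3
promoters and is adopted for that reason. Two published figures — the
"overall identity 75 %" (T7 vs 1575-3) and "37.5 % SLBM" (T7 vs 2049-6) —
do not recompute under this register (the 2049-6 SLBM evaluates to 50 %);
the alignment behind those two numbers is not described, so they are
documented here and deliberately not used as tests, and the register was
not tuned toward them.

Consensus building is per-column majority over the core-anchored windows
(no realignment needed); ties are recorded and broken by the fixed
precedence A > C > G > T with a warning. Variant enumeration proposes the
consensus with 1–3 substitutions, each observed in at least one hit at
that column, ranked by total support with a coordinate-then-base
tie-break; the candidate substitution list is capped at the 15
best-supported entries to bound the combination space deterministically.

## Named promoter regions

recognition −17..−5 (= ATM −17..−13 ∪ SLBM −12..−5), initiation −4..+6
(= unwinding −4..−1 ∪ TSS +1..+6), bac core −7..+1, conserved positions
{+1, −1, −3, −4}. Region comparison is positionwise (ungapped) identity on
the coordinate-excised windows. Anchoring uses the rightmost full-core
match (rightmost, because the core abuts the transcript start and promoter
strings are conventionally written 5′→3′ into the gene); a relaxed mode
tolerates ≤1 mismatch outside the conserved −7..−3 positions.

## IVT analytics

dsRNA content is a mass fraction: 100 × (dsRNA ng/mL) / (yield mg/mL ×
10⁶ ng/mg) — the conventional way a dsRNA immunoassay concentration is
converted against total RNA. Fold-reduction is reference/test, rounded to
the nearest integer by default because published folds are printed as
integers; a zero test value returns a `below_quantification` sentinel
rather than infinity. Per-enzyme summaries exclude templates whose dsRNA
is not measured (aptamer rows). Normalized fluorescence defaults to the
endpoint ratio at the final common time point (the plate-reader assay runs
240 min) with a trapezoidal AUC mode as the alternative; curves on
different grids are linearly interpolated. Published normalized
percentages from the original screen are not recomputable without the raw
curves and are not test targets.

## The synthetic-data generator

What it emulates: the discovery conditions. A contig carries one planted
ssRNAP gene (the 883-aa synthetic seed protein mutated by substitutions —
no indels — to a target identity, default 55 %, realized within ±2
points), one capsid-like gene (default 70 % identity to a capsid seed),
and `n_promoters` (default 14, the hit count reported for the worked
discovery example) promoter instances: a fixed 24-mer with independent
per-position substitution noise (default 0.1) applied **outside** the
CACTA core — the core is the conserved element both biologically and by
the scan's definition of plantedness. Decoy cores are planted inside the
capsid coding sequence and must be rejected by the scan. Background DNA is
rejection-sampled to exclude CACTA/TAGTG, and the generator self-checks on
emission: the core scan must recover exactly the planted instances, else
it retries with a derived subseed (deterministically). The seed proteins
are synthetic — random sequences with the seven catalytic residues planted
at the published T7 positions — because no real polymerase sequence is
embedded in the package; the planted polymerase protects those positions
during mutation by default.

The candidate fixture generates independent random proteins (pairwise
identity far below the 90 % safety margin) of 180–260 aa plus
`n_duplicate_pairs` partners mutated at <2 % of positions (identity >98 %),
shuffles deterministically, and places clone-failure flags on group
representatives. Protein length was chosen so the all-pairs deduplication
of a 74-candidate fixture runs in seconds; length plays no role in the
dedup/exclusion counting the fixture exercises. IVT tables add
mean-preserving multiplicative log-normal noise (σ² = ln(1+cv²)), so
replicate means recover the truths and cv = 0 reproduces them exactly.

What it does **not** emulate: real phage genome architecture (gene order,
terminal repeats), codon usage (back-translation picks synonymous codons
uniformly), natural promoter variation beyond independent per-position
substitution, sequencing error, or any assembly artifacts. Passing
recovery tests therefore demonstrates the correctness of the pipeline's
logic under the stated generative model, not its sensitivity/specificity
on real metagenomes.

## Numerical and degenerate-input choices

- Codons containing N translate to X; ORFs are not split on N.
- A local alignment whose best score is 0 aligns nothing and reports an
  empty alignment with score 0.
- Empty contig sets run to completion with zero counts and a warning.
- Scan hits with multiple eligible downstream genes attach to the nearest.
- All randomness flows through `numpy.random.default_rng` seeded
  explicitly; every generator is byte-deterministic under a fixed seed,
  and pipeline outputs contain no timestamps so reruns are byte-identical.

## Problem sizes

Defaults are sized for interactive use: contigs ≈ 10 kb with 15 genes,
candidate fixtures of 74 proteins (≈ 2 700 potential pairs, mostly skipped
by the length-ratio bound), reference proteins ≤ 883 aa. The full test
suite runs in a few seconds on one CPU.

## Known limitations

- The internal ORF finder is an acknowledged stand-in for a full gene
  annotator: no coding-potential model, no RBS scoring, no tRNA/rRNA.
- No e-value statistics: the original search's significance gate is
  replaced by identity/coverage floors, which is faithful to the filters
  that actually decide the funnel but not a BLAST replica.
- The 30–80 % ranking can use identity to the best of several references
  (default) or a single designated reference; the original procedure's
  choice is ambiguous between these readings.
- Deduplication accepts either protein or nucleotide candidates; the level
  at which the original >98 % screen operated is unstated.
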