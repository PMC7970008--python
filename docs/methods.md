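# Methods

`hypomre` models and analyses MRE-seq (methylation-sensitive restriction
enzyme sequencing) of clonally propagated plant accessions. This note
documents the model, the parameters that matter, the numerical choices, and
what the synthetic data does and does not demonstrate.

## The measurement model

HpaII recognizes CCGG and cleaves between the two cytosines (C^CGG) only
when the internal CG is unmethylated on both strands; full methylation
blocks cleavage and hemimethylation reduces it to slow single-strand
nicking, which we treat as no cleavage at all. Sequencing the released,
size-selected fragments therefore enriches the *hypomethylome* — the
low-methylation, typically gene-associated portion of the genome — and the
absence of read coverage at a locus in one accession becomes a proxy for
methylation at its flanking CCGG sites. All downstream analyses build on
this coverage-as-methylation logic.

## Synthetic study design (`simulate`)

The generator emulates a small clonal crop collection:

| parameter | default | meaning |
|---|---|---|
| `genome_length` | 500 kb | one linear chromosome |
| `n_accessions` | 5 | clonal lineages; the last one "divergent" |
| `gene_fraction` / `repeat_fraction` | 0.35 / 0.45 | bp shares of 1–3 kb feature blocks (rest intergenic) |
| `ccgg_boost` | 2.0 | CCGG motif density in genes relative to the 1/256 random background |
| `p_meth_gene` / `p_meth_repeat` / `p_meth_intergenic` | 0.15 / 0.90 / 0.50 | probability a CCGG site's baseline state is methylated |
| `p_accession_flip` | 0.05 | per-accession flip of a site's baseline state (the source of DMRs) |
| `p_hemi` | 0.05 | per-accession hemimethylation (never cut) |
| `snp_rate` / `indel_rate` | 5e-5 / 5e-6 per bp | clonal variants; SNPs take precedence at collisions |
| `divergent_snp_multiplier` | 5.0 | extra divergence of the designated accession |
| `read_length` | 300 bp | paired-end reads, R1 from the 5' end, R2 reverse-complement of the 3' end |
| `frag_min`–`frag_max` | 100–600 bp | size-selection window |
| `error_rate` | 0.002 | per-base substitution probability |
| `n_pairs` | 50 000 | pairs per accession, allocated uniformly over fragments |
| `contaminant_fractions` | ≤0.8 % per class | phiX, rRNA, chloroplast, mitochondrion, repeats |

Rationale for the values that are calibration choices rather than stated
study facts: the 100–600 bp size window makes merged fragments and contigs
land near ~320 bp mean contig length; `ccgg_boost = 2` yields a mean
inter-site spacing of ~130 bp in genes, so roughly half of gene-space
fragments survive size selection while the mostly methylated repeat space is
released only as over-long (discarded) fragments — reproducing the
gene-enrichment property of the assay. Base qualities follow a plateau at
Q38 with a linear decay to ~Q31 over the final third of the read plus ±3
jitter, so 3'-trimming is exercised without destroying reads. Sequencing
error is drawn independently of the quality string (no miscalibration
model).

Methylation is a per-CCGG-site 3-state label (unmethylated / hemimethylated
/ methylated), not per-cytosine-context: only the site state affects
observability by the enzyme. Digestion cuts at `site + 1` on the accession's
personalized (variant-applied) sequence; a variant that disrupts the motif
removes the cut, and coordinates are tracked on both the personalized and
the reference frame so truth tables stay comparable across accessions.
Variants that *create* a new CCGG are not cut — a new site carries no
methylation state — which slightly under-counts cut sites at the configured
variant rates (≤ a few sites per genome).

Determinism: every draw flows from the single config seed through fixed-tag
numpy child streams (reference genome = 0, accession profiles = 1, reads of
accession *i* = (2, *i*), contaminant references = 3). Identical configs
reproduce byte-identical outputs.

Truth tables emitted alongside the reads: per-accession variants, retained
digest fragments (with reference coordinates and sequences), a BED of
intervals sequenced in a strict subset of accessions (the DMR ground truth,
with both the exact-retainer and the overlap-covered accession subsets), and
contaminant read labels. Downstream tests consume only these files.

## Read QC (`qc`)

Each mate is trimmed of leading/trailing N runs and of 3' bases below Q30,
iterated to a fixed point so filtering is idempotent; mates shorter than
50 bp or with >10 % N are rejected and the whole pair is dropped with them
(no singleton rescue). Adapter trimming is a no-op by default because the
emulated library has adapter-free inserts; a fixed-sequence trim hook exists
for real data.

Contamination screening is alignment-free: each labelled reference becomes a
set of canonical (strand-collapsed) 31-mers, and a read is assigned to the
class containing the largest fraction of its 31-mers when that fraction
reaches 0.5, with ties resolved in the fixed order phiX → repeats → rRNA →
chloroplast → mitochondrion (the control spike can never be attributed to an
organelle). Implementation detail that does not change the contract: a
prefilter tests every 4th k-mer against the class union and full-resolution
fractions are computed only for reads with at least one hit; a read at the
0.5 decision boundary has ≥ 35 sampled contaminant k-mers, so the prefilter
cannot miss a classifiable read.

## Pair merging (`merge`)

Mate 2 is reverse-complemented and every innie overlap length L from 10 up
to min(len1, len2) is scored by mismatch density, with the denominator
capped at 250 (overlaps longer than the cap remain candidates; the cap only
stops the density from being diluted by very long overlaps). The minimal
density wins if ≤ 0.25, ties to the larger overlap; consensus bases come
from the higher-quality mate, consensus quality is the per-column maximum.
Consequences: every error-free pair whose fragment is ≤ 2·read_len − 10
merges exactly to its fragment, and since simulated fragments are capped at
600 bp the merge rate on synthetic data is ≈100 % — higher than on real
libraries, whose fragment distributions extend past the mergeable range.
Unmerged pairs are excluded from assembly.

## Assembly, mapping, pileup (`assembly`)

The assembler is a canonical-k-mer de Bruijn unitig assembler (k = 31, odd
so no k-mer is its own reverse complement): k-mers below a count threshold
are dropped, unitigs are maximal non-branching paths, contigs < 100 bp are
discarded, orientation is normalized to the lexicographically smaller
strand, and contigs are emitted in sorted-sequence order — fully
deterministic. The solid-k-mer threshold defaults to `"auto"` in the
pipeline: the first valley of the k-mer count histogram, because at the
default pooled coverage (hundreds of reads per fragment) recurrent
sequencing errors exceed any small fixed cutoff. The `assemble()` function
default remains 2, appropriate for ≤ ~30× data.

Reads map back gaplessly: exact seed 31-mers (stride 37) vote for
placements, the top candidates are verified by Hamming comparison, and the
best placement by matches (ties: lowest contig id, leftmost start, + strand)
is reported when identity ≥ 0.9. Placements may be end-clipped: the aligned
span is the intersection of the read with the contig and must contain a full
seed. Contigs supported by < 5 distinct mapped reads are removed; the
reference hypomethylome is the pooled assembly of all accessions with pooled
retention, and each accession's reads are re-mapped to it for pileups.
Pileups count {A, C, G, T, gap} per position; this gapless mapper never
emits gap evidence itself (the category serves the score contract below).

**Known structural limitation.** Without bubble popping (deliberately out of
scope), a biallelic site shared by ≥ 2 accessions splits the pooled graph
into two ~2k−1 bp arms that both fall under the 100 bp contig filter, so the
site leaves the reference coordinate system entirely and the end-to-end run
calls few or no threshold-passing variants on simulated data. The
variant-score machinery is therefore validated against controlled references
(contigs constructed from truth fragments), where the caller sees exactly
the mixed pileup columns the published workflow obtains from a
bubble-collapsing assembler plus a mismatch-tolerant mapper. Planted 1-bp
indels behave as designed: gapless mapping absorbs or rejects them, and
indel calling is best-effort through the gap category only.

## DMR calling (`dmr`)

"Covered" means depth ≥ 1 read by default — the literal reading of
presence/absence — exposed as `min_cov` because real data argue for ≥ 2.
Two strategies: (1) pairwise, the covered intervals of accession A minus the
covered intervals of accession B (interval subtraction per contig, each
surviving piece length-filtered at 50 bp individually); (2) unique,
positions covered in exactly one accession, merged to maximal intervals and
length-filtered. By construction pairwise regions never overlap the second
accession's coverage, and every region lies inside its owner's coverage. No
statistical test is attached: the design has no replicates, so the output is
descriptive, as in the underlying workflow.

## Difference-score variant calling (`variants`)

Per position the base counts of an accession form a vector over
{A, C, G, T, gap}; normalization divides by coverage and scales to
percentages (the ×100 scale is forced by the stated 0–200 score range); the
difference score of two accessions is the L1 distance of their normalized
vectors, symmetric and bounded by 200 (disjoint compositions). Calls require
coverage ≥ 10 in both accessions and score strictly > 180. The scalar path
computes integer-count scores by cross-multiplication so the bounds are
attained exactly; the vectorized path rounds at 1e-9 so representation dust
cannot tip the strict threshold at boundary compositions. The gap category
is included by default (`--bases ACGTgap`); with `ACGT` the gap-supporting
reads leave the coverage denominator too. An `--all-scores` mode returns
every coverage-passing position for the unthresholded analysis.

## GO polymorphism summaries (`go`)

A position is attributed to every accession participating in ≥ 1 passing
pair at that position — an interpretive rule, since per-accession counts are
not otherwise derivable from pairwise comparisons. Counts are reported both
as (position, GO) incidences and as distinct positions, because a contig may
carry several terms. The unthresholded companion analysis keeps every
observed difference (score > 0). The top-50 terms by total count (ties by GO
id) form a GO × accession matrix clustered on both axes (average linkage,
Euclidean distance — conventional defaults, exposed as flags). Annotation
comes from a contig → GO TSV; on simulated data the pipeline derives one by
locating contigs on the simulated genome with its own mapper and inheriting
the overlapping genes' terms. No ontology-graph propagation or enrichment
testing is performed.

## Population structure (`popstruct`)

Accessions are pooled samples of a polyploid clone, so matrix entries are
major-allele frequencies (0–100), not diploid genotypes: per variant column
the global major category is the argmax of counts summed over accessions
(ties A < C < G < T < gap), and columns failing the 10-read gate in any
accession are dropped — complete-case filtering, since imputation with five
samples is indefensible. PCA centers columns and eigendecomposes the
accession covariance via SVD; with n accessions at most n − 1 eigenvalues
are nonzero, eigenvalues ≤ 1e-12 are reported as zero, and explained
variance percentages sum to 100 over the nonzero components. The degenerate
all-identical-rows case is defined: zero eigenvalues, projections at the
origin.

## Pipeline and reproducibility (`pipeline`, `cli`)

Stages (simulate → qc → merge → assemble → reference → pileup → dmr →
variants → go → pca) communicate only through serialized artifacts in the
run directory; `manifest.json` lists every artifact with a sha256 checksum,
and a rerun with the same config and seed reproduces the checksums.
Execution is single-threaded; `--threads` is accepted but never changes any
output. Unknown config keys are rejected; the effective config is echoed
into the run directory.

## What the synthetic data does not show

The generator omits PCR amplification bias, adapter read-through,
quality-miscalibration, indel sequencing errors, polyploid allele dosage and
any real genome's repeat structure, and its contaminant references are
random stand-ins rather than the real phiX/organelle sequences. Passing
recovery tests therefore demonstrates the correctness of the algorithms
under the stated model, not performance on real libraries; in particular the
near-total merge rate and the near-perfect contaminant precision/recall are
properties of the clean simulation. Problem sizes used by the test suite
(genomes of 40–500 kb, 0.8k–50k pairs per accession) were chosen so the full
default study — 500 kb, five accessions, 50 000 pairs each — runs end to end
in a few minutes on one CPU.
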