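# Methods

This note documents the models and algorithms implemented in `pankit`,
the assumptions behind them, the defaults that matter, and what the
synthetic benchmarks do and do not establish.

## Data model

A dataset is a set of proteomes, one per genome, each gene carrying an
amino-acid sequence and optionally its coding nucleotide sequence. Genome
identity comes from the proteome filename stem. Sequences are uppercased
on read; a trailing `*` (stop) is kept in the stored record but stripped
for all scoring. A gene whose nucleotide length disagrees with
3 × (amino-acid length) by more than one codon is excluded from
back-translation steps with a warning — partial genes at contig edges are
common in draft assemblies. A pangenome is a plain three-column TSV
(gene, genome, orthogroup) with every gene assigned exactly once.

## Built-in sequence engine

The toolkit is usable with no external binaries; all comparisons run
through a deterministic built-in engine. A MAFFT adapter provides the
same `Msa` contract when the binary is available and better alignment
quality is wanted; engine choice changes scores, never types or
downstream logic.

- **k-mer identity estimate.** Shared distinct 5-mers as a fraction of
  the shorter sequence's distinct 5-mers. Cheap and monotone with true
  identity in the 50–100% range that matters here.
- **Preclustering.** Greedy incremental clustering: genes sorted by
  decreasing length; each joins the oldest precluster whose
  representative (founder, i.e. longest member) reaches the identity
  threshold, else founds its own. An inverted 5-mer index limits
  candidate lookups, keeping the scan near-linear. The default threshold
  (0.30 shared-5-mer fraction) deliberately over-fragments distant
  family members; the profile stage re-merges them.
- **Multiple alignment.** Progressive: sequences join in order of
  decreasing k-mer identity to the longest sequence and are merged by
  global pairwise alignment (BLOSUM62, gap open 11 / extend 1) against
  the current column-representative string. When the incoming sequence
  already has the alignment's width and ≥ 80% identity to the column
  representatives, the gapless merge is provably optimal at these
  penalties and is taken directly — the common case for prokaryotic
  ortholog families, and the main reason the engine stays fast.
  Alignment quality targets profile construction, not aligner fidelity;
  ungapping any row always reproduces its input.
- **Profiles.** Per-column residue frequencies with pseudocount
  α = 0.1 over a 20-letter alphabet: (count + α)/(n + 20α). Columns
  gapped in ≥ 50% of rows are dropped; the consensus is the per-column
  majority residue. Match scores are log2(frequency / (1/20)) — bits
  against a uniform background.
- **Profile–sequence scoring.** Smith–Waterman-style local alignment
  with affine gaps (open 4 bits, extend 0.5 bits), vectorized across the
  sequence axis; identity is counted over the aligned span. Verified
  against an independent brute-force dynamic-programming oracle on small
  inputs. Profile–profile score is the symmetrized mean of each
  consensus scored against the other profile.

## Pangenome inference

Superclusters: precluster profiles are compared all-versus-all behind a
consensus 5-mer prefilter (≥ 3 shared 5-mers); an edge is kept when the
symmetrized score reaches 0.2 × the self-score of the smaller profile,
and superclusters are the connected components. The 0.2 fraction is
scale-free: same-family preclusters at genus-level divergence score
0.3–0.7 of self, unrelated families essentially zero.

Splitting: each supercluster is split recursively. All members are
representatives below the alignment cap (M = 512), else N = 32 are
picked farthest-first on k-mer distance. Distances between aligned
representatives are 1 − fraction-identical over columns where neither
row is gapped (pairs with no overlap get distance 1). Average-linkage
clustering is cut at the root; non-representatives join their closest
representative by k-mer identity.

A proposed split A/B of a cluster with n genes is accepted iff the
number of genomes containing members of both subclusters is at least its
expectation under a uniformly random fixed-size bipartition
(hypergeometric; see README for the closed form). Two boundary rules:
observed = expected = 0 (all genomes hold one gene) is **rejected**, so
single-copy families always terminate as one orthogroup; and a
two-gene cluster within one genome has expected 0 but observed 1, so
within-genome pairs split. The expectation was validated against exact
enumeration and permutation Monte Carlo.

## Core inference

Four steps: (1) pangenome of ≤ 100 random seed genomes; (2) candidate
core = families single-copy in ≥ 90% of seeds (ceil on the count), each
aligned and profiled; (3) profiles searched against all seed sequences;
the per-profile cutoff is the midpoint of the member-score mean and the
mean of the best non-member score per genome; seeds are re-assigned by
cutoff and the final core keeps candidates single-copy in ≥ 95% of
seeds; (4) non-seed genes are assigned to the best-scoring profile whose
cutoff they pass (one family per gene).

Two readings of "mean of member and non-member scores" exist; the
midpoint of the two class means is used because a pooled mean would be
dominated by the far larger non-member class. Restricting non-members to
the best hit per genome targets the actual decision boundary — the
closest paralogs — and decouples the cutoff from search sensitivity. An
optional `max_core` keeps the highest-prevalence families only.

## ANI, tcANI and genome sampling

Per-gene identity is computed by global Levenshtein alignment (edlib),
as 1 − edit distance / alignment length — nucleotide-level when coding
sequences are available, else amino-acid (reported as AAI). The genome
pair's ANI is the mean over families single-copy in both genomes;
`meanXX` sorts the per-gene identities and drops floor((100−XX)/200 · m)
from each tail first. Trimming clips outlier genes (e.g. recent
horizontal transfers) whose identity is far from the genome background;
`mean90` never trims more than 10% in total.

Sampling is farthest-first traversal over 1 − ANI: the first genome is
the one farthest from a seeded random pivot; each next pick maximizes
the minimum distance to the sample, maintained incrementally (≤ k·n
distance evaluations; ties go to the lexicographically smallest id). The
novelty sequence is non-increasing by construction; the first entry is
reported as the sentinel 1.0. Stopping supports a fixed k or a maximum
identity (novelty floor), and a grouped mode samples within species
under a per-species cap and an identity ceiling.

## Profile DB, search, supermatrix

`build` persists per-family alignments, profiles and cutoffs as plain
TSV/FASTA; `search` assigns genes of new genomes to the best passing
profile. `concat` removes all copies of a family from genomes carrying
more than one, aligns members at the amino-acid level, back-translates
each row codon-by-codon (gap → `---`), and concatenates blocks in
sorted family order; genomes missing a family receive an all-gap block.
Blocks are always codon-multiples and rows equal-length.

## Prevalence/completeness model and fixation frequency

Observed presence o_ij ~ Bernoulli(c_i q_j), with q_j the orthogroup
prevalence and c_i the genome completeness. The likelihood is fitted by
alternating blocks of per-coordinate Newton steps (each block vectorized;
a candidate update is kept only where it does not lower that
coordinate's likelihood, making every sweep monotone). The scale
ambiguity (c, q) → (c/s, q·s) is resolved by anchoring max(c) = 1 after
each sweep, which leaves the likelihood unchanged. Empty rows/columns
are pinned at ε = 1e-6 with a warning. Convergence: likelihood gain
below 1e-6 (default), at most 200 sweeps.

Fixation frequency: species with ≥ 10 genomes are retained; per species,
the model is fitted on its presence matrix and a family is species-core
when its fitted prevalence is ≥ 0.95 (the toolkit's core threshold);
families present in ≥ 10 retained species are reported as
(#species core) / (#species present).

## Synthetic data generator

The generator emulates a multi-genome dataset with known orthogroup
truth: a Kingman coalescent tree over the genomes; per family an
ancestral stop-free coding sequence (uniform codon-multiple length,
300–1500 nt); Jukes–Cantor point substitution along branches, with the
tree scaled numerically so the *mean* tip-to-tip identity hits the
target (0.90 for a genus-level dataset). Core families originate at the
root and are never lost; accessory families originate at the root (gain
rate 0) or on a branch drawn proportionally to length, and are lost per
branch with probability 1 − exp(−loss_rate · ℓ/ℓ̄). In-paralog
duplications are ancestral (pre-speciation) with a 10% extra divergence
burst, and the duplicated lineage gets its own truth family, since
post-duplication copies are distinct orthogroups. Stop codons arising
from mutation are rewritten deterministically at output. Same seed,
same bytes.

Deliberately *not* modelled: indels within families (truth stays
alignment-free), recombination, codon-usage bias, assembly or
gene-calling artifacts. Benchmarks on this generator therefore measure
the clustering and splitting machinery under idealized gene calls; on
real data, upstream errors (fragmented assemblies, chimeric genes,
missed calls) will reduce accuracy for any tool, and the reported
F-measures should be read as comparative upper bounds.

## Problem sizes used in the checks

The test suite exercises the full pipeline at 20 genomes × 300 families
(pangenome accuracy), 120 genomes × 100 families (core-vs-pan
consistency), and 200 × 300 presence matrices (model recovery); the
benchmark script runs the pangenome target at 100 genomes × ~3000
families. These sizes keep a complete run in the minutes range on a
single CPU while leaving every code path exercised at realistic family
counts.

## Known limitations

- The built-in aligner trades quality for speed; highly gapped or
  multi-domain families are better served by `--engine mafft`.
- The co-occurrence split test needs paralogs to actually co-occur:
  lineage-specific duplications younger than the deepest speciation in
  the cluster may remain merged (their split is indistinguishable from a
  phylogenetic split under the null).
- ANI values from amino-acid fallback (AAI) are not numerically
  comparable to nucleotide ANI.
- The prevalence/completeness model assumes presence errors are
  independent across families and genomes; contamination (false
  presences) is not modelled.
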