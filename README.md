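# pankit

Scalable comparative genomics for Bacteria and Archaea: pangenome
inference, direct core-genome inference, and representative genome
subsampling, with supporting tools for profile databases, core-gene
supermatrices, and pangenome statistics.

## Who this is for

Microbial genomicists working with collections of genomes that span a
species, a genus, or a whole order. Given one predicted proteome (amino-acid
FASTA) per genome, `pankit` answers three questions:

1. **Which genes belong to the same orthogroup?** (`pan`) — full pangenome
   inference that stays fast on multi-species datasets.
2. **Which gene families are core?** (`core`) — direct core-genome
   inference that skips the full pangenome by working from a random subset
   of seed genomes.
3. **Which genomes are representative?** (`sample`) — linear-time
   subsampling of genomes by core-genome average nucleotide identity
   (cANI), so large, redundantly sampled collections can be reduced before
   heavier analyses.

## Methods at a glance

**Pangenome inference** clusters all genes into *superclusters* (greedy
k-mer preclustering, then profile-vs-profile merging), and then splits
each supercluster recursively. Each iteration aligns up to *M* = 512
sequences (or *N* = 32 farthest-first representatives), cuts an
average-linkage tree at the root into two subclusters, and accepts the
split only if the subclusters co-occur within genomes at least as often
as expected when the bipartition is random. For a genome with *k* of the
cluster's *n* genes and a proposed split of sizes *a* + *b* = *n*, the
null co-occurrence probability is hypergeometric:

    P(genome has both) = 1 - C(n-k, a)/C(n, a) - C(n-k, b)/C(n, b)

so strictly single-copy families are never split, while in-paralog groups
that co-occur within genomes are separated.

**Core inference** infers the pangenome of ≤ 100 random seed genomes,
keeps families single-copy in ≥ 90% of seeds, builds an alignment profile
per family with a score cutoff halfway between member and best-non-member
score means, re-applies the cutoffs (final core = single-copy in ≥ 95% of
seeds), and assigns genes in all remaining genomes by profile search.

**ANI and sampling.** The ANI of two genomes is the mean per-gene
identity over families single-copy in both; `mean90` (tcANI) trims the
extreme 5% of per-gene identities from each tail first, which makes the
measure robust to outlier genes such as recent horizontal transfers.
Representatives are chosen by farthest-first (maximin) traversal with an
incrementally maintained min-distance array — O(k·n) distance
evaluations, and the novelty (distance to the nearest genome already
sampled) of successive picks never increases.

**Statistics.** Presence of orthogroup *j* in genome *i* is modelled as
Bernoulli(c_i · q_j) — completeness times prevalence — fitted by
alternating Newton updates with max(c) anchored at 1. The *fixation
frequency* of an orthogroup is the fraction of species in which it is
species-core (fitted prevalence ≥ 0.95) among the species in which it
occurs at all.

Everything runs end-to-end with a deterministic built-in engine (no
external binaries); a MAFFT adapter (`--engine mafft`) is available when
higher-quality alignments are wanted.

## Worked example

Simulate a small genus-level dataset with known orthogroup truth, infer
its pangenome, and score the result:

```bash
pankit sim demo --genomes 6 --core 10 --accessory 5 --seed 1
pankit pan demo/faa demo/pan --seed 1
pankit stats prf demo/pan/pangenome.tsv demo/truth.tsv
```

which prints

```
76 genes in 6 genomes -> demo
17 orthogroups -> demo/pan/pangenome.tsv
precision	1.0000
recall	1.0000
F	1.0000
```

The simulator evolved 15 gene families (10 core, 5 accessory) along a
random coalescent tree to ~90% mean nucleotide identity, two of which
picked up an ancestral in-paralog duplication — hence 17 true
orthogroups. `pan` recovered exactly the true families (the co-occurrence
test split the paralog pairs), so every co-clustered gene pair is
correct.
The same dataset feeds the other modules, e.g.:

```bash
pankit core demo/faa demo/core --seeds 6 --seed 1   # core families + profile DB
pankit sample demo/faa demo/truth.tsv demo/samp --n 3 --method mean90 --ffn-dir demo/ffn
pankit concat demo/faa demo/ffn demo/truth.tsv demo/supermatrix.fasta
```

`demo/samp/samples.tsv` lists the sampled genomes with their novelty
(1 − tcANI to the closest genome already sampled), and the supermatrix is
an aligned, back-translated concatenation of the core genes ready for
phylogeny inference.

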