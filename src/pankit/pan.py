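"""Pangenome inference: superclustering plus iterative binary splitting.

All genes are first grouped into preclusters by fast greedy k-mer
clustering; per-precluster alignment profiles are then compared
all-versus-all (with a k-mer prefilter on the consensus sequences) and
preclusters whose symmetrized profile score reaches half the self-score of
the smaller profile are merged into superclusters (connected components).

Each supercluster is then split recursively: representatives are chosen
(all members below the alignment cap, otherwise a farthest-first subset),
aligned, average-linkage clustered on alignment distance, cut at the root
into two subclusters, and re-inflated.  A proposed split is accepted only
if the two subclusters co-occur in the same genomes at least as often as
expected when the bipartition is random (hypergeometric null); otherwise
the cluster becomes one orthogroup.  Genuinely single-copy families
therefore stay whole, while in-paralog groups that co-occur within genomes
get separated.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from math import comb
from typing import Callable, Sequence

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from . import backend
from .backend import Msa, Profile, kmer_identity, kmer_set
from .ficlin import ficlin_select
from .io import GeneRecord, Pangenome, ParamSet, Proteome

logger = logging.getLogger("pankit")

#: a profile-profile edge requires this fraction of the smaller profile's
#: self-score; unrelated families score near zero, same-family preclusters
#: at genus-level divergence around 0.3-0.7
EDGE_FRACTION = 0.2
#: minimum shared consensus 5-mers before two profiles are even scored
MIN_SHARED_KMERS = 3


@dataclass
class Cluster:
    """A set of genes with their genomes; intermediate clustering unit."""

    gene_ids: list[str]
    genome_ids: list[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("empty cluster")
        if len(self.gene_ids) != len(self.genome_ids):
            raise ValueError("gene_ids and genome_ids length mismatch")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class SplitVerdict:
    """Outcome of the co-occurrence test for a proposed binary split."""

    observed_cooccurrence: int
    expected_cooccurrence: float
    accepted: bool


def _all_genes(proteomes: Sequence[Proteome]) -> dict[str, GeneRecord]:
    genes: dict[str, GeneRecord] = {}
    for prot in proteomes:
        for g in prot.genes:
            if g.gene_id in genes:
                raise ValueError(f"duplicate gene id across genomes: {g.gene_id}")
            genes[g.gene_id] = g
    return genes


# ---------------------------------------------------------------------------
# Superclustering


def supercluster(
    proteomes: Sequence[Proteome],
    params: ParamSet | None = None,
    aligner: Callable[..., Msa] = backend.align,
) -> tuple[list[Cluster], dict[int, Msa]]:
    """Cluster all genes into superclusters.

    Returns the superclusters and a cache of alignments for superclusters
    that consist of a single precluster (reused during splitting).
    """
    params = params or ParamSet()
    genes = _all_genes(proteomes)
    records = list(genes.values())
    pre = backend.precluster(records, params.precluster_min_identity)
    logger.info("%d genes -> %d preclusters", len(records), len(pre))

    profiles: list[Profile] = []
    msas: list[Msa] = []
    for ci, members in enumerate(pre):
        recs = [genes[g] for g in members]
        if len(recs) > params.max_align:
            reps = _select_representatives(recs, params.n_reps, params.rng_seed)
            msa = aligner(reps)
        else:
            msa = aligner(recs)
        msas.append(msa)
        profiles.append(backend.build_profile(msa, orthogroup_id=str(ci)))

    # candidate pairs via shared consensus k-mers
    index: dict[str, list[int]] = defaultdict(list)
    kmer_counts = []
    for ci, prof in enumerate(profiles):
        ks = kmer_set(prof.consensus)
        kmer_counts.append(len(ks))
        for km in ks:
            index[km].append(ci)
    pair_counts: dict[tuple[int, int], int] = defaultdict(int)
    for km, members in index.items():
        if len(members) < 2:
            continue
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pair_counts[(members[i], members[j])] += 1

    self_scores = {}
    parent = list(range(len(pre)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for (i, j), shared in sorted(pair_counts.items()):
        if shared < MIN_SHARED_KMERS:
            continue
        if find(i) == find(j):
            continue
        for ci in (i, j):
            if ci not in self_scores:
                self_scores[ci] = profiles[ci].self_score()
        smaller = i if len(profiles[i].consensus) <= len(profiles[j].consensus) else j
        score = backend.score_profile_vs_profile(profiles[i], profiles[j])
        if score >= EDGE_FRACTION * self_scores[smaller]:
            union(i, j)

    groups: dict[int, list[int]] = defaultdict(list)
    for ci in range(len(pre)):
        groups[find(ci)].append(ci)

    clusters: list[Cluster] = []
    msa_cache: dict[int, Msa] = {}
    for root in sorted(groups):
        member_pre = groups[root]
        gene_ids = [g for ci in member_pre for g in pre[ci]]
        clusters.append(
            Cluster(
                gene_ids=gene_ids,
                genome_ids=[genes[g].genome_id for g in gene_ids],
            )
        )
        if len(member_pre) == 1 and len(msas[member_pre[0]]) == len(gene_ids):
            msa_cache[len(clusters) - 1] = msas[member_pre[0]]
    logger.info("%d preclusters -> %d superclusters", len(pre), len(clusters))
    return clusters, msa_cache


def _select_representatives(
    recs: Sequence[GeneRecord], n_reps: int, rng_seed: int
) -> list[GeneRecord]:
    by_id = {g.gene_id: g for g in recs}

    def dist(a: str, b: str) -> float:
        return 1.0 - kmer_identity(by_id[a].aa_stripped, by_id[b].aa_stripped)

    trace = ficlin_select(sorted(by_id), dist, k=n_reps, rng_seed=rng_seed)
    return [by_id[g] for g in trace.item_ids]


# ---------------------------------------------------------------------------
# Binary splitting


def _msa_distance_matrix(msa: Msa) -> np.ndarray:
    """1 - fraction identical over columns where neither row is gapped."""
    arr = msa.to_matrix()
    n = len(msa)
    nongap = arr != b"-"
    dmat = np.zeros((n, n))
    for i in range(n - 1):
        both = nongap[i] & nongap[i + 1 :]
        same = (arr[i] == arr[i + 1 :]) & both
        denom = both.sum(axis=1)
        ident = np.divide(
            same.sum(axis=1),
            denom,
            out=np.zeros(n - i - 1),
            where=denom > 0,
        )
        dmat[i, i + 1 :] = dmat[i + 1 :, i] = 1.0 - ident
    return dmat


def propose_split(
    cluster: Cluster,
    genes: dict[str, GeneRecord],
    params: ParamSet | None = None,
    msa: Msa | None = None,
    aligner: Callable[..., Msa] = backend.align,
) -> tuple[list[str], list[str], Msa]:
    """Propose a binary split of a cluster.

    Representatives (all members, or a farthest-first subset above the
    alignment cap) are aligned; average-linkage clustering on the alignment
    distance is cut at the root; non-representatives join their closest
    representative.  Returns the two gene-id lists and the representative
    alignment (so recursion can subset it).
    """
    params = params or ParamSet()
    if len(cluster) < 2:
        raise ValueError("cannot split a cluster of fewer than 2 genes")
    recs = [genes[g] for g in cluster.gene_ids]
    if len(recs) > params.max_align:
        reps = _select_representatives(recs, params.n_reps, params.rng_seed)
    else:
        reps = recs
    rep_ids = [g.gene_id for g in reps]
    if msa is not None and set(msa.gene_ids) >= set(rep_ids):
        rep_msa = msa.subset(rep_ids) if len(msa) != len(rep_ids) else msa
    else:
        rep_msa = aligner(reps)
    dmat = _msa_distance_matrix(rep_msa)
    if len(rep_ids) == 2:
        groups = np.array([0, 1])
        order = rep_msa.gene_ids
    else:
        Z = linkage(squareform(dmat, checks=False), method="average")
        groups = cut_tree(Z, n_clusters=2).ravel()
        order = rep_msa.gene_ids
    side = {gid: int(g) for gid, g in zip(order, groups)}

    rep_set = set(rep_ids)
    sub: tuple[list[str], list[str]] = ([], [])
    for gid in cluster.gene_ids:
        if gid in rep_set:
            sub[side[gid]].append(gid)
    for rec in recs:
        if rec.gene_id in rep_set:
            continue
        best = max(
            rep_ids,
            key=lambda r: (kmer_identity(rec.aa_stripped, genes[r].aa_stripped), r),
        )
        sub[side[best]].append(rec.gene_id)
    a, b = sub
    if not a or not b:  # degenerate linkage cut; force a 1/rest split
        merged = a + b
        a, b = merged[:1], merged[1:]
    return a, b, rep_msa


def evaluate_split(
    genomes_a: Sequence[str], genomes_b: Sequence[str]
) -> SplitVerdict:
    """Co-occurrence test of a proposed split against a random bipartition.

    ``genomes_a``/``genomes_b`` give the genome of each gene in the two
    subclusters.  Under the null, exactly |A| of the parent's genes are
    assigned to A at random (hypergeometric).  For a genome with k genes in
    the parent, P(no A-gene) = C(n-k, a)/C(n, a) and likewise for B, so
    P(both present) = 1 - P(no A) - P(no B) (both-absent is impossible for
    k >= 1).  Accepted iff observed >= expected, except the boundary
    observed == expected == 0, which is rejected so that strictly
    single-copy families are never split.
    """
    if not genomes_a or not genomes_b:
        raise ValueError("both subclusters must be non-empty")
    a, b = len(genomes_a), len(genomes_b)
    n = a + b
    per_genome: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    for g in genomes_a:
        per_genome[g][0] += 1
    for g in genomes_b:
        per_genome[g][1] += 1

    observed = sum(1 for ca, cb in per_genome.values() if ca > 0 and cb > 0)
    expected = 0.0
    denom_a = comb(n, a)
    denom_b = comb(n, b)
    for ca, cb in per_genome.values():
        k = ca + cb
        p_no_a = comb(n - k, a) / denom_a if n - k >= a else 0.0
        p_no_b = comb(n - k, b) / denom_b if n - k >= b else 0.0
        expected += 1.0 - p_no_a - p_no_b
    accepted = observed >= expected and not (observed == 0 and expected <= 0.0)
    return SplitVerdict(
        observed_cooccurrence=observed,
        expected_cooccurrence=expected,
        accepted=accepted,
    )


def infer_pangenome(
    proteomes: Sequence[Proteome],
    params: ParamSet | None = None,
    aligner: Callable[..., Msa] = backend.align,
) -> Pangenome:
    """Infer the full pangenome of a set of proteomes.

    Superclusters are recursively split depth-first; a rejected split (or a
    singleton) emits the cluster as one orthogroup.  The output partitions
    the input genes; deterministic for a fixed ``params.rng_seed``.
    """
    params = params or ParamSet()
    genes = _all_genes(proteomes)
    clusters, msa_cache = supercluster(proteomes, params, aligner)

    orthogroups: list[list[str]] = []
    for ci, cluster in enumerate(clusters):
        stack: list[tuple[Cluster, Msa | None]] = [(cluster, msa_cache.get(ci))]
        while stack:
            cur, cur_msa = stack.pop()
            if len(cur) == 1:
                orthogroups.append(cur.gene_ids)
                continue
            a, b, rep_msa = propose_split(cur, genes, params, cur_msa, aligner)
            verdict = evaluate_split(
                [genes[g].genome_id for g in a], [genes[g].genome_id for g in b]
            )
            if not verdict.accepted:
                orthogroups.append(cur.gene_ids)
                continue
            for part in (a, b):
                part_cluster = Cluster(
                    gene_ids=part,
                    genome_ids=[genes[g].genome_id for g in part],
                )
                part_msa = None
                if set(rep_msa.gene_ids) >= set(part):
                    part_msa = rep_msa.subset(part)
                stack.append((part_cluster, part_msa))

    orthogroups.sort(key=lambda og: og[0])
    width = max(6, len(str(len(orthogroups))))
    rows: list[tuple[str, str, str]] = []
    for i, og in enumerate(orthogroups):
        og_id = f"F{i:0{width}d}"
        for gid in sorted(og):
            rows.append((gid, genes[gid].genome_id, og_id))
    return Pangenome(rows)
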