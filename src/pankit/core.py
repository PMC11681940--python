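"""Direct core-genome inference without a full pangenome.

The strategy: infer the pangenome of a random subset of seed genomes only,
keep the gene families that are single-copy in at least 90% of seeds as
candidates, turn each candidate into an alignment profile with a
per-profile score cutoff, and then assign genes in all remaining genomes
by profile search.  The cutoff for each profile sits halfway between the
mean score of its member sequences and the mean best score of non-member
sequences (one per genome), i.e. against the closest paralogs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from . import backend
from .backend import Msa, Profile
from .io import Pangenome, ParamSet, Proteome
from .pan import infer_pangenome

logger = logging.getLogger("pankit")


@dataclass
class CoreProfile:
    """A family profile with its calibrated membership score cutoff."""

    profile: Profile
    score_cutoff: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.score_cutoff):
            raise ValueError("score cutoff must be finite")


def select_seed_genomes(
    proteomes: Sequence[Proteome], n: int = 100, rng_seed: int = 0
) -> list[Proteome]:
    """Uniformly sample min(n, all) genomes without replacement, seeded."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = sorted(proteomes, key=lambda p: p.genome_id)
    if n >= len(ordered):
        return ordered
    rng = np.random.default_rng(rng_seed)
    idx = rng.choice(len(ordered), size=n, replace=False)
    return [ordered[i] for i in sorted(idx)]


def candidate_core(pangenome: Pangenome, prev: float = 0.90) -> list[str]:
    """Orthogroups with exactly one copy in at least ``prev`` of the genomes.

    The denominator is the number of distinct genomes in the pangenome;
    a genome with two copies does not count toward the single-copy total.
    """
    if len(pangenome) == 0:
        return []
    cn = pangenome.copy_number()
    n_genomes = cn.shape[0]
    needed = math.ceil(prev * n_genomes)
    single = (cn == 1).sum(axis=0)
    return sorted(single.index[single >= needed])


def calibrate_cutoff(
    profile: Profile,
    member_scores: Sequence[float],
    nonmember_scores: Sequence[float],
) -> CoreProfile:
    """Cutoff halfway between the member and non-member class means.

    ``nonmember_scores`` should already be the best non-member hit per
    genome.  With no non-member hits at all, the cutoff falls back to half
    the member mean.
    """
    if len(member_scores) == 0:
        raise ValueError("at least one member score is required")
    mmean = float(np.mean(member_scores))
    if len(nonmember_scores) == 0:
        return CoreProfile(profile, 0.5 * mmean)
    nmean = float(np.mean(nonmember_scores))
    if nmean >= mmean:
        logger.warning(
            "profile %s: non-member mean %.2f >= member mean %.2f "
            "(degenerate separation)",
            profile.orthogroup_id, nmean, mmean,
        )
    return CoreProfile(profile, (mmean + nmean) / 2.0)


def _assign_by_cutoff(
    hits_by_gene: dict[str, list[backend.SearchHit]],
    cutoffs: dict[str, float],
) -> dict[str, str]:
    """gene -> best-scoring profile whose cutoff it passes."""
    assign: dict[str, str] = {}
    for gene_id, hits in hits_by_gene.items():
        passing = [h for h in hits if h.score >= cutoffs[h.query_id]]
        if passing:
            best = max(passing, key=lambda h: (h.score, h.query_id))
            assign[gene_id] = best.query_id
    return assign


def infer_core(
    proteomes: Sequence[Proteome],
    params: ParamSet | None = None,
    aligner: Callable[..., Msa] = backend.align,
) -> tuple[Pangenome, dict[str, CoreProfile]]:
    """Infer the core genome of a set of proteomes.

    Returns the core pangenome (rows only for genes assigned to a core
    family, one family per gene) and the calibrated profile per family.
    """
    params = params or ParamSet()
    if len(proteomes) < 2:
        raise ValueError("core inference requires at least 2 genomes")
    seeds = select_seed_genomes(proteomes, params.n_seed_genomes, params.rng_seed)
    if len(seeds) < params.n_seed_genomes:
        logger.warning(
            "only %d genomes available for %d requested seeds; using all",
            len(seeds), params.n_seed_genomes,
        )
    seed_ids = {p.genome_id for p in seeds}

    # step 1: pangenome of the seed genomes
    seed_pan = infer_pangenome(seeds, params, aligner)

    # step 2: candidate core families and their profiles
    candidates = candidate_core(seed_pan, params.candidate_core_prev)
    logger.info("%d candidate core families", len(candidates))
    gene_rec = {g.gene_id: g for p in seeds for g in p.genes}
    members: dict[str, list[str]] = {og: [] for og in candidates}
    gene_og = {}
    for gene, _genome, og in seed_pan.rows:
        gene_og[gene] = og
        if og in members:
            members[og].append(gene)
    profiles: list[Profile] = []
    for og in candidates:
        msa = aligner([gene_rec[g] for g in members[og]])
        profiles.append(backend.build_profile(msa, orthogroup_id=og))

    # step 3: search against seed sequences, calibrate cutoffs, re-assign
    seed_genes = [g for p in seeds for g in p.genes]
    hits = backend.search_profiles(profiles, seed_genes)
    by_profile_member: dict[str, list[float]] = {og: [] for og in candidates}
    by_profile_nonmember: dict[str, dict[str, float]] = {og: {} for og in candidates}
    for gene_id, gene_hits in hits.items():
        genome = gene_rec[gene_id].genome_id
        for h in gene_hits:
            if gene_og.get(gene_id) == h.query_id:
                by_profile_member[h.query_id].append(h.score)
            else:
                pool = by_profile_nonmember[h.query_id]
                if h.score > pool.get(genome, -math.inf):
                    pool[genome] = h.score
    core_profiles: dict[str, CoreProfile] = {}
    for og, prof in zip(candidates, profiles):
        member_scores = by_profile_member[og]
        if not member_scores:  # search missed its own members; profile unusable
            logger.warning("profile %s recovered no member scores; dropped", og)
            continue
        core_profiles[og] = calibrate_cutoff(
            prof, member_scores, list(by_profile_nonmember[og].values())
        )

    cutoffs = {og: cp.score_cutoff for og, cp in core_profiles.items()}
    usable = [cp.profile for cp in core_profiles.values()]
    hits_usable = {
        g: [h for h in hs if h.query_id in cutoffs] for g, hs in hits.items()
    }
    seed_assign = _assign_by_cutoff(hits_usable, cutoffs)

    # final core: single-copy (post-reassignment) in >= final_core_prev of seeds
    per_og_genome: dict[str, dict[str, int]] = {og: {} for og in cutoffs}
    for gene_id, og in seed_assign.items():
        genome = gene_rec[gene_id].genome_id
        per_og_genome[og][genome] = per_og_genome[og].get(genome, 0) + 1
    needed = math.ceil(params.final_core_prev * len(seeds))
    final_prev = {
        og: sum(1 for c in genomes.values() if c == 1)
        for og, genomes in per_og_genome.items()
    }
    final = sorted(og for og, sc in final_prev.items() if sc >= needed)
    if params.max_core is not None and len(final) > params.max_core:
        final = sorted(
            sorted(final, key=lambda og: (-final_prev[og], og))[: params.max_core]
        )
    logger.info("%d final core families", len(final))

    final_profiles = {og: core_profiles[og] for og in final}
    final_cutoffs = {og: final_profiles[og].score_cutoff for og in final}

    # step 4: assign non-seed genes by profile search + cutoffs
    rows: list[tuple[str, str, str]] = []
    for gene_id, og in seed_assign.items():
        if og in final_profiles:
            rows.append((gene_id, gene_rec[gene_id].genome_id, og))
    nonseed = [p for p in proteomes if p.genome_id not in seed_ids]
    if nonseed:
        ns_genes = [g for p in nonseed for g in p.genes]
        ns_hits = backend.search_profiles(
            [cp.profile for cp in final_profiles.values()], ns_genes
        )
        ns_assign = _assign_by_cutoff(
            {g: [h for h in hs if h.query_id in final_cutoffs]
             for g, hs in ns_hits.items()},
            final_cutoffs,
        )
        genome_of = {g.gene_id: g.genome_id for g in ns_genes}
        for gene_id, og in ns_assign.items():
            rows.append((gene_id, genome_of[gene_id], og))
    rows.sort()
    return Pangenome(rows), final_profiles
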