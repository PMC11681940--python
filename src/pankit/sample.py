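"""Genome-level ANI from shared single-copy genes, and representative
genome subsampling.

The ANI between two genomes is the mean per-gene identity over all gene
families with exactly one copy in each of the two genomes; with a core
pangenome as input this is the core-genome ANI (cANI).  The ``meanXX``
methods trim the extreme per-gene identities before averaging (``mean90``
keeps the middle 90%), which buffers the measure against outlier genes
such as recent horizontal transfers (tcANI).  Per-gene identity is
computed by global (Levenshtein) alignment of the two member sequences,
at the nucleotide level when nucleotide sequences are available and the
amino-acid level otherwise (in which case the value is an AAI).

Representative genomes are picked by farthest-first traversal over
1 - ANI, either a fixed number or until the next genome's novelty would
exceed a maximum identity to the sample.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import numpy as np

from .ficlin import SampleTrace, ficlin_select
from .io import GeneRecord, Pangenome, Proteome

logger = logging.getLogger("pankit")

#: returned when two genomes share no single-copy family
ANI_UNDEFINED = float("nan")


@dataclass(frozen=True)
class AniSpec:
    """ANI method: 'mean' or 'meanXX' (keep the middle XX% of identities)."""

    method: str = "mean"

    def __post_init__(self) -> None:
        if self.method != "mean" and not re.fullmatch(r"mean\d{2}", self.method):
            raise ValueError(f"unknown ANI method {self.method!r}")

    @property
    def tail_fraction(self) -> float:
        """Fraction trimmed from each tail: (100 - XX) / 200."""
        if self.method == "mean":
            return 0.0
        return (100 - int(self.method[4:])) / 200.0


def pair_identity(a: str, b: str) -> float:
    """Identity of a global pairwise alignment, over alignment columns."""
    if a == b:
        return 1.0
    res = edlib.align(a, b, mode="NW", task="path")
    aln_len = sum(int(n) for n in re.findall(r"(\d+)", res["cigar"]))
    return 1.0 - res["editDistance"] / aln_len


def trimmed_mean(values: Sequence[float], tail_fraction: float) -> float:
    """Mean after dropping floor(tail * m) values from each sorted tail."""
    vals = sorted(values)
    drop = math.floor(tail_fraction * len(vals))
    if drop:
        vals = vals[drop:-drop]
    return float(np.mean(vals))


def single_copy_table(pangenome: Pangenome) -> dict[str, dict[str, str]]:
    """Per genome, the families with exactly one copy: genome -> {og: gene}."""
    counts: dict[str, dict[str, list[str]]] = {}
    for gene, genome, og in pangenome.rows:
        counts.setdefault(genome, {}).setdefault(og, []).append(gene)
    return {
        genome: {og: genes[0] for og, genes in per.items() if len(genes) == 1}
        for genome, per in counts.items()
    }


def _ani_from_tables(
    sc_a: Mapping[str, str],
    sc_b: Mapping[str, str],
    gene_map: Mapping[str, GeneRecord],
    spec: AniSpec,
    restrict: set[str] | None = None,
) -> float:
    shared = sorted(set(sc_a) & set(sc_b))
    if restrict is not None:
        shared = [og for og in shared if og in restrict]
    if not shared:
        return ANI_UNDEFINED
    idents = []
    for og in shared:
        ra, rb = gene_map[sc_a[og]], gene_map[sc_b[og]]
        if ra.nt_seq is not None and rb.nt_seq is not None:
            idents.append(pair_identity(ra.nt_seq, rb.nt_seq))
        else:
            idents.append(pair_identity(ra.aa_stripped, rb.aa_stripped))
    return trimmed_mean(idents, spec.tail_fraction)


def pairwise_ani(
    pangenome: Pangenome,
    proteomes: Sequence[Proteome] | Mapping[str, Proteome],
    genome_a: str,
    genome_b: str,
    spec: AniSpec = AniSpec(),
) -> float:
    """ANI between two genomes from their shared single-copy families.

    Returns NaN (with a warning) when no family is single-copy in both.
    """
    gene_map = _gene_map(proteomes)
    sc = single_copy_table(pangenome)
    ani = _ani_from_tables(
        sc.get(genome_a, {}), sc.get(genome_b, {}), gene_map, spec
    )
    if math.isnan(ani):
        logger.warning(
            "no shared single-copy family between %s and %s; ANI undefined",
            genome_a, genome_b,
        )
    return ani


def _gene_map(
    proteomes: Sequence[Proteome] | Mapping[str, Proteome]
) -> dict[str, GeneRecord]:
    prots = proteomes.values() if isinstance(proteomes, Mapping) else proteomes
    return {g.gene_id: g for p in prots for g in p.genes}


class _AniDistance:
    """Memoized 1 - ANI distance oracle over genomes; NaN counts as far."""

    def __init__(self, pangenome, proteomes, spec, restrict=None):
        self.sc = single_copy_table(pangenome)
        self.gene_map = _gene_map(proteomes)
        self.spec = spec
        self.restrict = restrict
        self.cache: dict[tuple[str, str], float] = {}
        self.calls = 0

    def __call__(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        key = (a, b) if a <= b else (b, a)
        if key not in self.cache:
            self.calls += 1
            ani = _ani_from_tables(
                self.sc.get(a, {}), self.sc.get(b, {}),
                self.gene_map, self.spec, self.restrict,
            )
            self.cache[key] = 1.0 if math.isnan(ani) else 1.0 - ani
        return self.cache[key]


def sample_genomes(
    pangenome: Pangenome,
    proteomes: Sequence[Proteome],
    k: int | None = None,
    max_identity: float | None = None,
    spec: AniSpec = AniSpec(),
    rng_seed: int = 0,
    restrict_orthogroups: Sequence[str] | None = None,
) -> SampleTrace:
    """Representative genome subsample by farthest-first traversal on ANI.

    Stops after ``k`` genomes, or before sampling a genome whose ANI to the
    sample would exceed ``max_identity``.  ``restrict_orthogroups`` limits
    the ANI computation to a family subset (e.g. 100 core genes).
    """
    genome_ids = sorted({p.genome_id for p in proteomes})
    restrict = set(restrict_orthogroups) if restrict_orthogroups else None
    dist = _AniDistance(pangenome, list(proteomes), spec, restrict)
    stop = None if max_identity is None else 1.0 - max_identity
    return ficlin_select(genome_ids, dist, k=k, stop_novelty=stop, rng_seed=rng_seed)


def sample_genomes_grouped(
    pangenome: Pangenome,
    proteomes: Sequence[Proteome],
    species_map: Mapping[str, str],
    per_species_cap: int = 100,
    max_identity: float = 0.9999,
    spec: AniSpec = AniSpec(),
    rng_seed: int = 0,
) -> dict[str, SampleTrace]:
    """Per-species sampling honoring a cap and a maximum-identity ceiling."""
    by_species: dict[str, list[Proteome]] = {}
    for p in proteomes:
        by_species.setdefault(species_map[p.genome_id], []).append(p)
    out = {}
    for species in sorted(by_species):
        group = by_species[species]
        out[species] = sample_genomes(
            pangenome, group,
            k=min(per_species_cap, len(group)),
            max_identity=max_identity, spec=spec, rng_seed=rng_seed,
        )
    return out


def subset_core(
    core_pangenome: Pangenome, n_genes: int = 100, rng_seed: int = 0
) -> list[str]:
    """Uniform random subset of core families, seeded."""
    ogs = core_pangenome.orthogroup_ids
    if n_genes >= len(ogs):
        return ogs
    rng = np.random.default_rng(rng_seed)
    idx = rng.choice(len(ogs), size=n_genes, replace=False)
    return sorted(ogs[i] for i in idx)
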