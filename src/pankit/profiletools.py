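"""Profile database build/search utilities and the core-gene supermatrix.

``build`` persists, for a chosen set of orthogroups, the member alignment,
the alignment profile with consensus, and a calibrated membership score
cutoff.  ``search`` identifies those families in new genomes.  ``concat``
assembles the classic phylogenomics input: per-family amino-acid
alignments back-translated to nucleotides and concatenated horizontally
into one row per genome, with an explicit block map.

On-disk profile DB layout (text only)::

    db_dir/
      msa/<orthogroup>.aln     aligned FASTA
      profiles.tsv             orthogroup, consensus, cutoff
      frequencies.tsv          orthogroup, column, 20 residue frequencies
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from . import backend
from .backend import AA_ORDER, Msa, Profile
from .core import CoreProfile, calibrate_cutoff, _assign_by_cutoff
from .io import (
    GeneRecord,
    Pangenome,
    Proteome,
    _atomic_write,
    write_fasta,
)

logger = logging.getLogger("pankit")


@dataclass
class ProfileDB:
    """Per-orthogroup alignment, profile and score cutoff."""

    entries: dict[str, CoreProfile]
    msas: dict[str, Msa] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def save(self, db_dir: str | os.PathLike) -> None:
        db_dir = Path(db_dir)
        (db_dir / "msa").mkdir(parents=True, exist_ok=True)
        lines = []
        freq_lines = []
        for og in sorted(self.entries):
            cp = self.entries[og]
            lines.append(f"{og}\t{cp.profile.consensus}\t{cp.score_cutoff:.6f}\n")
            for col in range(len(cp.profile.consensus)):
                freqs = "\t".join(f"{v:.6f}" for v in cp.profile.freqs[col])
                freq_lines.append(f"{og}\t{col}\t{freqs}\n")
            if og in self.msas:
                msa = self.msas[og]
                write_fasta(
                    dict(zip(msa.gene_ids, msa.rows)), db_dir / "msa" / f"{og}.aln"
                )
        _atomic_write(db_dir / "profiles.tsv", "".join(lines))
        _atomic_write(db_dir / "frequencies.tsv", "".join(freq_lines))

    @classmethod
    def load(cls, db_dir: str | os.PathLike) -> "ProfileDB":
        db_dir = Path(db_dir)
        freqs: dict[str, list[tuple[int, np.ndarray]]] = {}
        with open(db_dir / "frequencies.tsv", encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                og, col = parts[0], int(parts[1])
                freqs.setdefault(og, []).append(
                    (col, np.array([float(x) for x in parts[2:]]))
                )
        entries: dict[str, CoreProfile] = {}
        with open(db_dir / "profiles.tsv", encoding="utf-8") as fh:
            for line in fh:
                og, consensus, cutoff = line.rstrip("\n").split("\t")
                fmat = np.vstack(
                    [v for _c, v in sorted(freqs[og], key=lambda t: t[0])]
                )
                prof = Profile(
                    orthogroup_id=og, consensus=consensus, freqs=fmat
                )
                entries[og] = CoreProfile(prof, float(cutoff))
        msas: dict[str, Msa] = {}
        msa_dir = db_dir / "msa"
        if msa_dir.is_dir():
            for p in sorted(msa_dir.glob("*.aln")):
                recs = [(r.id, str(r.seq)) for r in SeqIO.parse(str(p), "fasta")]
                msas[p.stem] = Msa([i for i, _ in recs], [s for _, s in recs])
        return cls(entries=entries, msas=msas)


def build(
    pangenome: Pangenome,
    proteomes: Sequence[Proteome],
    orthogroup_ids: Sequence[str],
    aligner: Callable[..., Msa] = backend.align,
) -> ProfileDB:
    """Build a profile DB for the given orthogroups.

    Each family's members are aligned and profiled; the score cutoff is
    calibrated exactly as in core inference (midpoint of member mean and
    best-nonmember-per-genome mean).
    """
    gene_map = {g.gene_id: g for p in proteomes for g in p.genes}
    members: dict[str, list[str]] = {}
    gene_og: dict[str, str] = {}
    for gene, _genome, og in pangenome.rows:
        gene_og[gene] = og
        members.setdefault(og, []).append(gene)
    missing = [og for og in orthogroup_ids if og not in members]
    if missing:
        raise ValueError(f"orthogroups absent from pangenome: {missing}")

    profiles: list[Profile] = []
    msas: dict[str, Msa] = {}
    for og in sorted(set(orthogroup_ids)):
        msa = aligner([gene_map[g] for g in sorted(members[og])])
        msas[og] = msa
        profiles.append(backend.build_profile(msa, orthogroup_id=og))

    all_genes = [g for p in proteomes for g in p.genes]
    hits = backend.search_profiles(profiles, all_genes)
    member_scores: dict[str, list[float]] = {p.orthogroup_id: [] for p in profiles}
    nonmember_best: dict[str, dict[str, float]] = {
        p.orthogroup_id: {} for p in profiles
    }
    for gene_id, gene_hits in hits.items():
        genome = gene_map[gene_id].genome_id
        for h in gene_hits:
            if gene_og.get(gene_id) == h.query_id:
                member_scores[h.query_id].append(h.score)
            else:
                pool = nonmember_best[h.query_id]
                if h.score > pool.get(genome, -math.inf):
                    pool[genome] = h.score
    entries: dict[str, CoreProfile] = {}
    for prof in profiles:
        og = prof.orthogroup_id
        scores = member_scores[og]
        if not scores:
            logger.warning("profile %s recovered no member scores; dropped", og)
            continue
        entries[og] = calibrate_cutoff(
            prof, scores, list(nonmember_best[og].values())
        )
    return ProfileDB(entries=entries, msas=msas)


def search(db: ProfileDB, proteomes: Sequence[Proteome]) -> Pangenome:
    """Identify the DB's families in a set of proteomes.

    Each gene is assigned to the best-scoring profile whose cutoff it
    passes; genes passing no cutoff are absent from the output.
    """
    if not db.entries:
        raise ValueError("empty profile DB")
    cutoffs = {og: cp.score_cutoff for og, cp in db.entries.items()}
    profiles = [cp.profile for _og, cp in sorted(db.entries.items())]
    genes = [g for p in proteomes for g in p.genes]
    genome_of = {g.gene_id: g.genome_id for g in genes}
    hits = backend.search_profiles(profiles, genes)
    assign = _assign_by_cutoff(hits, cutoffs)
    rows = sorted(
        (gene, genome_of[gene], og) for gene, og in assign.items()
    )
    return Pangenome(rows)


# ---------------------------------------------------------------------------
# Supermatrix


@dataclass
class Supermatrix:
    """Concatenated per-family nucleotide alignments, one row per genome."""

    genome_ids: list[str]
    rows: list[str]
    blocks: list[tuple[str, int, int]]  # (orthogroup, start, end), end exclusive

    def __post_init__(self) -> None:
        width = len(self.rows[0]) if self.rows else 0
        for r in self.rows:
            if len(r) != width:
                raise ValueError("ragged supermatrix")
        if self.blocks:
            if self.blocks[-1][2] != width:
                raise ValueError("block map does not cover the matrix")
            for og, start, end in self.blocks:
                if (end - start) % 3:
                    raise ValueError(f"block {og} is not codon-multiple")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def block_of(self, genome_id: str, orthogroup_id: str) -> str:
        i = self.genome_ids.index(genome_id)
        for og, start, end in self.blocks:
            if og == orthogroup_id:
                return self.rows[i][start:end]
        raise KeyError(orthogroup_id)

    def write(self, fasta_path: str | os.PathLike, blocks_path: str | os.PathLike) -> None:
        write_fasta(dict(zip(self.genome_ids, self.rows)), fasta_path)
        _atomic_write(
            blocks_path,
            "".join(f"{og}\t{s}\t{e}\n" for og, s, e in self.blocks),
        )


def _backtranslate(aa_row: str, nt: str) -> str:
    """Expand an aligned amino-acid row to codons; gaps become '---'."""
    out = []
    pos = 0
    for c in aa_row:
        if c == "-":
            out.append("---")
        else:
            out.append(nt[pos : pos + 3])
            pos += 3
    return "".join(out)


def concat(
    core_pangenome: Pangenome,
    proteomes: Sequence[Proteome],
    orthogroup_ids: Sequence[str] | None = None,
    aligner: Callable[..., Msa] = backend.align,
) -> Supermatrix:
    """Build the core-gene nucleotide supermatrix.

    Per family (in sorted family order): all copies are dropped from
    genomes with more than one copy; the remaining members are aligned at
    the amino-acid level; each aligned row is back-translated to its
    nucleotide codons (gap columns become ``---``); genomes missing the
    family get an all-gap block.  Genes whose nucleotide length is
    inconsistent with their amino-acid length are skipped with a warning.
    """
    gene_map = {g.gene_id: g for p in proteomes for g in p.genes}
    genome_ids = sorted({p.genome_id for p in proteomes})
    members: dict[str, dict[str, list[str]]] = {}
    for gene, genome, og in core_pangenome.rows:
        members.setdefault(og, {}).setdefault(genome, []).append(gene)
    ogs = sorted(orthogroup_ids) if orthogroup_ids else sorted(members)

    row_parts: dict[str, list[str]] = {g: [] for g in genome_ids}
    blocks: list[tuple[str, int, int]] = []
    pos = 0
    for og in ogs:
        fam = members.get(og, {})
        keep: dict[str, GeneRecord] = {}
        for genome, genes in fam.items():
            if len(genes) != 1:
                continue  # multi-copy genomes are purged from this family
            rec = gene_map[genes[0]]
            # back-translation needs an exact codon-for-residue nt sequence
            if rec.nt_seq is None or not rec.nt_consistent(tolerance_nt=0):
                logger.warning(
                    "gene %s: nucleotide/protein length mismatch; skipped "
                    "from supermatrix", rec.gene_id,
                )
                continue
            keep[genome] = rec
        if not keep:
            continue
        msa = aligner([keep[g] for g in sorted(keep)])
        width_nt = 3 * msa.width
        aligned = dict(zip(msa.gene_ids, msa.rows))
        for genome in genome_ids:
            if genome in keep:
                rec = keep[genome]
                row_parts[genome].append(
                    _backtranslate(aligned[rec.gene_id], rec.coding_nt())
                )
            else:
                row_parts[genome].append("-" * width_nt)
        blocks.append((og, pos, pos + width_nt))
        pos += width_nt

    return Supermatrix(
        genome_ids=genome_ids,
        rows=["".join(row_parts[g]) for g in genome_ids],
        blocks=blocks,
    )
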