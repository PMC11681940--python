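"""Readers/writers for on-disk formats and the shared in-memory data model.

Proteomes are amino-acid FASTA files, one file per genome, with the genome
identifier taken from the filename stem.  A pangenome is a headerless
three-column TSV (gene, genome, orthogroup) assigning every gene to exactly
one orthogroup.  All outputs are written atomically (temp file + rename).
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("pankit")

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}


@dataclass(frozen=True)
class GeneRecord:
    """A single predicted gene: amino-acid sequence, optional nucleotide CDS."""

    gene_id: str
    genome_id: str
    aa_seq: str
    nt_seq: str | None = None

    @property
    def aa_stripped(self) -> str:
        """Amino-acid sequence without the trailing stop symbol.

        Gene callers emit a trailing ``*``; every downstream scoring step
        works on the stripped sequence while ``aa_seq`` keeps the raw record.
        """
        return self.aa_seq[:-1] if self.aa_seq.endswith("*") else self.aa_seq

    def nt_consistent(self, tolerance_nt: int = 3) -> bool:
        """True if nt length matches 3x the aa length within ``tolerance_nt``.

        The expected nucleotide length is ``3 * len(aa)`` plus an optional
        trailing stop codon; partial genes at contig edges may be one codon
        short or long, which we tolerate.
        """
        if self.nt_seq is None:
            return False
        n_aa = len(self.aa_stripped)
        for expected in (3 * n_aa, 3 * n_aa + 3):
            if abs(len(self.nt_seq) - expected) <= tolerance_nt:
                return True
        return False

    def coding_nt(self) -> str:
        """Nucleotide sequence trimmed of the trailing stop codon, if present."""
        if self.nt_seq is None:
            raise ValueError(f"gene {self.gene_id} has no nucleotide sequence")
        n_aa = len(self.aa_stripped)
        nt = self.nt_seq
        if len(nt) >= 3 * n_aa + 3:
            nt = nt[: 3 * n_aa]
        return nt[: 3 * n_aa]


@dataclass
class Proteome:
    """All predicted genes of one genome."""

    genome_id: str
    genes: list[GeneRecord]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"proteome {self.genome_id!r} has no genes")
        for g in self.genes:
            if g.genome_id != self.genome_id:
                raise ValueError(
                    f"gene {g.gene_id} has genome {g.genome_id!r}, "
                    f"expected {self.genome_id!r}"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.genes)


@dataclass
class Pangenome:
    """Assignment of every gene to exactly one orthogroup.

    Stored as rows of (gene_id, genome_id, orthogroup_id); each gene_id
    appears exactly once.
    """

    rows: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for gene, _genome, _og in self.rows:
            if gene in seen:
                raise ValueError(f"gene {gene!r} assigned more than once")
            seen.add(gene)

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["gene", "genome", "orthogroup"])

    @property
    def gene_to_orthogroup(self) -> dict[str, str]:
        return {gene: og for gene, _genome, og in self.rows}

    @property
    def orthogroup_ids(self) -> list[str]:
        return sorted({og for _g, _gm, og in self.rows})

    def genomes_of(self, orthogroup_id: str) -> set[str]:
        return {gm for _g, gm, og in self.rows if og == orthogroup_id}

    def subset_orthogroups(self, keep: Iterable[str]) -> "Pangenome":
        keep = set(keep)
        return Pangenome([r for r in self.rows if r[2] in keep])

    def presence_matrix(self) -> pd.DataFrame:
        """Genome x orthogroup binary presence (>=1 copy) matrix."""
        df = self.to_frame()
        counts = df.groupby(["genome", "orthogroup"]).size().unstack(fill_value=0)
        return (counts > 0).astype(int)

    def copy_number(self) -> pd.DataFrame:
        """Genome x orthogroup copy-number matrix."""
        df = self.to_frame()
        return df.groupby(["genome", "orthogroup"]).size().unstack(fill_value=0)


@dataclass
class ParamSet:
    """Tunable parameters shared across the inference modules."""

    n_reps: int = 32
    max_align: int = 512
    n_seed_genomes: int = 100
    candidate_core_prev: float = 0.90
    final_core_prev: float = 0.95
    ani_method: str = "mean"
    rng_seed: int = 0
    # built-in engine knobs
    precluster_min_identity: float = 0.30
    max_core: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.candidate_core_prev <= self.final_core_prev <= 1):
            raise ValueError(
                "require 0 < candidate_core_prev <= final_core_prev <= 1"
            )
        if self.n_reps > self.max_align:
            raise ValueError("n_reps must not exceed max_align")


def orthogroup_ids(n: int, width: int = 6) -> list[str]:
    """Opaque orthogroup identifiers: zero-padded integers prefixed 'F'."""
    return [f"F{i:0{width}d}" for i in range(n)]


# ---------------------------------------------------------------------------
# FASTA


def read_faa(path: str | os.PathLike, nt_path: str | os.PathLike | None = None) -> Proteome:
    """Read one genome's proteome from an amino-acid FASTA file.

    The genome id is the filename stem; the FASTA header token before the
    first whitespace is the gene id.  Sequences are uppercased.  If
    ``nt_path`` is given, nucleotide sequences are attached by gene id.

    Raises ``ValueError`` on an empty file or a duplicate gene id.
    """
    path = Path(path)
    genome_id = path.stem
    nt_map: dict[str, str] = {}
    if nt_path is not None:
        for rec in SeqIO.parse(str(nt_path), "fasta"):
            nt_map[rec.id] = str(rec.seq).upper()

    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate gene id {rec.id!r} in {path}")
        seen.add(rec.id)
        genes.append(
            GeneRecord(
                gene_id=rec.id,
                genome_id=genome_id,
                aa_seq=str(rec.seq).upper(),
                nt_seq=nt_map.get(rec.id),
            )
        )
    if not genes:
        raise ValueError(f"empty FASTA file: {path}")
    return Proteome(genome_id=genome_id, genes=genes)


def read_proteome_dir(
    faa_dir: str | os.PathLike, ffn_dir: str | os.PathLike | None = None
) -> list[Proteome]:
    """Read every ``*.faa``/``*.fasta`` in a directory, sorted by genome id.

    If ``ffn_dir`` is given, nucleotide FASTAs with matching stems are
    attached.
    """
    faa_dir = Path(faa_dir)
    paths = sorted(
        p for p in faa_dir.iterdir() if p.suffix in {".faa", ".fasta", ".fa"}
    )
    if not paths:
        raise ValueError(f"no FASTA files found in {faa_dir}")
    proteomes = []
    for p in paths:
        nt_path = None
        if ffn_dir is not None:
            for suffix in (".ffn", ".fasta", ".fa", ".fna"):
                cand = Path(ffn_dir) / (p.stem + suffix)
                if cand.exists():
                    nt_path = cand
                    break
        proteomes.append(read_faa(p, nt_path))
    return proteomes


def write_fasta(records: Mapping[str, str], path: str | os.PathLike) -> None:
    """Write ``{id: sequence}`` as FASTA, atomically."""
    _atomic_write(
        path, "".join(f">{name}\n{seq}\n" for name, seq in records.items())
    )


# ---------------------------------------------------------------------------
# Pangenome TSV


def read_pangenome(path: str | os.PathLike) -> Pangenome:
    """Read a headerless 3-column pangenome TSV (gene, genome, orthogroup)."""
    rows: list[tuple[str, str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected 3 tab-separated columns, "
                    f"got {len(parts)}"
                )
            rows.append((parts[0], parts[1], parts[2]))
    return Pangenome(rows)


def write_pangenome(pangenome: Pangenome, path: str | os.PathLike) -> None:
    """Write a pangenome as headerless TSV, atomically."""
    text = "".join(f"{g}\t{gm}\t{og}\n" for g, gm, og in pangenome.rows)
    _atomic_write(path, text)


def _atomic_write(path: str | os.PathLike, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
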