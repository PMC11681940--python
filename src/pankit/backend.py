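"""Built-in sequence-comparison engine plus adapters to external binaries.

The engine provides everything the inference modules need: fast greedy
k-mer preclustering, progressive multiple alignment, per-family alignment
profiles with consensus sequences, and local profile-to-sequence scoring
with affine gaps.  It is deterministic and pure Python/numpy, so the whole
toolkit runs end-to-end without external binaries; a MAFFT adapter is
provided for users who want higher-quality alignments.

Scores are bits-like: per-column log2 odds of the profile frequency over a
uniform 1/20 background.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .io import GeneRecord

logger = logging.getLogger("pankit")

KMER_SIZE = 5
PSEUDOCOUNT = 0.1
BACKGROUND = 1.0 / 20.0
#: affine gap penalties for the profile DP, in bits
PROFILE_GAP_OPEN = 4.0
PROFILE_GAP_EXT = 0.5

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
_BLOSUM_ALPHABET = set("ARNDCQEGHILKMFPSTWYVBZX*")
GAP = "-"


# ---------------------------------------------------------------------------
# k-mer identity estimation and preclustering


def kmer_set(seq: str, k: int = KMER_SIZE) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def kmer_identity(a: str, b: str, k: int = KMER_SIZE) -> float:
    """Shared distinct k-mers as a fraction of the shorter sequence's k-mers.

    Cheap identity proxy: monotone with true identity for moderately
    diverged protein sequences.
    """
    if len(a) > len(b):
        a, b = b, a
    ka = kmer_set(a, k)
    if not ka:
        return 1.0 if a == b else 0.0
    return len(ka & kmer_set(b, k)) / len(ka)


def precluster(
    genes: Sequence[GeneRecord], min_identity: float, k: int = KMER_SIZE
) -> list[list[str]]:
    """Greedy incremental clustering of genes into preclusters.

    Genes are processed by decreasing length; each joins the oldest existing
    precluster whose representative (its longest member, i.e. its founder)
    shares a k-mer-estimated identity of at least ``min_identity``,
    otherwise it founds a new precluster.  An inverted k-mer index keeps the
    scan near-linear.  Returns a partition of gene ids.
    """
    if not genes:
        raise ValueError("precluster requires at least one gene")
    order = sorted(genes, key=lambda g: (-len(g.aa_stripped), g.gene_id))
    clusters: list[list[str]] = []
    index: dict[str, list[int]] = defaultdict(list)

    for gene in order:
        seq = gene.aa_stripped
        kmers = kmer_set(seq, k)
        best = None
        if kmers:
            counts: dict[int, int] = defaultdict(int)
            for km in kmers:
                for ci in index.get(km, ()):
                    counts[ci] += 1
            # the incoming gene is the shorter sequence (reps are founders,
            # inserted in decreasing length order)
            needed = min_identity * len(kmers)
            eligible = [ci for ci, c in counts.items() if c >= needed]
            if eligible:
                best = min(eligible)  # oldest precluster wins
        if best is None:
            ci = len(clusters)
            clusters.append([gene.gene_id])
            for km in kmers:
                index[km].append(ci)
        else:
            clusters[best].append(gene.gene_id)
    return clusters


# ---------------------------------------------------------------------------
# Multiple sequence alignment


@dataclass
class Msa:
    """An aligned set of amino-acid sequences; rows equal length, gap '-'."""

    gene_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.rows):
            raise ValueError("gene_ids and rows length mismatch")
        if self.rows:
            width = len(self.rows[0])
            for r in self.rows:
                if len(r) != width:
                    raise ValueError("ragged alignment")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.rows)

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def to_matrix(self) -> np.ndarray:
        return np.frombuffer(
            "".join(self.rows).encode("ascii"), dtype="S1"
        ).reshape(len(self.rows), self.width)

    def subset(self, gene_ids: Iterable[str]) -> "Msa":
        """Row-subset with all-gap columns dropped (still a valid alignment)."""
        keep = set(gene_ids)
        idx = [i for i, g in enumerate(self.gene_ids) if g in keep]
        if not idx:
            raise ValueError("subset selects no rows")
        arr = np.frombuffer(
            "".join(self.rows[i] for i in idx).encode("ascii"), dtype="S1"
        ).reshape(len(idx), self.width)
        nongap = (arr != b"-").any(axis=0)
        arr = arr[:, nongap]
        rows = [a.tobytes().decode("ascii") for a in arr]
        return Msa([self.gene_ids[i] for i in idx], rows)


def _pairwise_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def _sanitize(seq: str) -> str:
    return "".join(c if c in _BLOSUM_ALPHABET else "X" for c in seq)


def _column_representatives(mat: np.ndarray) -> str:
    """Most frequent non-gap residue per column of an (n, w) byte matrix."""
    w = mat.shape[1]
    counts = np.zeros((w, len(AA_ORDER)), dtype=np.int64)
    for ai, aa in enumerate(AA_ORDER):
        counts[:, ai] = (mat == aa.encode("ascii")).sum(axis=0)
    idx = np.argmax(counts, axis=1)
    reps = np.array(list(AA_ORDER), dtype="U1")[idx]
    empty = counts.sum(axis=1) == 0
    reps[empty] = "X"
    return "".join(reps)


def align(genes: Sequence[GeneRecord] | Sequence[tuple[str, str]]) -> Msa:
    """Progressive multiple alignment of amino-acid sequences.

    Sequences are added in order of decreasing k-mer identity to the longest
    sequence (a star-topology guide derived from k-mer distances) and merged
    into the growing alignment by globally aligning each against the current
    column-representative string (BLOSUM62, gap open 11, extend 1).  When
    the incoming sequence has the alignment's width and is highly similar
    to the column representatives, the gapless merge is taken directly.
    Quality targets family-level profile construction, not external-aligner
    fidelity; ungapping any row always reproduces the input sequence.
    """
    items: list[tuple[str, str]] = []
    for g in genes:
        if isinstance(g, GeneRecord):
            items.append((g.gene_id, g.aa_stripped))
        else:
            items.append((g[0], g[1].rstrip("*")))
    if not items:
        raise ValueError("align requires at least one sequence")
    if len(items) == 1:
        return Msa([items[0][0]], [items[0][1]])

    center = max(items, key=lambda it: (len(it[1]), it[0]))
    rest = [it for it in items if it is not center]
    rest.sort(key=lambda it: (-kmer_identity(it[1], center[1]), it[0]))

    ids = [center[0]]
    mat = np.frombuffer(center[1].encode("ascii"), dtype="S1").reshape(1, -1).copy()
    reps = _sanitize(center[1])
    aligner = _pairwise_aligner()

    for gid, seq in rest:
        mat, inserted = _merge_into(mat, reps, seq, aligner)
        ids.append(gid)
        if inserted:
            reps = _sanitize(_column_representatives(mat))
    rows = [r.tobytes().decode("ascii") for r in mat]
    order = {gid: i for i, gid in enumerate(ids)}
    perm = [order[gid] for gid, _ in items]
    return Msa([ids[i] for i in perm], [rows[i] for i in perm])


def _merge_into(
    mat: np.ndarray, reps: str, seq: str, aligner: Align.PairwiseAligner
) -> tuple[np.ndarray, bool]:
    """Merge ``seq`` into the alignment as a new row.

    Returns (new matrix, whether gap columns were inserted).
    """
    width = mat.shape[1]
    seq_bytes = np.frombuffer(seq.encode("ascii"), dtype="S1")
    # fast path: equal width and high identity -> the gapless merge is optimal
    if len(seq) == width:
        b = np.frombuffer(reps.encode("ascii"), dtype="S1")
        if (seq_bytes == b).mean() >= 0.8:
            return np.vstack([mat, seq_bytes]), False
    aln = aligner.align(reps, _sanitize(seq))[0]
    rep_aln, seq_aln = str(aln[0]), str(aln[1])
    new_row: list[str] = []
    insert_at: list[tuple[int, int]] = []  # (column index, gap columns to insert)
    col = 0
    pending = 0
    seq_pos = 0
    for rc, sc in zip(rep_aln, seq_aln):
        if sc == GAP:
            new_row.append(GAP)
        else:
            new_row.append(seq[seq_pos])  # original (unsanitized) residue
            seq_pos += 1
        if rc == GAP:
            pending += 1
        else:
            if pending:
                insert_at.append((col, pending))
                pending = 0
            col += 1
    if pending:
        insert_at.append((col, pending))
    if insert_at:
        gap = np.full((mat.shape[0], 1), b"-", dtype="S1")
        pieces = []
        prev = 0
        for at, count in insert_at:
            pieces.append(mat[:, prev:at])
            pieces.append(np.repeat(gap, count, axis=1))
            prev = at
        pieces.append(mat[:, prev:])
        mat = np.hstack(pieces)
    row = np.frombuffer("".join(new_row).encode("ascii"), dtype="S1").reshape(1, -1)
    return np.vstack([mat, row]), bool(insert_at)


def align_mafft(genes: Sequence[GeneRecord] | Sequence[tuple[str, str]]) -> Msa:
    """External-aligner adapter: run MAFFT on the input sequences.

    Requires the ``mafft`` binary on PATH; returns the same ``Msa`` type as
    the built-in aligner.
    """
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft binary not found on PATH")
    items = [
        (g.gene_id, g.aa_stripped) if isinstance(g, GeneRecord) else (g[0], g[1])
        for g in genes
    ]
    if len(items) == 1:
        return Msa([items[0][0]], [items[0][1]])
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.faa"
        infile.write_text("".join(f">{i}\n{s}\n" for i, s in items))
        res = subprocess.run(
            ["mafft", "--quiet", "--auto", str(infile)],
            capture_output=True,
            text=True,
            check=True,
        )
        outfile = Path(tmp) / "out.aln"
        outfile.write_text(res.stdout)
        recs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(outfile), "fasta")}
    return Msa([i for i, _ in items], [recs[i] for i, _ in items])


def get_aligner(engine: str = "builtin"):
    """Select the MSA engine: 'builtin' or 'mafft'."""
    if engine == "builtin":
        return align
    if engine == "mafft":
        return align_mafft
    raise ValueError(f"unknown engine {engine!r}")


def mmseqs_available() -> bool:
    return shutil.which("mmseqs") is not None


# ---------------------------------------------------------------------------
# Profiles


@dataclass
class Profile:
    """Position-specific residue frequencies over consensus (match) columns.

    Alignment columns that are gapped in at least half the rows are dropped;
    the remaining columns carry pseudocounted frequency vectors and a
    consensus residue each.
    """

    orthogroup_id: str
    consensus: str
    freqs: np.ndarray  # (len(consensus), 20), rows sum to 1
    n_rows: int = 1
    _score_matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.freqs.shape != (len(self.consensus), 20):
            raise ValueError("freqs shape must be (len(consensus), 20)")

    @property
    def score_matrix(self) -> np.ndarray:
        """Per-column log2-odds scores vs the uniform background."""
        if self._score_matrix is None:
            self._score_matrix = np.log2(self.freqs / BACKGROUND)
        return self._score_matrix

    def self_score(self) -> float:
        return score_profile_vs_seq(self, self.consensus).score


def build_profile(msa: Msa, orthogroup_id: str = "") -> Profile:
    """Column frequencies with pseudocounts and a consensus sequence.

    Frequency of residue a in a column with n non-gap residues is
    ``(count_a + alpha) / (n + 20 alpha)`` with ``alpha = 0.1``; unknown
    residues (X etc.) contribute uniformly.  Columns gapped in >= 50% of
    rows are dropped from the consensus and the profile.
    """
    if len(msa) == 0:
        raise ValueError("empty alignment")
    arr = np.frombuffer(
        "".join(msa.rows).encode("ascii"), dtype="S1"
    ).reshape(len(msa), msa.width)
    n, width = arr.shape
    counts = np.zeros((width, 20), dtype=np.float64)
    for ai, aa in enumerate(AA_ORDER):
        counts[:, ai] = (arr == aa.encode("ascii")).sum(axis=0)
    nongap = (arr != b"-").sum(axis=0).astype(np.float64)
    unknown = nongap - counts.sum(axis=1)
    counts += unknown[:, None] / 20.0

    keep = nongap * 2 > n  # gapped in >= 50% of rows -> dropped
    if not keep.any():
        keep = nongap > 0  # degenerate: keep anything with residues
    kept_counts = counts[keep]
    kept_nongap = nongap[keep]
    cons_idx = np.argmax(kept_counts, axis=1)
    consensus = "".join(AA_ORDER[i] for i in cons_idx)
    freqs = (kept_counts + PSEUDOCOUNT) / (kept_nongap[:, None] + 20 * PSEUDOCOUNT)
    return Profile(
        orthogroup_id=orthogroup_id, consensus=consensus, freqs=freqs, n_rows=n
    )


# ---------------------------------------------------------------------------
# Profile scoring


@dataclass(frozen=True)
class SearchHit:
    query_id: str
    target_id: str
    score: float
    pct_identity: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("score must be finite")
        if not (0.0 <= self.pct_identity <= 1.0):
            raise ValueError("pct_identity must be in [0, 1]")


def _seq_column_scores(profile: Profile, seq: str) -> np.ndarray:
    """(L, m) match scores: profile column i vs sequence position j.

    Unknown residues score 0 (background odds).
    """
    S = profile.score_matrix
    m = len(seq)
    out = np.zeros((S.shape[0], m), dtype=np.float64)
    idx = np.array([_AA_INDEX.get(c, -1) for c in seq], dtype=np.int64)
    known = idx >= 0
    if known.any():
        out[:, known] = S[:, idx[known]]
    return out


def score_profile_vs_seq(
    profile: Profile,
    aa_seq: str,
    query_id: str = "",
    target_id: str = "",
    gap_open: float = PROFILE_GAP_OPEN,
    gap_ext: float = PROFILE_GAP_EXT,
) -> SearchHit:
    """Optimal local alignment of a sequence against a profile.

    Match scores are per-column log2 odds (column frequency over a uniform
    1/20 background); gaps are affine (Gotoh).  Smith-Waterman style: score
    is the best local path; identity is matches to the consensus over the
    aligned span (alignment columns including gaps).
    """
    seq = aa_seq.rstrip("*")
    if not seq:
        raise ValueError("empty sequence")
    S = _seq_column_scores(profile, seq)
    L, m = S.shape
    NEG = -1e30
    M = np.full((L + 1, m + 1), NEG)
    Ix = np.full((L + 1, m + 1), NEG)
    Iy = np.full((L + 1, m + 1), NEG)
    jarange = np.arange(m)
    for i in range(1, L + 1):
        diag = np.maximum(
            0.0,
            np.maximum(M[i - 1, :-1], np.maximum(Ix[i - 1, :-1], Iy[i - 1, :-1])),
        )
        M[i, 1:] = diag + S[i - 1]
        Ix[i, :] = np.maximum(M[i - 1, :] - gap_open, Ix[i - 1, :] - gap_ext)
        run = np.maximum.accumulate(M[i, :-1] + jarange * gap_ext)
        Iy[i, 1:] = run - gap_open - jarange * gap_ext

    inner = M[1:, 1:]
    best = float(inner.max())
    if best <= 0.0:
        return SearchHit(query_id, target_id, max(best, 0.0), 0.0)
    bi, bj = np.unravel_index(int(np.argmax(inner)), inner.shape)
    i, j = bi + 1, bj + 1
    matches, cols = _traceback_identity(
        profile.consensus, seq, S, M, Ix, Iy, i, j, gap_open
    )
    pct = matches / cols if cols else 0.0
    return SearchHit(query_id, target_id, best, float(min(max(pct, 0.0), 1.0)))


def _traceback_identity(consensus, seq, S, M, Ix, Iy, i, j, gap_open):
    eps = 1e-6
    matches = 0
    cols = 0
    state = "M"
    while i > 0 and j > 0:
        if state == "M":
            cols += 1
            if consensus[i - 1] == seq[j - 1]:
                matches += 1
            prev = M[i, j] - S[i - 1, j - 1]
            pi, pj = i - 1, j - 1
            if pi > 0 and pj > 0 and abs(prev - M[pi, pj]) < eps and M[pi, pj] > eps:
                state = "M"
            elif abs(prev - Ix[pi, pj]) < eps:
                state = "X"
            elif abs(prev - Iy[pi, pj]) < eps:
                state = "Y"
            else:
                break  # local start
            i, j = pi, pj
        elif state == "X":
            cols += 1
            if abs(Ix[i, j] - (M[i - 1, j] - gap_open)) < eps:
                state = "M"
            i -= 1
        else:
            cols += 1
            if abs(Iy[i, j] - (M[i, j - 1] - gap_open)) < eps:
                state = "M"
            j -= 1
    return matches, cols


def search_profiles(
    profiles: Sequence[Profile],
    genes: Sequence[GeneRecord],
    min_shared_kmers: int = 3,
) -> dict[str, list[SearchHit]]:
    """Score every gene against candidate profiles.

    A k-mer prefilter on the profile consensi keeps the search near-linear:
    a gene is scored against a profile only when they share at least
    ``min_shared_kmers`` distinct 5-mers.  Returns, per gene id, the hits
    sorted by decreasing score (query_id = orthogroup, target_id = gene).
    """
    index: dict[str, list[int]] = defaultdict(list)
    for pi, prof in enumerate(profiles):
        for km in kmer_set(prof.consensus):
            index[km].append(pi)
    out: dict[str, list[SearchHit]] = {}
    for gene in genes:
        seq = gene.aa_stripped
        counts: dict[int, int] = defaultdict(int)
        for km in kmer_set(seq):
            for pi in index.get(km, ()):
                counts[pi] += 1
        hits = []
        for pi, c in counts.items():
            if c < min_shared_kmers:
                continue
            hit = score_profile_vs_seq(
                profiles[pi], seq,
                query_id=profiles[pi].orthogroup_id, target_id=gene.gene_id,
            )
            if hit.score > 0:
                hits.append(hit)
        hits.sort(key=lambda h: (-h.score, h.query_id))
        out[gene.gene_id] = hits
    return out


def score_profile_vs_profile(p1: Profile, p2: Profile) -> float:
    """Symmetrized profile comparison via each consensus against the other."""
    a = score_profile_vs_seq(p1, p2.consensus).score
    b = score_profile_vs_seq(p2, p1.consensus).score
    return (a + b) / 2.0
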