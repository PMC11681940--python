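"""Synthetic multi-genome datasets with known orthogroup truth.

Emulates a genus- or species-level prokaryotic dataset: a gene-family
complement evolves by gain and loss along a random coalescent tree, and
sequences diverge by Jukes-Cantor point substitution scaled so that the
mean tip-to-tip nucleotide identity hits a target (~0.90 for a genus-level
dataset, near 1.0 within a species).  Optional in-paralog duplications
create second copies with an extra divergence burst; the duplicated
lineage is recorded as a separate family in the truth table, since
post-duplication copies are distinct orthogroups.

The generator returns in-memory proteomes (amino-acid plus nucleotide
sequences), the ground-truth pangenome, the genome tree in newick, and an
event log from which the gain/loss history can be replayed.  Same seed,
same bytes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .io import GeneRecord, Pangenome, Proteome, write_fasta, _atomic_write

NT = np.array(list("ACGT"), dtype="U1")
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset."""

    n_genomes: int = 20
    n_core_families: int = 50
    n_accessory_families: int = 50
    target_identity: float = 0.90
    gain_rate: float = 1.0
    loss_rate: float = 0.3
    dup_prob: float = 0.05
    rng_seed: int = 0
    min_len_nt: int = 300
    max_len_nt: int = 1500

    def __post_init__(self) -> None:
        if not (0 < self.target_identity <= 1):
            raise ValueError("target_identity must be in (0, 1]")
        if min(self.gain_rate, self.loss_rate, self.dup_prob) < 0:
            raise ValueError("rates must be non-negative")
        if self.n_genomes < 1 or self.n_core_families + self.n_accessory_families < 1:
            raise ValueError("need at least one genome and one family")


@dataclass
class Tree:
    """Rooted binary tree from a Kingman coalescent; branch lengths in
    expected substitutions per site after scaling."""

    parent: np.ndarray  # parent[node] or -1 for root
    children: list[tuple[int, int] | None]  # None for tips
    blen: np.ndarray  # branch length to parent
    tip_names: list[str]

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    @property
    def root(self) -> int:
        return len(self.children) - 1

    def newick(self) -> str:
        def rec(node: int) -> str:
            if self.children[node] is None:
                label = self.tip_names[node]
            else:
                a, b = self.children[node]
                label = f"({rec(a)},{rec(b)})"
            if node == self.root:
                return f"{label};"
            return f"{label}:{self.blen[node]:.6f}"

        return rec(self.root)

    def tip_depths(self) -> np.ndarray:
        depths = np.zeros(len(self.children))
        stack = [self.root]
        while stack:
            node = stack.pop()
            if self.children[node] is not None:
                for ch in self.children[node]:
                    depths[ch] = depths[node] + self.blen[ch]
                    stack.append(ch)
        return depths[: self.n_tips]


def _coalescent_tree(n: int, rng: np.random.Generator, names: list[str]) -> Tree:
    """Kingman coalescent over n tips; times in coalescent units."""
    total = 2 * n - 1
    parent = np.full(total, -1, dtype=np.int64)
    children: list[tuple[int, int] | None] = [None] * total
    times = np.zeros(total)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = active[i], active[j]
        children[nxt] = (a, b)
        parent[a] = parent[b] = nxt
        times[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    blen = np.zeros(total)
    for node in range(total - 1):
        blen[node] = times[parent[node]] - times[node]
    return Tree(parent=parent, children=children, blen=blen, tip_names=names)


def _jc_identity(d: np.ndarray | float) -> np.ndarray | float:
    return 0.25 + 0.75 * np.exp(-4.0 * np.asarray(d) / 3.0)


def _pairwise_path_lengths(tree: Tree) -> np.ndarray:
    n = tree.n_tips
    total = len(tree.children)
    # ancestor chains per tip
    depth_to_root = np.zeros(total)
    anc: list[dict[int, float]] = []
    for tip in range(n):
        chain: dict[int, float] = {}
        node, d = tip, 0.0
        while node != -1:
            chain[node] = d
            if tree.parent[node] == -1:
                break
            d += tree.blen[node]
            node = tree.parent[node]
            chain[node] = d
        anc.append(chain)
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            common = set(anc[i]) & set(anc[j])
            mrca_d = min(anc[i][c] + anc[j][c] for c in common)
            out.append(mrca_d)
    return np.array(out)


def _calibrate_scale(tree: Tree, target_identity: float) -> float:
    """Branch-length scale so mean tip-tip JC identity equals the target."""
    if target_identity >= 1.0:
        return 0.0
    paths = _pairwise_path_lengths(tree)
    lo, hi = 0.0, 1.0
    while float(np.mean(_jc_identity(paths * hi))) > target_identity:
        hi *= 2.0
        if hi > 1e6:
            break
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if float(np.mean(_jc_identity(paths * mid))) > target_identity:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def _random_cds(length_nt: int, rng: np.random.Generator) -> np.ndarray:
    """Random stop-free coding sequence as uint8 codes 0..3."""
    seq = rng.integers(0, 4, size=length_nt, dtype=np.uint8)
    return _purge_stops(seq)


def _purge_stops(seq: np.ndarray) -> np.ndarray:
    """Rewrite internal stop codons (TAA/TAG/TGA -> third base C)."""
    codons = seq.reshape(-1, 3)
    # A=0 C=1 G=2 T=3
    t = codons[:, 0] == 3
    stop = t & (
        ((codons[:, 1] == 0) & ((codons[:, 2] == 0) | (codons[:, 2] == 2)))
        | ((codons[:, 1] == 2) & (codons[:, 2] == 0))
    )
    codons[stop, 2] = 1
    return codons.reshape(-1)


def _mutate_block(
    block: np.ndarray, p: float, rng: np.random.Generator
) -> np.ndarray:
    """One Jukes-Cantor step: each site differs with probability p."""
    if p <= 0.0 or block.size == 0:
        return block
    mask = rng.random(block.size) < p
    if mask.any():
        block = block.copy()
        shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
        block[mask] = (block[mask] + shift) % 4
    return block


@dataclass
class SimResult:
    proteomes: list[Proteome]
    truth: Pangenome
    tree_newick: str
    events: list[tuple[str, str, str]] = field(default_factory=list)
    config: SimConfig | None = None

    def write(self, out_dir: str | os.PathLike) -> None:
        out = Path(out_dir)
        (out / "faa").mkdir(parents=True, exist_ok=True)
        (out / "ffn").mkdir(parents=True, exist_ok=True)
        for prot in self.proteomes:
            write_fasta(
                {g.gene_id: g.aa_seq for g in prot.genes},
                out / "faa" / f"{prot.genome_id}.faa",
            )
            write_fasta(
                {g.gene_id: g.nt_seq for g in prot.genes if g.nt_seq},
                out / "ffn" / f"{prot.genome_id}.ffn",
            )
        from .io import write_pangenome

        write_pangenome(self.truth, out / "truth.tsv")
        _atomic_write(out / "tree.nwk", self.tree_newick + "\n")
        _atomic_write(
            out / "events.tsv",
            "".join("\t".join(ev) + "\n" for ev in self.events),
        )


def simulate_pangenome(config: SimConfig) -> SimResult:
    """Generate proteomes with known orthogroup truth along a random tree."""
    rng = np.random.default_rng(config.rng_seed)
    names = [f"G{i:04d}" for i in range(config.n_genomes)]
    if config.n_genomes == 1:
        tree = Tree(
            parent=np.array([-1]),
            children=[None],
            blen=np.array([0.0]),
            tip_names=names,
        )
        scale = 0.0
    else:
        tree = _coalescent_tree(config.n_genomes, rng, names)
        scale = _calibrate_scale(tree, config.target_identity)
    tree.blen *= scale
    total_nodes = len(tree.children)
    mean_blen = float(tree.blen[: total_nodes - 1].mean()) if total_nodes > 1 else 0.0

    n_fam = config.n_core_families + config.n_accessory_families
    fam_ids = [f"F{i:06d}" for i in range(n_fam)]
    core_ids = set(fam_ids[: config.n_core_families])
    lengths = (
        rng.integers(
            config.min_len_nt // 3, config.max_len_nt // 3 + 1, size=n_fam
        )
        * 3
    )

    # family origins: core at root; accessory at root if gain_rate == 0,
    # else on a branch sampled proportionally to branch length
    events: list[tuple[str, str, str]] = []
    origin: dict[int, list[str]] = {tree.root: []}
    branch_nodes = [x for x in range(total_nodes) if x != tree.root]
    weights = tree.blen[branch_nodes]
    wsum = float(weights.sum())
    for fi, fam in enumerate(fam_ids):
        if fam in core_ids or config.gain_rate == 0.0 or wsum == 0.0:
            origin.setdefault(tree.root, []).append(fam)
            events.append(("gain", fam, f"node{tree.root}"))
        else:
            node = int(rng.choice(branch_nodes, p=weights / wsum))
            origin.setdefault(node, []).append(fam)
            events.append(("gain", fam, f"node{node}"))

    fam_len = {fam: int(lengths[i]) for i, fam in enumerate(fam_ids)}
    root_state: dict[str, np.ndarray] = {}
    for fam in origin.get(tree.root, []):
        root_state[fam] = _random_cds(fam_len[fam], rng)

    # in-paralog duplications: ancestral (pre-speciation), so duplicated
    # families are multi-copy across genomes; the copy gets an extra 10%
    # divergence burst and is lossable like an accessory family
    for fam in list(root_state):
        if rng.random() < config.dup_prob:
            root_state[f"{fam}d"] = _mutate_block(root_state[fam], 0.10, rng)
            events.append(("duplication", fam, f"node{tree.root}"))

    tip_states: dict[int, dict[str, np.ndarray]] = {}

    def mutate_state(
        state: dict[str, np.ndarray], p: float
    ) -> dict[str, np.ndarray]:
        if not state or p <= 0.0:
            return dict(state)
        keys = list(state)
        sizes = [state[kk].size for kk in keys]
        blob = np.concatenate([state[kk] for kk in keys])
        blob = _mutate_block(blob, p, rng)
        out: dict[str, np.ndarray] = {}
        pos = 0
        for kk, sz in zip(keys, sizes):
            out[kk] = blob[pos : pos + sz]
            pos += sz
        return out

    def descend(node: int, state: dict[str, np.ndarray]) -> None:
        if tree.children[node] is None:
            tip_states[node] = state
            return
        for child in tree.children[node]:
            d = float(tree.blen[child])
            p = float(0.75 * (1.0 - np.exp(-4.0 * d / 3.0)))
            child_state = mutate_state(state, p)
            # losses: accessory and duplicate copies only
            if config.loss_rate > 0.0 and mean_blen > 0.0:
                p_loss = 1.0 - np.exp(-config.loss_rate * d / mean_blen)
                for fam in list(child_state):
                    if fam in core_ids:
                        continue
                    if rng.random() < p_loss:
                        del child_state[fam]
                        events.append(("loss", fam, f"node{child}"))
            # gains scheduled on this branch
            for fam in origin.get(child, []):
                child_state[fam] = _random_cds(fam_len[fam], rng)
            descend(child, child_state)

    if config.n_genomes == 1:
        tip_states[0] = root_state
    else:
        descend(tree.root, root_state)

    proteomes: list[Proteome] = []
    truth_rows: list[tuple[str, str, str]] = []
    for tip in range(config.n_genomes):
        genome = names[tip]
        state = tip_states[tip]
        if not state:
            raise ValueError(
                f"simulated genome {genome} lost all families; lower loss_rate"
            )
        genes: list[GeneRecord] = []
        for gi, fam in enumerate(sorted(state)):
            seq = _purge_stops(state[fam].copy())
            nt = "".join(NT[seq])
            aa = str(Seq(nt).translate())
            gene_id = f"{genome}_{gi:05d}"
            genes.append(
                GeneRecord(gene_id=gene_id, genome_id=genome, aa_seq=aa, nt_seq=nt)
            )
            truth_rows.append((gene_id, genome, fam))
        proteomes.append(Proteome(genome_id=genome, genes=genes))

    return SimResult(
        proteomes=proteomes,
        truth=Pangenome(truth_rows),
        tree_newick=tree.newick(),
        events=events,
        config=config,
    )
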