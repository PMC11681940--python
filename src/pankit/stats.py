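"""Pangenome statistics and evaluation metrics.

Includes the joint maximum-likelihood model of orthogroup prevalence and
genome completeness, the derived gene fixation frequency, gene-pair
precision/recall/F for benchmarking predicted pangenomes against a truth
table, the orthogroup-mapping rule for comparing two pangenomes of the
same genes, and a phylogenetic check that a genome sampling order
discovers old ancestors before recent ones.

Prevalence/completeness model
-----------------------------
The observed presence o_ij of orthogroup j in genome i is modelled as
Bernoulli with success probability c_i * q_j, where q_j is the orthogroup
prevalence (fraction of genomes that truly carry it) and c_i the genome
completeness (probability that a truly present gene was assembled and
called).  Parameters are fitted by alternating per-coordinate Newton
updates on the Bernoulli log-likelihood, with a monotonicity safeguard
(an update is kept only where it improves the likelihood) and the scale
fixed by anchoring max(c) = 1 after every sweep, which leaves all products
c_i*q_j, and hence the likelihood, unchanged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .io import Pangenome

logger = logging.getLogger("pankit")

EPS = 1e-6


@dataclass
class PrevalenceModel:
    """Fitted per-orthogroup prevalence and per-genome completeness."""

    q: pd.Series  # prevalence per orthogroup, in [0, 1]
    c: pd.Series  # completeness per genome, in [0, 1]
    log_likelihood: float
    n_sweeps: int
    ll_path: list[float]

    def __post_init__(self) -> None:
        if ((self.q < 0) | (self.q > 1)).any() or ((self.c < 0) | (self.c > 1)).any():
            raise ValueError("parameters must lie in [0, 1]")


def _bernoulli_ll(O: np.ndarray, c: np.ndarray, q: np.ndarray) -> float:
    P = np.clip(np.outer(c, q), EPS, 1 - EPS)
    return float((O * np.log(P) + (1 - O) * np.log1p(-P)).sum())


def _newton_update_q(O: np.ndarray, c: np.ndarray, q: np.ndarray) -> np.ndarray:
    """One vectorized Newton step for every q_j with c fixed."""
    P = np.clip(c[:, None] * q[None, :], EPS, 1 - EPS)
    grad = (O / np.clip(q[None, :], EPS, None)).sum(axis=0) - (
        (1 - O) * c[:, None] / (1 - P)
    ).sum(axis=0)
    hess = -(O / np.clip(q[None, :], EPS, None) ** 2).sum(axis=0) - (
        (1 - O) * (c[:, None] / (1 - P)) ** 2
    ).sum(axis=0)
    step = np.where(hess < 0, grad / hess, 0.0)
    return np.clip(q - step, EPS, 1.0)


def fit_prevalence_completeness(
    presence: pd.DataFrame | np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> PrevalenceModel:
    """Joint ML fit of orthogroup prevalence and genome completeness.

    ``presence`` is a genome x orthogroup binary matrix.  Coordinate-ascent
    sweeps alternate Newton updates of all q (columns) and all c (rows);
    each update is kept only where it does not decrease the likelihood, so
    the log-likelihood is non-decreasing across sweeps by construction.
    All-zero rows/columns are pinned at EPS with a warning.
    """
    if isinstance(presence, pd.DataFrame):
        O = presence.to_numpy(dtype=float)
        genome_index, og_index = presence.index, presence.columns
    else:
        O = np.asarray(presence, dtype=float)
        genome_index = pd.RangeIndex(O.shape[0])
        og_index = pd.RangeIndex(O.shape[1])
    if O.ndim != 2 or O.shape[0] < 2 or O.shape[1] < 2:
        raise ValueError("presence matrix must be at least 2 x 2")

    zero_rows = O.sum(axis=1) == 0
    zero_cols = O.sum(axis=0) == 0
    if zero_rows.any() or zero_cols.any():
        logger.warning(
            "%d empty genomes and %d absent orthogroups pinned at %.0e",
            int(zero_rows.sum()), int(zero_cols.sum()), EPS,
        )

    c = np.clip(O.mean(axis=1) / max(O.mean(), EPS), EPS, 1.0)
    q = np.clip(O.mean(axis=0), EPS, 1.0)
    ll = _bernoulli_ll(O, c, q)
    ll_path = [ll]
    sweeps = 0
    for sweeps in range(1, max_iter + 1):
        q_new = _newton_update_q(O, c, q)
        q = _keep_if_better_cols(O, c, q, q_new)
        c_new = _newton_update_q(O.T, q, c)
        c = _keep_if_better_cols(O.T, q, c, c_new)
        # anchor max(c) = 1; rescaling both blocks leaves c*q unchanged
        s = float(c.max())
        if s > 0:
            c = np.clip(c / s, EPS, 1.0)
            q = np.clip(q * s, EPS, 1.0)
        q[zero_cols] = EPS
        c[zero_rows] = EPS
        ll_new = _bernoulli_ll(O, c, q)
        ll_path.append(ll_new)
        if ll_new - ll < tol:
            ll = ll_new
            break
        ll = ll_new
    return PrevalenceModel(
        q=pd.Series(q, index=og_index),
        c=pd.Series(c, index=genome_index),
        log_likelihood=ll,
        n_sweeps=sweeps,
        ll_path=ll_path,
    )


def _keep_if_better_cols(
    O: np.ndarray, other: np.ndarray, cur: np.ndarray, new: np.ndarray
) -> np.ndarray:
    """Per-column comparison of the likelihood; keep the better value."""
    P_cur = np.clip(other[:, None] * cur[None, :], EPS, 1 - EPS)
    P_new = np.clip(other[:, None] * new[None, :], EPS, 1 - EPS)
    ll_cur = (O * np.log(P_cur) + (1 - O) * np.log1p(-P_cur)).sum(axis=0)
    ll_new = (O * np.log(P_new) + (1 - O) * np.log1p(-P_new)).sum(axis=0)
    return np.where(ll_new >= ll_cur, new, cur)


# ---------------------------------------------------------------------------
# Fixation frequency


@dataclass(frozen=True)
class FixationRecord:
    """Per-orthogroup species-level fixation summary."""

    orthogroup_id: str
    n_species_present: int
    n_species_core: int
    fixation_freq: float

    def __post_init__(self) -> None:
        if not (0 <= self.n_species_core <= self.n_species_present):
            raise ValueError("need 0 <= core <= present")
        expected = self.n_species_core / self.n_species_present
        if abs(self.fixation_freq - expected) > 1e-12:
            raise ValueError("fixation_freq must equal core/present")


def fixation_frequencies(
    pangenome: Pangenome,
    species_map: Mapping[str, str],
    min_genomes: int = 10,
    min_species: int = 10,
    core_prev: float = 0.95,
) -> list[FixationRecord]:
    """Fixation frequency of each orthogroup across species.

    Species with at least ``min_genomes`` genomes are retained; per
    species, the prevalence/completeness model is fitted on its presence
    matrix and an orthogroup counts as species-core when its fitted
    prevalence reaches ``core_prev``.  Orthogroups present (>= 1 genome)
    in at least ``min_species`` retained species get a record: the
    fraction of present-in species in which they are core.
    """
    df = pangenome.to_frame()
    missing = set(df["genome"]) - set(species_map)
    if missing:
        raise ValueError(f"species_map missing genomes: {sorted(missing)[:5]}")
    df["species"] = df["genome"].map(species_map)
    genomes_per_species = df.groupby("species")["genome"].nunique()
    kept_species = genomes_per_species.index[genomes_per_species >= min_genomes]

    present_in: dict[str, set[str]] = {}
    core_in: dict[str, set[str]] = {}
    for species in kept_species:
        sub = df[df["species"] == species]
        presence = (
            sub.groupby(["genome", "orthogroup"]).size().unstack(fill_value=0) > 0
        ).astype(int)
        for og in presence.columns:
            present_in.setdefault(og, set()).add(species)
        if presence.shape[0] < 2 or presence.shape[1] < 2:
            core = set(presence.columns[presence.mean(axis=0) >= core_prev])
        else:
            model = fit_prevalence_completeness(presence)
            core = set(model.q.index[model.q >= core_prev])
        for og in core:
            core_in.setdefault(og, set()).add(species)

    records = []
    for og in sorted(present_in):
        n_present = len(present_in[og])
        if n_present < min_species:
            continue
        n_core = len(core_in.get(og, set()))
        records.append(
            FixationRecord(
                orthogroup_id=og,
                n_species_present=n_present,
                n_species_core=n_core,
                fixation_freq=n_core / n_present,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Gene-pair precision/recall/F


def genepair_prf(
    predicted: Pangenome, truth: Pangenome
) -> tuple[float, float, float]:
    """Precision, recall and F over co-clustered gene pairs.

    Family-size-aware: pair counts come from the predicted-vs-truth
    contingency table, never from materializing the pairs.  With no
    predicted (resp. true) pairs at all, precision (resp. recall) is 1 by
    convention, with a warning.
    """
    pred = {g: og for g, _gm, og in predicted.rows}
    true = {g: og for g, _gm, og in truth.rows}
    if set(pred) != set(true):
        diff = len(set(pred) ^ set(true))
        raise ValueError(f"gene universes differ by {diff} genes")

    df = pd.DataFrame(
        {"pred": pd.Series(pred), "true": pd.Series(true)}
    )
    joint = df.groupby(["pred", "true"]).size()
    tp = int((joint * (joint - 1) // 2).sum())
    pred_sizes = df.groupby("pred").size()
    true_sizes = df.groupby("true").size()
    pred_pairs = int((pred_sizes * (pred_sizes - 1) // 2).sum())
    true_pairs = int((true_sizes * (true_sizes - 1) // 2).sum())
    if pred_pairs == 0:
        logger.warning("no co-clustered pairs predicted; precision set to 1")
        precision = 1.0
    else:
        precision = tp / pred_pairs
    if true_pairs == 0:
        logger.warning("no co-clustered pairs in truth; recall set to 1")
        recall = 1.0
    else:
        recall = tp / true_pairs
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f


# ---------------------------------------------------------------------------
# Orthogroup mapping between two pangenomes


def map_orthogroups(
    pg_a: Pangenome, pg_b: Pangenome, share_prev: float = 0.95
) -> list[tuple[str, str]]:
    """Match orthogroups of two pangenomes over the same genes.

    Orthogroups a (from A) and b (from B) are 'the same' when the genomes
    holding shared genes (genes assigned to a in A and to b in B) cover at
    least ``share_prev`` of the genomes of a AND of b (symmetric rule).
    Greedy 1:1 matching, ties broken by largest shared-gene count then
    lexicographic ids.
    """
    a_of = {g: og for g, _gm, og in pg_a.rows}
    genome_of = {g: gm for g, gm, _og in pg_a.rows}
    genome_of.update({g: gm for g, gm, _og in pg_b.rows})
    genomes_a: dict[str, set[str]] = {}
    genomes_b: dict[str, set[str]] = {}
    for g, gm, og in pg_a.rows:
        genomes_a.setdefault(og, set()).add(gm)
    for g, gm, og in pg_b.rows:
        genomes_b.setdefault(og, set()).add(gm)

    shared_genes: dict[tuple[str, str], set[str]] = {}
    for g, gm, og_b in pg_b.rows:
        og_a = a_of.get(g)
        if og_a is not None:
            shared_genes.setdefault((og_a, og_b), set()).add(g)

    candidates = []
    for (og_a, og_b), genes in shared_genes.items():
        shared_genomes = {genome_of[g] for g in genes}
        if (
            len(shared_genomes) >= share_prev * len(genomes_a[og_a])
            and len(shared_genomes) >= share_prev * len(genomes_b[og_b])
        ):
            candidates.append((-len(genes), og_a, og_b))
    candidates.sort()
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs = []
    for _neg, og_a, og_b in candidates:
        if og_a in used_a or og_b in used_b:
            continue
        used_a.add(og_a)
        used_b.add(og_b)
        pairs.append((og_a, og_b))
    return sorted(pairs)


def mapping_prf(
    pg_pred: Pangenome, pg_ref: Pangenome, share_prev: float = 0.95
) -> tuple[float, float, float]:
    """Precision/recall/F of predicted orthogroups against a reference,
    under the orthogroup-mapping rule."""
    pairs = map_orthogroups(pg_pred, pg_ref, share_prev)
    n_pred = len(set(og for _g, _gm, og in pg_pred.rows))
    n_ref = len(set(og for _g, _gm, og in pg_ref.rows))
    precision = len(pairs) / n_pred if n_pred else 1.0
    recall = len(pairs) / n_ref if n_ref else 1.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f


# ---------------------------------------------------------------------------
# Ancestor discovery order


def ancestor_discovery_order(
    tree: str | dendropy.Tree, sample_order: Sequence[str]
) -> float:
    """Fraction of consecutive ancestor discoveries in old-before-recent order.

    Each sampled genome (from the second on) discovers the most recent
    common ancestor of itself and the closest already-sampled genome by
    patristic distance.  Returns the fraction of consecutive discovery
    pairs where the earlier-discovered ancestor is at least as old (no
    deeper from the root) as the later one; 1.0 by convention for a single
    discovery.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    taxa = {t.label: t for t in tree.taxon_namespace}
    missing = [s for s in sample_order if s not in taxa]
    if missing:
        raise ValueError(f"tips missing from tree: {missing}")
    if len(sample_order) < 2:
        raise ValueError("need at least two sampled genomes")
    pdm = tree.phylogenetic_distance_matrix()
    root_dist = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        d = 0.0 if parent is None else root_dist[parent] + (node.edge.length or 0.0)
        root_dist[node] = d

    depths = []
    for i in range(1, len(sample_order)):
        new = sample_order[i]
        prev = min(
            sample_order[:i],
            key=lambda s: (pdm.patristic_distance(taxa[new], taxa[s]), s),
        )
        mrca = pdm.mrca(taxa[new], taxa[prev])
        depths.append(root_dist[mrca])
    if len(depths) == 1:
        return 1.0
    good = sum(
        1 for d1, d2 in zip(depths, depths[1:]) if d1 <= d2 + 1e-12
    )
    return good / (len(depths) - 1)
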