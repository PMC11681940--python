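import itertools

import numpy as np
import pytest

from pankit.io import GeneRecord, ParamSet
from pankit.pan import (
    Cluster,
    _all_genes,
    evaluate_split,
    infer_pangenome,
    propose_split,
    supercluster,
)
from pankit.simulate import SimConfig, simulate_pangenome


def mc_expected_cooccurrence(genomes_a, genomes_b, n_draws=10_000, seed=0):
    """Monte-Carlo permutation oracle for the random-bipartition null."""
    rng = np.random.default_rng(seed)
    labels = list(genomes_a) + list(genomes_b)
    a = len(genomes_a)
    total = 0
    for _ in range(n_draws):
        perm = rng.permutation(len(labels))
        ga = {labels[i] for i in perm[:a]}
        gb = {labels[i] for i in perm[a:]}
        total += len(ga & gb)
    return total / n_draws


class TestEvaluateSplit:
    def test_strict_single_copy_boundary_rejected(self):
        # 10 genomes, one gene each, split 5/5: observed = expected = 0;
        # the boundary tie is rejected so single-copy families stay whole
        genomes = [f"G{i}" for i in range(10)]
        v = evaluate_split(genomes[:5], genomes[5:])
        assert v.observed_cooccurrence == 0
        assert v.expected_cooccurrence == pytest.approx(0.0, abs=1e-12)
        assert not v.accepted

    def test_clean_paralogs_accepted(self):
        genomes = [f"G{i}" for i in range(8)]
        v = evaluate_split(genomes, genomes)  # every genome holds one A + one B
        assert v.observed_cooccurrence == 8
        assert v.observed_cooccurrence >= v.expected_cooccurrence
        assert v.accepted

    def test_unequal_single_copy_split_rejected(self):
        # k_g = 1 everywhere forces expected = 0 regardless of sizes
        genomes = [f"G{i}" for i in range(10)]
        v = evaluate_split(genomes[:7], genomes[7:])
        assert v.expected_cooccurrence == pytest.approx(0.0, abs=1e-12)
        assert not v.accepted

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            evaluate_split([], ["G1"])

    @pytest.mark.parametrize("seed", range(6))
    def test_expected_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        n_genomes = int(rng.integers(2, 10))
        genomes = [f"G{i}" for i in range(n_genomes)]
        labels = [genomes[i] for i in rng.integers(0, n_genomes,
                                                   size=int(rng.integers(4, 40)))]
        a = int(rng.integers(1, len(labels)))
        ga, gb = labels[:a], labels[a:]
        v = evaluate_split(ga, gb)
        n_draws = 10_000
        mc = mc_expected_cooccurrence(ga, gb, n_draws, seed)
        # binomial-ish SE per genome, summed conservatively
        se = max(0.5 * np.sqrt(n_genomes / n_draws), 1e-9)
        assert v.expected_cooccurrence == pytest.approx(mc, abs=3 * max(se, 0.05))


class TestProposeSplit:
    def _genes(self, seqs_by_genome):
        gs = {}
        for genome, seqs in seqs_by_genome.items():
            for i, s in enumerate(seqs):
                gid = f"{genome}_{i}"
                gs[gid] = GeneRecord(gid, genome, s)
        return gs

    def test_two_sequence_types_separated(self):
        rng = np.random.default_rng(4)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        s1 = "".join(rng.choice(aa, 40))
        s2 = "".join(rng.choice(aa, 40))
        genes = self._genes({"G1": [s1, s2], "G2": [s1, s2]})
        cluster = Cluster(sorted(genes), [genes[g].genome_id for g in sorted(genes)])
        a, b, _ = propose_split(cluster, genes, ParamSet())
        groups = {frozenset(a), frozenset(b)}
        # brute-force optimal 2-partition by within-group identity: the two
        # copies of each sequence type belong together
        assert groups == {
            frozenset({"G1_0", "G2_0"}), frozenset({"G1_1", "G2_1"})
        }

    def test_pair_cluster_splits_into_singletons(self):
        genes = self._genes({"G1": ["MKVHDEAAK"], "G2": ["MKVHDEAAH"]})
        cluster = Cluster(sorted(genes), ["G1", "G2"])
        a, b, _ = propose_split(cluster, genes, ParamSet())
        assert len(a) == len(b) == 1

    def test_identical_sequences_still_binary(self):
        genes = self._genes({"G1": ["MKVHDE"], "G2": ["MKVHDE"], "G3": ["MKVHDE"]})
        cluster = Cluster(sorted(genes), ["G1", "G2", "G3"])
        a, b, _ = propose_split(cluster, genes, ParamSet())
        assert a and b and set(a) | set(b) == set(genes)

    def test_size_one_rejected(self):
        genes = self._genes({"G1": ["MKV"]})
        with pytest.raises(ValueError):
            propose_split(Cluster(["G1_0"], ["G1"]), genes, ParamSet())


class TestInferPangenome:
    def test_partition_and_determinism(self, small_sim):
        params = ParamSet(rng_seed=7)
        pg1 = infer_pangenome(small_sim.proteomes, params)
        pg2 = infer_pangenome(small_sim.proteomes, params)
        assert pg1.rows == pg2.rows
        all_genes = {g.gene_id for p in small_sim.proteomes for g in p.genes}
        assert {r[0] for r in pg1.rows} == all_genes

    def test_dissimilar_genes_become_singletons(self):
        rng = np.random.default_rng(12)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        genes = [
            GeneRecord(f"g{i}", "G1", "".join(rng.choice(aa, 50)))
            for i in range(6)
        ]
        from pankit.io import Proteome

        pg = infer_pangenome([Proteome("G1", genes)], ParamSet())
        assert len(pg.orthogroup_ids) == 6

    def test_ancestral_paralogs_split_by_cooccurrence(self):
        sim = simulate_pangenome(SimConfig(
            n_genomes=8, n_core_families=10, n_accessory_families=0,
            dup_prob=0.5, loss_rate=0.0, rng_seed=6,
        ))
        truth_fams = set(r[2] for r in sim.truth.rows)
        dup_fams = {f for f in truth_fams if f.endswith("d")}
        assert dup_fams  # the scenario actually contains duplications
        pg = infer_pangenome(sim.proteomes, ParamSet(rng_seed=1))
        from pankit.stats import genepair_prf

        p, r, f = genepair_prf(pg, sim.truth)
        assert f >= 0.95

    def test_supercluster_merges_diverged_preclusters(self, small_sim):
        clusters, _ = supercluster(small_sim.proteomes, ParamSet(rng_seed=0))
        truth = {r[0]: r[2] for r in small_sim.truth.rows}
        # every true family must land inside a single supercluster
        fam_to_clusters = {}
        for ci, c in enumerate(clusters):
            for g in c.gene_ids:
                fam_to_clusters.setdefault(truth[g].rstrip("d"), set()).add(ci)
        n_split = sum(1 for v in fam_to_clusters.values() if len(v) > 1)
        assert n_split == 0
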