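import itertools

import numpy as np
import pytest

from pankit import backend
from pankit.backend import (
    Msa,
    Profile,
    align,
    build_profile,
    kmer_identity,
    precluster,
    score_profile_vs_profile,
    score_profile_vs_seq,
)
from pankit.io import GeneRecord

from conftest import make_proteome


def genes(seqs):
    return [GeneRecord(f"g{i}", "G", s) for i, s in enumerate(seqs)]


RNG = np.random.default_rng(0)
AA = list("ACDEFGHIKLMNPQRSTVWY")


def random_seq(n, rng=RNG):
    return "".join(rng.choice(AA, size=n))


def mutate(seq, p, rng=RNG):
    out = []
    for c in seq:
        out.append(rng.choice(AA) if rng.random() < p else c)
    return "".join(out)


# ---------------------------------------------------------------------------
# preclustering


class TestPrecluster:
    def test_identical_sequences_one_cluster(self):
        gs = genes(["MKVHDEAAKKL" * 3] * 2)
        assert len(precluster(gs, 0.5)) == 1

    def test_disjoint_kmers_two_clusters(self):
        gs = genes(["AAAAAAAAAA", "WWWWWWWWWW"])
        assert len(precluster(gs, 0.3)) == 2

    def test_two_families_recovered_against_bruteforce_oracle(self):
        # 2 families at ~50% mutual identity; within-family ~98%
        rng = np.random.default_rng(7)
        fam_a = random_seq(60, rng)
        fam_b = mutate(fam_a, 0.5, rng)
        seqs = [mutate(fam_a, 0.02, rng) for _ in range(5)] + [
            mutate(fam_b, 0.02, rng) for _ in range(5)
        ]
        gs = genes(seqs)
        clusters = precluster(gs, 0.5)
        # oracle: single-linkage on brute-force k-mer identity at the cutoff
        ids = [g.gene_id for g in gs]
        seq_of = {g.gene_id: g.aa_stripped for g in gs}
        parent = {i: i for i in ids}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for a, b in itertools.combinations(ids, 2):
            if kmer_identity(seq_of[a], seq_of[b]) >= 0.5:
                parent[find(a)] = find(b)
        oracle = {frozenset(g for g in ids if find(g) == r)
                  for r in {find(i) for i in ids}}
        assert {frozenset(c) for c in clusters} == oracle

    def test_partition_property_random_inputs(self):
        rng = np.random.default_rng(11)
        for trial in range(5):
            seqs = [random_seq(int(rng.integers(8, 80)), rng)
                    for _ in range(int(rng.integers(1, 25)))]
            gs = genes(seqs)
            clusters = precluster(gs, float(rng.uniform(0.1, 0.9)))
            flat = [g for c in clusters for g in c]
            assert sorted(flat) == sorted(g.gene_id for g in gs)


# ---------------------------------------------------------------------------
# alignment


class TestAlign:
    def test_identical_sequences_no_gaps(self):
        msa = align(genes(["MKVHDE", "MKVHDE"]))
        assert msa.rows == ["MKVHDE", "MKVHDE"]

    def test_single_gap_total(self):
        msa = align(genes(["ACDEF", "ACEF"]))
        assert msa.width == 5
        assert sum(r.count("-") for r in msa.rows) == 1

    def test_ungap_reproduces_inputs(self):
        rng = np.random.default_rng(3)
        base = random_seq(50, rng)
        seqs = [mutate(base, 0.1, rng) for _ in range(6)]
        seqs[2] = seqs[2][:20] + seqs[2][25:]  # deletion
        msa = align(genes(seqs))
        for i, s in enumerate(seqs):
            assert msa.ungapped(i) == s

    def test_single_sequence_trivial(self):
        msa = align(genes(["MKV"]))
        assert msa.rows == ["MKV"]

    def test_subset_drops_allgap_columns(self):
        msa = Msa(["a", "b", "c"], ["AC-D", "AC-D", "ACXD"])
        sub = msa.subset(["a", "b"])
        assert sub.rows == ["ACD", "ACD"]


# ---------------------------------------------------------------------------
# profiles


class TestBuildProfile:
    def test_single_sequence_consensus_is_sequence(self):
        msa = align(genes(["MKVHDE"]))
        prof = build_profile(msa)
        assert prof.consensus == "MKVHDE"

    def test_pseudocount_arithmetic_two_identical_rows(self):
        prof = build_profile(Msa(["a", "b"], ["A", "A"]))
        ai = backend.AA_ORDER.index("A")
        assert prof.freqs[0, ai] == pytest.approx((2 + 0.1) / (2 + 2))
        assert prof.freqs[0].sum() == pytest.approx(1.0)

    def test_majority_consensus(self):
        prof = build_profile(Msa(["a", "b", "c"], ["A", "A", "C"]))
        assert prof.consensus == "A"

    def test_majority_gap_columns_dropped(self):
        # col2 gapped in 2/3 rows and col3 in all rows -> both dropped
        prof = build_profile(Msa(["a", "b", "c"], ["AD-", "A--", "A--"]))
        assert prof.consensus == "A"

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError):
            Msa(["a", "b"], ["AA", "A"])


# ---------------------------------------------------------------------------
# profile scoring vs independent DP oracle


def oracle_local_profile_score(profile, seq, gap_open, gap_ext):
    """Plain-python Gotoh local alignment; independent of the engine."""
    S = [
        [
            float(np.log2(profile.freqs[i][backend.AA_ORDER.index(c)] * 20))
            if c in backend.AA_ORDER
            else 0.0
            for c in seq
        ]
        for i in range(len(profile.consensus))
    ]
    L, m = len(S), len(seq)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(L + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(L + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(L + 1)]
    best = 0.0
    for i in range(1, L + 1):
        for j in range(1, m + 1):
            diag = max(0.0, M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = diag + S[i - 1][j - 1]
            Ix[i][j] = max(M[i - 1][j] - gap_open, Ix[i - 1][j] - gap_ext)
            Iy[i][j] = max(M[i][j - 1] - gap_open, Iy[i][j - 1] - gap_ext)
            best = max(best, M[i][j])
    return best


class TestProfileScoring:
    def test_consensus_scores_identity_one(self):
        prof = build_profile(align(genes(["MKVHDEAAKKLW"] * 3)))
        hit = score_profile_vs_seq(prof, prof.consensus)
        assert hit.pct_identity == pytest.approx(1.0)

    def test_unrelated_sequence_scores_below_consensus(self):
        prof = build_profile(align(genes(["MKVHDEAAKKLW" * 3] * 3)))
        rng = np.random.default_rng(5)
        random_hit = score_profile_vs_seq(prof, random_seq(36, rng))
        self_hit = score_profile_vs_seq(prof, prof.consensus)
        assert random_hit.score < self_hit.score

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_bruteforce_dp_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n_rows = int(rng.integers(1, 4))
        base = random_seq(int(rng.integers(5, 30)), rng)
        msa = align(genes([mutate(base, 0.1, rng) for _ in range(n_rows)]))
        prof = build_profile(msa)
        seq = mutate(random_seq(int(rng.integers(5, 30)), rng), 0.5, rng)
        expected = oracle_local_profile_score(
            prof, seq, backend.PROFILE_GAP_OPEN, backend.PROFILE_GAP_EXT
        )
        got = score_profile_vs_seq(prof, seq).score
        assert got == pytest.approx(expected, abs=1e-6)

    def test_profile_vs_profile_symmetric_and_separating(self):
        rng = np.random.default_rng(9)
        fam_a = random_seq(40, rng)
        fam_b = random_seq(40, rng)
        pa = build_profile(align(genes([mutate(fam_a, 0.05, rng) for _ in range(3)])))
        pb = build_profile(align(genes([mutate(fam_a, 0.15, rng) for _ in range(3)])))
        pc = build_profile(align(genes([mutate(fam_b, 0.05, rng) for _ in range(3)])))
        assert score_profile_vs_profile(pa, pb) == pytest.approx(
            score_profile_vs_profile(pb, pa)
        )
        assert score_profile_vs_profile(pa, pb) > score_profile_vs_profile(pa, pc)


class TestExternalEngines:
    def test_get_aligner_selects_engine(self):
        assert backend.get_aligner("builtin") is align
        with pytest.raises(ValueError):
            backend.get_aligner("muscle")

    @pytest.mark.skipif(
        __import__("shutil").which("mafft") is None,
        reason="mafft binary not installed",
    )
    def test_mafft_adapter_returns_valid_msa(self):
        seqs = ["MKVHDEAAKKLW", "MKVHDEAKKLW", "MKVHDEAAKKLW"]
        msa = backend.align_mafft(genes(seqs))
        assert len(msa) == 3
        for i, s in enumerate(seqs):
            assert msa.ungapped(i) == s


def test_search_profiles_finds_own_family():
    rng = np.random.default_rng(21)
    fams = [random_seq(50, rng) for _ in range(4)]
    profiles = [
        build_profile(
            align(genes([mutate(f, 0.05, rng) for _ in range(3)])), f"F{i}"
        )
        for i, f in enumerate(fams)
    ]
    queries = [GeneRecord(f"q{i}", "G", mutate(f, 0.1, rng))
               for i, f in enumerate(fams)]
    hits = backend.search_profiles(profiles, queries)
    for i, q in enumerate(queries):
        assert hits[q.gene_id][0].query_id == f"F{i}"
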