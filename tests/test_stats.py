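import itertools

import numpy as np
import pandas as pd
import pytest

from pankit.io import Pangenome
from pankit.stats import (
    FixationRecord,
    ancestor_discovery_order,
    fit_prevalence_completeness,
    fixation_frequencies,
    genepair_prf,
    map_orthogroups,
    mapping_prf,
)


def pg_from(assign):
    """Pangenome from {gene: (genome, og)}."""
    return Pangenome([(g, gm, og) for g, (gm, og) in sorted(assign.items())])


# ---------------------------------------------------------------------------
# prevalence / completeness model


class TestPrevalenceCompleteness:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        n, m = 200, 300
        q = rng.uniform(0.2, 1.0, m)
        c = rng.uniform(0.8, 1.0, n)
        O = (rng.random((n, m)) < np.outer(c, q)).astype(int)
        model = fit_prevalence_completeness(pd.DataFrame(O))
        assert np.abs(model.q.to_numpy() - q).mean() <= 0.05

    def test_loglik_nondecreasing_every_sweep(self):
        rng = np.random.default_rng(1)
        O = (rng.random((50, 80)) < 0.6).astype(int)
        model = fit_prevalence_completeness(pd.DataFrame(O))
        assert all(
            b >= a - 1e-9 for a, b in zip(model.ll_path, model.ll_path[1:])
        )

    def test_all_ones_boundary(self):
        model = fit_prevalence_completeness(np.ones((5, 6), dtype=int))
        assert np.allclose(model.q, 1.0, atol=1e-3)
        assert np.allclose(model.c, 1.0, atol=1e-3)

    def test_anchor_keeps_scale_identifiable(self):
        rng = np.random.default_rng(2)
        O = (rng.random((30, 40)) < 0.5).astype(int)
        model = fit_prevalence_completeness(O)
        assert model.c.max() == pytest.approx(1.0)

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError):
            fit_prevalence_completeness(np.ones((1, 5)))


# ---------------------------------------------------------------------------
# fixation frequency


def make_species_pangenome(core_species, present_species, n_genomes=12):
    """One orthogroup 'X' core in some species, present-in-one-genome in
    others; plus background families so each species has a pangenome."""
    rows = []
    species_map = {}
    all_species = sorted(set(core_species) | set(present_species))
    for si, sp in enumerate(all_species):
        for gi in range(n_genomes):
            genome = f"{sp}_g{gi}"
            species_map[genome] = sp
            for f in range(5):  # background core families per species
                rows.append((f"{genome}_b{f}", genome, f"BG{f}"))
            if sp in core_species:
                rows.append((f"{genome}_x", genome, "X"))
            elif sp in present_species and gi == 0:
                rows.append((f"{genome}_x", genome, "X"))
    return Pangenome(rows), species_map


class TestFixationFrequencies:
    def test_toy_three_of_ten(self):
        core = [f"S{i}" for i in range(3)]
        present = [f"S{i}" for i in range(3, 10)]
        pg, smap = make_species_pangenome(core, present)
        recs = {r.orthogroup_id: r for r in fixation_frequencies(pg, smap)}
        assert recs["X"].n_species_present == 10
        assert recs["X"].n_species_core == 3
        assert recs["X"].fixation_freq == pytest.approx(0.30)

    def test_boundaries_zero_and_one(self):
        pg1, smap1 = make_species_pangenome([f"S{i}" for i in range(10)], [])
        assert {r.fixation_freq for r in fixation_frequencies(pg1, smap1)
                if r.orthogroup_id == "X"} == {1.0}
        pg0, smap0 = make_species_pangenome([], [f"S{i}" for i in range(10)])
        assert {r.fixation_freq for r in fixation_frequencies(pg0, smap0)
                if r.orthogroup_id == "X"} == {0.0}

    def test_min_species_filter(self):
        pg, smap = make_species_pangenome(["S0"], ["S1", "S2"])
        recs = fixation_frequencies(pg, smap, min_species=10)
        assert "X" not in {r.orthogroup_id for r in recs}

    def test_record_invariant(self):
        with pytest.raises(ValueError):
            FixationRecord("F", 10, 3, 0.5)


# ---------------------------------------------------------------------------
# gene-pair precision / recall / F


def brute_force_prf(pred, truth):
    def pairs(pg):
        by = {}
        for g, _gm, og in pg.rows:
            by.setdefault(og, []).append(g)
        return {
            frozenset(p)
            for genes in by.values()
            for p in itertools.combinations(sorted(genes), 2)
        }

    P, T = pairs(pred), pairs(truth)
    tp, fp, fn = len(P & T), len(P - T), len(T - P)
    prec = tp / (tp + fp) if tp + fp else 1.0
    rec = tp / (tp + fn) if tp + fn else 1.0
    f = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f


class TestGenepairPrf:
    def test_identical_is_perfect(self):
        pg = pg_from({f"g{i}": ("G", f"F{i % 3}") for i in range(9)})
        assert genepair_prf(pg, pg) == (1.0, 1.0, 1.0)

    def test_split_family_of_four(self):
        truth = pg_from({f"g{i}": ("G", "F") for i in range(4)})
        pred = pg_from({f"g{i}": ("G", f"F{i // 2}") for i in range(4)})
        p, r, f = genepair_prf(pred, truth)
        assert (p, r, f) == (1.0, pytest.approx(1 / 3), pytest.approx(0.5))

    def test_all_singletons_convention(self):
        truth = pg_from({f"g{i}": ("G", "F") for i in range(4)})
        pred = pg_from({f"g{i}": ("G", f"F{i}") for i in range(4)})
        p, r, f = genepair_prf(pred, truth)
        assert p == 1.0 and r == 0.0

    def test_universe_mismatch_reports_size(self):
        a = pg_from({"g1": ("G", "F")})
        b = pg_from({"g2": ("G", "F")})
        with pytest.raises(ValueError, match="2"):
            genepair_prf(a, b)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 200))
        genes = {
            f"g{i}": (f"G{rng.integers(5)}", f"F{rng.integers(1, 8)}")
            for i in range(n)
        }
        truth = pg_from(genes)
        pred = pg_from({
            g: (gm, f"P{rng.integers(1, 8)}") for g, (gm, _og) in genes.items()
        })
        assert genepair_prf(pred, truth) == pytest.approx(
            brute_force_prf(pred, truth)
        )


# ---------------------------------------------------------------------------
# orthogroup mapping


class TestMapOrthogroups:
    def test_identical_pangenomes_map_perfectly(self):
        pg = pg_from({f"g{i}": (f"G{i % 5}", f"F{i % 3}") for i in range(15)})
        pairs = map_orthogroups(pg, pg)
        assert pairs == [(og, og) for og in sorted({"F0", "F1", "F2"})]
        assert mapping_prf(pg, pg) == (1.0, 1.0, 1.0)

    def test_disjoint_assignments_no_match(self):
        a = pg_from({f"g{i}": (f"G{i}", "FA") for i in range(4)})
        b_rows = {f"g{i}": (f"G{i}", f"FB{i}") for i in range(4)}
        pairs = map_orthogroups(a, pg_from(b_rows))
        assert pairs == []  # singletons share genes in only 1/4 of a's genomes

    def test_renamed_orthogroups_still_match(self):
        genes = {f"g{i}": (f"G{i % 6}", f"F{i % 2}") for i in range(12)}
        a = pg_from(genes)
        b = pg_from({g: (gm, og.replace("F", "Z")) for g, (gm, og) in genes.items()})
        assert map_orthogroups(a, b) == [("F0", "Z0"), ("F1", "Z1")]


# ---------------------------------------------------------------------------
# ancestor discovery order


BALANCED8 = (
    "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
)


class TestAncestorDiscoveryOrder:
    def test_root_to_tip_order_is_perfect(self):
        # A then E discovers the root; then C (depth 1), then B... depths
        # never decrease
        assert ancestor_discovery_order(
            BALANCED8, ["A", "E", "C", "G", "B", "D", "F", "H"]
        ) == 1.0

    def test_reversed_order_is_imperfect(self):
        frac = ancestor_discovery_order(
            BALANCED8, ["A", "B", "C", "D", "E", "F", "G", "H"]
        )
        assert frac < 1.0

    def test_two_samples_convention(self):
        assert ancestor_discovery_order(BALANCED8, ["A", "H"]) == 1.0

    def test_missing_tip_errors(self):
        with pytest.raises(ValueError, match="missing"):
            ancestor_discovery_order(BALANCED8, ["A", "ZZ"])
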