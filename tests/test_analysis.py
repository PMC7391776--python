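"""Genotypes, clades, Muller tables, topology, matrices and PCA."""

import numpy as np
import pandas as pd
import pytest

from microverse.analysis import (
    CladeRecord,
    MetabolicGenotype,
    build_muller_table,
    classify_topology,
    community_production_rate,
    gene_frequency_matrix,
    metabolic_genotype,
    pca_scores,
    proteome_matrix,
)
from microverse.cell import Cell, CellState
from microverse.chemistry import BB_ENERGY, NO_ENERGY, RESOURCE_ENERGY
from microverse.genome import Gene, Genome


def _enzyme(idx, **kw):
    params = dict(promoter=1.0, k_s=0.5, v_max=2.0)
    params.update(kw)
    return Gene("enzyme", conversion_index=idx, **params)


def _conv_index(universe, rxn_str):
    return next(r.index for r in universe.conversions if str(r) == rxn_str)


class TestMetabolicGenotype:
    def test_copy_number_invariance(self, universe):
        one = Genome([_enzyme(5)])
        three = Genome([_enzyme(5, promoter=1.0), _enzyme(5, promoter=7.0), _enzyme(5)])
        assert metabolic_genotype(one, universe) == metabolic_genotype(three, universe)

    def test_empty_genome_all_zero(self, universe):
        bits = metabolic_genotype(Genome([]), universe)
        assert not any(bits.bits)

    def test_importer_exporter_distinct_bits(self, universe):
        imp = Genome([Gene("transporter", 1, 0.5, 1, substrate="B1", k_e=0.3,
                           exporting=False)])
        exp = Genome([Gene("transporter", 1, 0.5, 1, substrate="B1", k_e=0.3,
                           exporting=True)])
        assert metabolic_genotype(imp, universe) != metabolic_genotype(exp, universe)

    def test_six_gene_genome_at_most_six_bits(self, universe, rng):
        genes = [_enzyme(int(i)) for i in rng.integers(0, 43, 6)]
        bits = metabolic_genotype(Genome(genes), universe)
        assert 1 <= sum(bits.bits) <= 6


def _clade(cid, parent, origin, abundance):
    bits = MetabolicGenotype(tuple([cid % 2 == 0] * 59))
    return CladeRecord(cid, parent, bits, origin, abundance)


class TestMullerTable:
    def test_single_clade_flat_series(self):
        clades = [_clade(0, None, 0, {0: 10, 500: 10, 1000: 10})]
        edges, pops = build_muller_table(clades, subsample=500)
        assert edges.empty
        assert list(pops.Population) == [10, 10, 10]

    def test_rare_child_folds_into_parent(self):
        clades = [
            _clade(0, None, 0, {0: 100, 500: 96, 1000: 98}),
            _clade(1, 0, 300, {500: 4, 1000: 2}),  # peaks at 4% of max pop
        ]
        edges, pops = build_muller_table(clades, subsample=500, cutoff_frac=0.05)
        assert set(pops.Identity) == {0}
        # abundance conserved: folded child counts stay in the totals
        totals = pops.groupby("Generation").Population.sum()
        assert totals.loc[500] == 100 and totals.loc[1000] == 100

    def test_population_size_conserved_per_sampled_step(self):
        clades = [
            _clade(0, None, 0, {0: 50, 500: 30, 1000: 20}),
            _clade(1, 0, 100, {500: 40, 1000: 10}),
            _clade(2, 1, 600, {1000: 60}),
        ]
        _, pops = build_muller_table(clades, subsample=500, cutoff_frac=0.05)
        totals = pops.groupby("Generation").Population.sum().to_dict()
        assert totals == {0: 50, 500: 70, 1000: 90}

    def test_orphan_reattaches_to_surviving_ancestor(self):
        clades = [
            _clade(0, None, 0, {0: 100, 500: 50}),
            _clade(1, 0, 100, {500: 1}),           # pruned intermediate
            _clade(2, 1, 200, {500: 49}),          # abundant grandchild
        ]
        edges, _ = build_muller_table(clades, subsample=500, cutoff_frac=0.05)
        assert {(r.Parent, r.Identity) for r in edges.itertuples()} == {(0, 2)}


class TestTopology:
    def test_resource_energy_genotype(self, universe):
        g = Genome([_enzyme(_conv_index(universe, "R -> M2 + 5 E"))])
        assert classify_topology(metabolic_genotype(g, universe), universe) == RESOURCE_ENERGY

    def test_bb_energy_genotype(self, universe):
        g = Genome([_enzyme(_conv_index(universe, "B1 -> M5 + 3 E"))])
        assert classify_topology(metabolic_genotype(g, universe), universe) == BB_ENERGY

    def test_hybrid_genotype(self, universe):
        g = Genome([
            _enzyme(_conv_index(universe, "R -> M2 + 5 E")),
            _enzyme(_conv_index(universe, "B1 -> M5 + 3 E")),
        ])
        assert classify_topology(metabolic_genotype(g, universe), universe) == "hybrid"

    def test_no_energy_reactions(self, universe):
        g = Genome([_enzyme(_conv_index(universe, "M2 + M5 -> B1"))])
        assert classify_topology(metabolic_genotype(g, universe), universe) == NO_ENERGY

    def test_gene_order_invariance(self, universe, rng):
        idx = [_conv_index(universe, "R -> B1 + E"), _conv_index(universe, "2 M2 -> B1")]
        for _ in range(5):
            order = rng.permutation(idx)
            g = Genome([_enzyme(int(i)) for i in order])
            assert classify_topology(metabolic_genotype(g, universe), universe) == RESOURCE_ENERGY

    def test_community_frequency_threshold(self, universe):
        freqs = np.zeros(59)
        freqs[_conv_index(universe, "R -> M2 + 5 E")] = 0.04  # below threshold
        assert classify_topology(freqs, universe) == NO_ENERGY
        freqs[_conv_index(universe, "R -> M2 + 5 E")] = 0.06
        assert classify_topology(freqs, universe) == RESOURCE_ENERGY


class TestCommunityProduction:
    def _cell(self, production):
        st = CellState(volume=0.3, budget=0.1, internal=np.zeros(9),
                       proteins=np.zeros(0), production=production)
        return Cell(Genome([]), st)

    def test_empty_population(self):
        assert community_production_rate([]) == 0.0

    def test_additive_over_cells(self):
        cells = [self._cell(0.5), self._cell(0.2), self._cell(0.3)]
        assert community_production_rate(cells) == pytest.approx(1.0)
        assert community_production_rate(cells[:2]) + community_production_rate(
            cells[2:]
        ) == pytest.approx(1.0)


class TestMatrices:
    def test_gene_frequency_rows_in_unit_interval(self):
        ts = pd.DataFrame({
            "step": [0, 1],
            "freq_0": [1.0, 0.5],
            "freq_1": [0.0, 0.25],
        })
        mat = gene_frequency_matrix([ts, ts])
        assert mat.shape == (4, 2)
        assert ((mat >= 0) & (mat <= 1)).all().all()
        assert mat.index.names == ["run", "step"]

    def test_proteome_rows_sum_to_one_and_pool_copies(self, universe):
        g = Genome([_enzyme(3), _enzyme(3), _enzyme(7)])
        st = CellState(volume=0.3, budget=0.1, internal=np.zeros(9),
                       proteins=np.array([0.2, 0.3, 0.5]))
        mat, zero = proteome_matrix({0: Cell(g, st)}, universe)
        assert not zero[0]
        assert mat.loc[0].sum() == pytest.approx(1.0)
        assert mat.loc[0, "rxn_3"] == pytest.approx(0.5)
        assert mat.loc[0, "rxn_7"] == pytest.approx(0.5)

    def test_zero_protein_cell_flagged(self, universe):
        g = Genome([_enzyme(3)])
        st = CellState(volume=0.3, budget=0.1, internal=np.zeros(9),
                       proteins=np.array([0.0]))
        mat, zero = proteome_matrix({0: Cell(g, st)}, universe)
        assert zero[0]
        assert mat.loc[0].sum() == 0.0


class TestPCA:
    def test_two_clusters_separate_on_pc1(self, rng):
        a = rng.normal(0, 0.05, size=(20, 5)) + np.array([1, 0, 0, 0, 0])
        b = rng.normal(0, 0.05, size=(20, 5)) - np.array([1, 0, 0, 0, 0])
        scores, loadings, var = pca_scores(np.vstack([a, b]), 2)
        assert np.all(scores[:20, 0] * scores[20:, 0].mean() < 0)
        assert var[0] > var[1]

    def test_explained_variance_non_increasing(self, rng):
        x = rng.normal(size=(30, 8))
        _, _, var = pca_scores(x, 8)
        assert all(a >= b - 1e-12 for a, b in zip(var, var[1:]))

    def test_full_reconstruction(self, rng):
        x = rng.normal(size=(12, 6))
        scores, loadings, _ = pca_scores(x, 6)
        xc = x - x.mean(axis=0)
        np.testing.assert_allclose(scores @ loadings, xc, atol=1e-10)

    def test_constant_matrix_zero_variance(self):
        scores, loadings, var = pca_scores(np.ones((5, 4)), 2)
        np.testing.assert_allclose(var, 0.0, atol=1e-20)

    def test_deterministic_sign_convention(self, rng):
        x = rng.normal(size=(15, 4))
        _, l1, _ = pca_scores(x, 2)
        _, l2, _ = pca_scores(x.copy(), 2)
        np.testing.assert_array_equal(l1, l2)
        for row in l1:
            assert row[np.argmax(np.abs(row))] > 0
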