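"""Genes, genomes and the mutation operators."""

import numpy as np
import pytest

from microverse.genome import (
    PARAM_MAX,
    PARAM_MIN,
    Gene,
    Genome,
    MutationParams,
    discover_gene,
    hgt_copy,
    point_mutate_parameter,
    replicate_genome,
    sample_stretch_length,
)


def _enzyme(idx=0, **kw):
    params = dict(promoter=1.0, k_s=0.5, v_max=2.0)
    params.update(kw)
    return Gene("enzyme", conversion_index=idx, **params)


def _transporter(substrate="R", exporting=False, **kw):
    params = dict(promoter=1.0, k_s=0.5, v_max=2.0, k_e=0.3)
    params.update(kw)
    return Gene("transporter", substrate=substrate, exporting=exporting, **params)


def _ten_gene_genome():
    return Genome([_enzyme(i % 43) for i in range(10)])


class TestStretchLength:
    def test_degenerate_geometric_always_one(self, rng):
        assert all(sample_stretch_length(rng, 1.0) == 1 for _ in range(100))

    def test_mean_matches_geometric(self, rng):
        draws = [sample_stretch_length(rng, 0.3) for _ in range(100_000)]
        assert min(draws) >= 1
        # E = 1/0.3 = 3.333, sd of the mean ~ 0.0088
        assert np.mean(draws) == pytest.approx(1 / 0.3, abs=0.04)

    def test_invalid_parameter(self, rng):
        with pytest.raises(ValueError):
            sample_stretch_length(rng, 0.0)


class TestPointMutation:
    def test_parameters_stay_in_range_under_repeated_mutation(self, rng):
        g = _transporter(promoter=8.0, v_max=0.01)
        for _ in range(5000):
            g = point_mutate_parameter(g, rng)
            assert PARAM_MIN <= g.promoter <= PARAM_MAX
            assert PARAM_MIN <= g.k_s <= PARAM_MAX
            assert PARAM_MIN <= g.k_e <= PARAM_MAX
            assert PARAM_MIN <= g.v_max <= PARAM_MAX

    def test_exactly_one_parameter_changes(self, rng):
        g = _transporter()
        for _ in range(200):
            g2 = point_mutate_parameter(g, rng)
            diffs = [
                p for p in g.evolvable_parameters()
                if getattr(g, p) != getattr(g2, p)
            ]
            assert len(diffs) <= 1  # factor exactly 1 has probability ~0

    def test_boolean_flip(self, rng):
        g = _transporter(exporting=False)
        flips = [point_mutate_parameter(g, rng).exporting for _ in range(2000)]
        assert any(flips)  # exporting chosen ~1/5 of the time
        assert all(f in (True, False) for f in flips)


class TestReplicateGenome:
    def test_zero_rates_is_identity(self, rng, universe):
        parent = _ten_gene_genome()
        child, events = replicate_genome(parent, MutationParams.zero(), universe, rng)
        assert events == []
        assert [g.__dict__ for g in child] == [g.__dict__ for g in parent]

    def test_forced_point_mutation_changes_one_parameter(self, rng, universe):
        parent = Genome([_enzyme()])
        params = MutationParams(0, 0, 0, 0, p_point=1.0)
        child, events = replicate_genome(parent, params, universe, rng)
        assert len(events) == 1 and events[0].kind == "point"
        diffs = [
            p for p in ("promoter", "k_s", "v_max")
            if getattr(parent.genes[0], p) != getattr(child.genes[0], p)
        ]
        assert len(diffs) == 1

    def test_point_rate_recovery(self, rng, universe):
        parent = _ten_gene_genome()
        params = MutationParams()
        n_rep, hits = 20_000, 0
        for _ in range(n_rep):
            _, events = replicate_genome(parent, params, universe, rng)
            hits += sum(1 for e in events if e.kind == "point")
        rate = hits / (n_rep * 10)
        # binomial sd at p=0.02, n=2e5 draws: 3.1e-4
        assert rate == pytest.approx(0.02, abs=0.0015)

    @pytest.mark.parametrize("op", ["p_dup", "p_del", "p_inv", "p_transloc"])
    def test_stretch_operators_preserve_outside_genes(self, rng, universe, op):
        parent = _ten_gene_genome()
        params = MutationParams.zero()
        setattr(params, op, 1.0)
        ids = [g.conversion_index for g in parent]
        for _ in range(300):
            child, events = replicate_genome(parent, params, universe, rng)
            assert len(events) == 1
            kind = events[0].kind
            cids = [g.conversion_index for g in child]
            if kind == "duplication":
                start, length = events[0].detail
                assert cids == ids[:start] + ids[start:start + length] + ids[start:]
            elif kind == "deletion":
                start, length = events[0].detail
                assert cids == ids[:start] + ids[start + length:]
            elif kind == "inversion":
                start, length = events[0].detail
                assert cids == ids[:start] + ids[start:start + length][::-1] + ids[start + length:]
            else:  # translocation preserves the multiset and stretch order
                start, length, dest = events[0].detail
                chunk = ids[start:start + length]
                rest = ids[:start] + ids[start + length:]
                assert cids == rest[:dest] + chunk + rest[dest:]

    def test_payload_follows_genes(self, rng, universe):
        parent = _ten_gene_genome()
        payload = list(range(10))
        params = MutationParams(p_dup=0.5, p_del=0.5, p_inv=0.5, p_transloc=0.5,
                                p_point=0.0)
        for _ in range(200):
            child, _, pay = replicate_genome(parent, params, universe, rng, payload=payload)
            assert len(pay) == len(child)
            for gene, tag in zip(child, pay):
                assert gene.conversion_index == parent.genes[tag].conversion_index

    def test_event_stream_detects_genotype_change(self, rng, universe):
        """Without deletions or direction flips the genotype cannot shrink or move."""
        from microverse.analysis import metabolic_genotype

        parent = _ten_gene_genome()
        params = MutationParams(p_dup=0.2, p_del=0.2, p_inv=0.2, p_transloc=0.2,
                                p_point=0.2)
        for _ in range(300):
            child, events = replicate_genome(parent, params, universe, rng)
            may_change = any(
                e.kind == "deletion" or (e.kind == "point" and e.detail[1] == "exporting")
                for e in events
            )
            if not may_change:
                assert metabolic_genotype(child, universe) == metabolic_genotype(
                    parent, universe
                )


class TestDiscoveryAndHGT:
    def test_discovery_covers_all_reactions(self, rng, universe):
        seen = {discover_gene(universe, rng).reaction_index(universe) for _ in range(10_000)}
        assert seen == set(range(59))

    def test_discovery_parameters_in_range(self, rng, universe):
        for _ in range(500):
            g = discover_gene(universe, rng)
            assert PARAM_MIN <= g.promoter <= PARAM_MAX
            assert PARAM_MIN <= g.v_max <= PARAM_MAX
            if g.gtype == "transporter":
                assert PARAM_MIN <= g.k_e <= PARAM_MAX
                assert g.exporting in (True, False)

    def test_hgt_appends_one_copied_gene(self, rng):
        donor = Genome([_enzyme(7, promoter=3.3)])
        recipient = Genome([_enzyme(1), _enzyme(2)])
        child, event = hgt_copy(recipient, donor, rng)
        assert event.kind == "hgt"
        assert len(child) == 3
        new = next(g for g in child if g.conversion_index == 7)
        assert new.promoter == 3.3
        assert new is not donor.genes[0]  # deep copy

    def test_hgt_empty_donor_is_noop(self, rng):
        recipient = Genome([_enzyme(1)])
        child, event = hgt_copy(recipient, Genome([]), rng)
        assert event.kind == "hgt_noop"
        assert len(child) == 1

    def test_hgt_donor_gene_choice_uniform(self, rng):
        donor = Genome([_enzyme(i) for i in range(5)])
        counts = np.zeros(5)
        n = 10_000
        for _ in range(n):
            _, event = hgt_copy(Genome([]), donor, rng)
            counts[event.detail[0]] += 1
        # chi-square against uniform, 4 dof; 0.999 quantile ~ 18.5
        chi2 = ((counts - n / 5) ** 2 / (n / 5)).sum()
        assert chi2 < 18.5


def test_gene_serialization_round_trip(universe):
    genes = [_enzyme(17, promoter=2.5), _transporter("B1", exporting=True)]
    genome = Genome(genes)
    back = Genome.from_list(genome.to_list(universe), universe)
    assert [g.__dict__ for g in back] == [g.__dict__ for g in genome]


def test_mutation_params_validate_range():
    with pytest.raises(ValueError):
        MutationParams(p_dup=1.5)
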