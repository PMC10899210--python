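import numpy as np
import pytest

from dgnet.interactome import GeneUniverse, SeedGeneSet, build_interactome, overlap_stats
from dgnet.io_formats import read_expression_long, read_gda_table, read_gmt, read_ppi_table
from dgnet.synthetic import (
    SyntheticConfig,
    archetype_active_coordinates,
    gen_brain_reference,
    gen_expression,
    gen_gda_table,
    gen_ppi_network,
    gen_two_block_profiles,
    write_bundle,
)


SMALL = dict(n_genes=300, community_size=30, planted_module_size=8)


class TestConfig:
    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SyntheticConfig(archetype_fractions=(0.5, 0.5, 0.5, 0.5))

    def test_infeasible_sizes_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            SyntheticConfig(n_genes=100, community_size=50)

    def test_archetype_geometry_covers_all_coordinates(self):
        cfg = SyntheticConfig(**SMALL)
        actives = archetype_active_coordinates(cfg)
        assert set(actives) == {1, 2, 3, 4}
        # archetype 1 is temporally uniform; 4 is strictly prenatal
        stages1 = {s for _, s in actives[1]}
        assert stages1 == set(cfg.stages)
        assert {s for _, s in actives[4]} == cfg.prenatal_stages


class TestPPINetwork:
    def test_same_seed_identical_edge_list(self):
        cfg = SyntheticConfig(rng_seed=4, **SMALL)
        e1, t1 = gen_ppi_network(cfg)
        e2, t2 = gen_ppi_network(cfg)
        assert e1 == e2 and t1.seeds == t2.seeds

    def test_planted_overlap_is_strongly_significant(self):
        hits = 0
        for seed in range(5):
            cfg = SyntheticConfig(rng_seed=seed, planted_overlap_fraction=0.5)
            edges, truth = gen_ppi_network(cfg)
            inters = [
                build_interactome(SeedGeneSet(d, truth.seeds[d], len(truth.seeds[d])), edges)
                for d in cfg.disease_ids
            ]
            r = overlap_stats(inters[0], inters[1], GeneUniverse.from_edges(edges))
            hits += r.p_value < 1e-10
        assert hits >= 4

    def test_zero_planted_overlap_is_chance_level(self):
        small_ps = 0
        for seed in range(10):
            cfg = SyntheticConfig(rng_seed=seed, planted_overlap_fraction=0.0)
            edges, truth = gen_ppi_network(cfg)
            inters = [
                build_interactome(SeedGeneSet(d, truth.seeds[d], len(truth.seeds[d])), edges)
                for d in cfg.disease_ids
            ]
            r = overlap_stats(inters[0], inters[1], GeneUniverse.from_edges(edges))
            small_ps += r.p_value < 0.05
        assert small_ps <= 2

    def test_affiliations_cover_communities(self):
        cfg = SyntheticConfig(rng_seed=0, **SMALL)
        _, truth = gen_ppi_network(cfg)
        counts = {a: sum(v == a for v in truth.affiliation.values())
                  for a in ("PD-unique", "SZ-unique", "shared", "background")}
        assert counts["PD-unique"] == counts["SZ-unique"] == counts["shared"] == 30
        assert counts["background"] == 300 - 90


class TestGDATable:
    def test_top_k_selection_recovers_planted_seeds(self):
        from dgnet.interactome import select_top_seeds

        cfg = SyntheticConfig(rng_seed=2, **SMALL)
        _, truth = gen_ppi_network(cfg)
        records = gen_gda_table(cfg, truth)
        for d in cfg.disease_ids:
            sel = select_top_seeds(records, d, cfg.n_seeds_per_disease)
            assert sorted(sel.genes) == truth.seeds[d]

    def test_tie_at_cut_exists_and_is_resolved_lexicographically(self):
        cfg = SyntheticConfig(rng_seed=2, **SMALL)
        _, truth = gen_ppi_network(cfg)
        records = gen_gda_table(cfg, truth)
        d = cfg.disease_ids[0]
        mine = [r for r in records if r.disease_id == d]
        tie_score = 0.70
        tied = sorted(r.gene for r in mine if r.gda_score == tie_score)
        assert len(tied) == 3  # two seeds and one decoy share the cut score
        assert tied[-1] not in truth.seeds[d]
        assert set(tied[:2]) <= set(truth.seeds[d])

    def test_row_order_does_not_change_selection(self, rng):
        from dgnet.interactome import select_top_seeds

        cfg = SyntheticConfig(rng_seed=2, **SMALL)
        _, truth = gen_ppi_network(cfg)
        records = gen_gda_table(cfg, truth)
        shuffled = [records[i] for i in rng.permutation(len(records))]
        d = cfg.disease_ids[1]
        assert (select_top_seeds(records, d, 20).genes
                == select_top_seeds(shuffled, d, 20).genes)


class TestExpression:
    def test_same_seed_identical_records(self):
        cfg = SyntheticConfig(rng_seed=5, **SMALL)
        r1, _ = gen_expression(cfg)
        r2, _ = gen_expression(cfg)
        assert r1 == r2

    def test_noiseless_profiles_are_archetype_exact(self):
        cfg = SyntheticConfig(rng_seed=1, noise_sd=0.0, dropout_rate=0.0, **SMALL)
        records, truth = gen_expression(cfg)
        actives = archetype_active_coordinates(cfg)
        by_gene_coord = {}
        for r in records:
            by_gene_coord.setdefault((r.gene, r.region, r.stage), []).append(r.rpkm)
        for (g, region, stage), vals in list(by_gene_coord.items())[:2000]:
            mu = 2.5 if (region, stage) in actives[truth.archetype[g]] else 0.5
            assert vals == pytest.approx([10.0**mu] * len(vals))

    def test_affiliation_coupled_to_archetype(self):
        cfg = SyntheticConfig(rng_seed=3, **SMALL)
        _, truth = gen_expression(cfg)
        from dgnet.synthetic import ARCHETYPE_AFFILIATION

        match = np.mean([
            truth.affiliation[g] == ARCHETYPE_AFFILIATION[a]
            for g, a in truth.archetype.items()
        ])
        assert 0.7 < match < 0.95  # purity 0.8 plus chance matches

    def test_dropout_rate_realised(self):
        cfg = SyntheticConfig(rng_seed=4, dropout_rate=0.2, **SMALL)
        records, _ = gen_expression(cfg)
        frac0 = np.mean([r.rpkm == 0.0 for r in records])
        assert 0.17 < frac0 < 0.23


class TestTwoBlockProfiles:
    def test_planted_block_structure(self):
        prof, blocks = gen_two_block_profiles(0)
        assert prof.shape == (20, 4)
        b0 = [c for c, b in blocks.items() if b == 0]
        b1 = [c for c, b in blocks.items() if b == 1]
        assert (prof.iloc[:10][b0].to_numpy() > prof.iloc[:10][b1].to_numpy()).all()

    def test_deterministic_under_seed(self):
        p1, _ = gen_two_block_profiles(3, noise_sd=0.5)
        p2, _ = gen_two_block_profiles(3, noise_sd=0.5)
        assert p1.equals(p2)


class TestBundle:
    def test_bundle_round_trips_through_readers(self, tmp_path, caplog):
        cfg = SyntheticConfig(rng_seed=6, **SMALL)
        with caplog.at_level("WARNING"):
            paths = write_bundle(cfg, tmp_path / "bundle")
            edges = read_ppi_table(paths["ppi"])
            gda = read_gda_table(paths["gda"])
            records = read_expression_long(paths["expression"])
            sets = read_gmt(paths["gene_sets"])
        assert not caplog.records  # readers accept every emitted file silently
        assert len(edges) > 0 and len(gda) > 0 and len(records) > 0 and len(sets) > 0

    def test_bundle_byte_identical_under_seed(self, tmp_path):
        cfg = SyntheticConfig(rng_seed=6, **SMALL)
        p1 = write_bundle(cfg, tmp_path / "b1")
        p2 = write_bundle(cfg, tmp_path / "b2")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes()

    def test_brain_reference_fraction(self):
        cfg = SyntheticConfig(rng_seed=7, brain_expressed_fraction=0.5, **SMALL)
        ref = gen_brain_reference(cfg)
        frac = np.mean([v > 1.0 for v in ref.values()])
        assert 0.4 < frac < 0.6
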