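"""Generator contracts: determinism, CTMC limits and expectations,
cassette layout, annotation planting, round trips."""

import filecmp
import json

import numpy as np
import pytest

from paleomem.io_formats import (
    read_fasta,
    read_gene_table,
    read_gene_tables,
    read_lineage_map,
    read_orthology,
    read_tree,
)
from paleomem.membrane import predict_tm_segments
from paleomem.neighborhood import predict_operons
from paleomem.funnel import filter_hypothetical
from paleomem.simulate import (
    SimConfig,
    expected_leaf_presence,
    generate_scenario,
    simulate_gene_content,
    simulate_tree,
    write_scenario,
)


class TestConfig:
    def test_probability_bounds_validated(self):
        with pytest.raises(ValueError, match="cassette_retention"):
            SimConfig(cassette_retention=1.4)

    def test_empty_vocabulary_rejected(self):
        with pytest.raises(ValueError, match="vocabulary"):
            SimConfig(annotation_vocabulary=())


class TestTree:
    @pytest.mark.parametrize("shape", ["balanced", "random"])
    def test_ultrametric_with_requested_height(self, shape):
        cfg = SimConfig(n_genomes=14, n_lineages=4, tree_shape=shape)
        tree = simulate_tree(cfg, np.random.default_rng(2))
        depths = tree.tree.calc_node_root_distances(
            return_leaf_distances_only=True
        )
        assert np.allclose(depths, cfg.tree_height, atol=1e-9)

    def test_lineages_cover_all_genomes(self):
        cfg = SimConfig(n_genomes=20, n_lineages=5)
        tree = simulate_tree(cfg, np.random.default_rng(0))
        assert sorted(tree.lineage_map) == sorted(tree.leaf_ids)
        assert len(set(tree.lineage_map.values())) == 5


class TestGeneContent:
    def test_no_loss_full_root_means_all_present(self):
        cfg = SimConfig(
            n_genomes=8, n_lineages=2, n_families=50,
            fraction_root_present=1.0, loss_rate=0.0, gain_rate=0.1,
            n_cassettes=1,
        )
        _, presence, roots = simulate_gene_content(cfg, np.random.default_rng(1))
        assert presence.values.all()
        assert roots.all()

    def test_no_gain_means_no_de_novo_families(self):
        cfg = SimConfig(
            n_genomes=8, n_lineages=2, n_families=200, gain_rate=0.0,
            loss_rate=0.3, n_cassettes=1,
        )
        _, presence, roots = simulate_gene_content(cfg, np.random.default_rng(2))
        absent_at_root = presence.loc[roots == 0]
        assert not absent_at_root.values.any()

    def test_leaf_presence_matches_analytic_expectation(self):
        """Empirical per-leaf presence within 3 Monte-Carlo s.e. of the
        CTMC's closed-form expectation."""
        cfg = SimConfig(n_genomes=10, n_lineages=2, n_families=2000,
                        n_cassettes=1)
        rng = np.random.default_rng(3)
        tree, presence, _ = simulate_gene_content(cfg, rng)
        expected = expected_leaf_presence(cfg, tree)
        for gid in presence.columns:
            p = expected[gid]
            se = np.sqrt(p * (1 - p) / cfg.n_families)
            assert abs(presence[gid].mean() - p) <= 3 * se


class TestGeneOrders:
    def test_full_retention_keeps_cassettes_contiguous(self):
        cfg = SimConfig(
            n_genomes=10, n_lineages=2, n_families=200, n_cassettes=2,
            cassette_retention=1.0,
        )
        sc = generate_scenario(cfg, seed=4, with_proteins=False)
        for cas in sc.cassettes:
            for gid, table in sc.tables.items():
                if not all(sc.presence.at[f, gid] for f in cas):
                    continue
                fams = [
                    sc.orthology.family_of(g.protein_id) for g in table
                ]
                positions = sorted(
                    i for i, f in enumerate(fams) if f in set(cas)
                )
                assert positions[-1] - positions[0] == len(cas) - 1

    def test_cassettes_fall_in_single_operon(self):
        """Intra-cassette gaps stay below the operon threshold, so a
        retained cassette is always co-transcribed in the prediction."""
        cfg = SimConfig(
            n_genomes=6, n_lineages=2, n_families=150, n_cassettes=2,
            cassette_retention=1.0,
        )
        sc = generate_scenario(cfg, seed=5, with_proteins=False)
        for cas in sc.cassettes:
            for gid, table in sc.tables.items():
                if not all(sc.presence.at[f, gid] for f in cas):
                    continue
                operons = predict_operons(table, max_gap=100)
                fams_by_operon = [
                    {sc.orthology.family_of(g.protein_id) for g in op.genes}
                    for op in operons
                ]
                assert any(set(cas) <= fams for fams in fams_by_operon)


class TestProteins:
    def test_soluble_families_have_no_tm_window(self, small_scenario):
        """Families with true count 0 and no signal never reach the
        hydropathy threshold."""
        roles = small_scenario.roles
        soluble = roles.index[(roles.true_tm == 0) & (~roles.signal)]
        checked = 0
        for fam in soluble:
            for pid in small_scenario.members.get(fam, []):
                assert predict_tm_segments(small_scenario.proteins[pid]) == []
                checked += 1
        assert checked > 50

    def test_tm_count_recovered_per_member(self, small_scenario):
        """Member TM counts are recovered exactly for >= 90% of members
        of multi-TM families."""
        from paleomem.membrane import predict_membrane

        roles = small_scenario.roles
        fams = roles.index[roles.membrane]
        hits = total = 0
        for fam in fams:
            for pid in small_scenario.members.get(fam, []):
                call = predict_membrane(pid, small_scenario.proteins[pid])
                planted = small_scenario.true_segments[pid]
                n_true = len(planted) - (1 if roles.loc[fam, "signal"] else 0)
                hits += call.effective_tm_count == n_true
                total += 1
        assert total > 100
        assert hits / total >= 0.90

    def test_signal_families_flagged(self, small_scenario):
        from paleomem.membrane import predict_membrane

        roles = small_scenario.roles
        fams = roles.index[roles.signal]
        flagged = total = 0
        for fam in fams:
            for pid in small_scenario.members.get(fam, []):
                flagged += predict_membrane(
                    pid, small_scenario.proteins[pid]
                ).signal_peptide
                total += 1
        assert total > 30
        assert flagged / total >= 0.80


class TestAnnotations:
    def test_zero_noise_exact_recovery(self):
        cfg = SimConfig(
            n_genomes=8, n_lineages=2, n_families=150, annotation_noise=0.0,
            n_cassettes=1,
        )
        sc = generate_scenario(cfg, seed=6, with_proteins=False)
        family_anns = {
            fam: [sc.annotations[p] for p in pids]
            for fam, pids in sc.members.items()
        }
        kept = set(
            filter_hypothetical(sorted(family_anns), family_anns)
        )
        truth = {
            f for f in family_anns
            if sc.roles.loc[f, "hypothetical"]
        }
        assert kept == truth

    def test_heavy_noise_still_rejects_most_informative_families(self):
        """At noise 0.4 most non-hypothetical families keep an informative
        majority; the flip rate is governed by the binomial upper tail
        P(Binom(n, 0.4) > n/2), which is 10-18% at desk-scale family
        sizes, so "rejected" can only hold for the large majority."""
        cfg = SimConfig(
            n_genomes=12, n_lineages=3, n_families=300, annotation_noise=0.4,
            n_cassettes=1,
        )
        sc = generate_scenario(cfg, seed=7, with_proteins=False)
        family_anns = {
            fam: [sc.annotations[p] for p in pids]
            for fam, pids in sc.members.items()
            if not sc.roles.loc[fam, "hypothetical"] and len(pids) >= 6
        }
        kept = filter_hypothetical(sorted(family_anns), family_anns)
        assert len(kept) / max(1, len(family_anns)) <= 0.25


class TestWriteScenario:
    def test_same_seed_byte_identical(self, tmp_path, small_config):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_scenario(small_config, d1, seed=9)
        write_scenario(small_config, d2, seed=9)
        for rel in (
            "gene_tables.tsv", "proteins.faa", "orthology.tsv", "tree.nwk",
            "lineages.tsv", "truth.json", "config.json",
        ):
            assert filecmp.cmp(d1 / rel, d2 / rel, shallow=False), rel
        for gff in sorted((d1 / "genomes").glob("*.gff3")):
            assert filecmp.cmp(gff, d2 / "genomes" / gff.name, shallow=False)

    def test_bundle_parses_back_consistently(self, tmp_path, small_config):
        sc = write_scenario(small_config, tmp_path / "s", seed=10)
        outdir = tmp_path / "s"
        tables = read_gene_tables(outdir / "gene_tables.tsv")
        assert set(tables) == set(sc.tables)
        for gid, table in tables.items():
            gff = read_gene_table(outdir / "genomes" / f"{gid}.gff3", "gff3")
            assert gff.records == table.records
        assert dict(read_orthology(outdir / "orthology.tsv").items()) == dict(
            sc.orthology.items()
        )
        assert read_fasta(outdir / "proteins.faa") == sc.proteins
        tree = read_tree(outdir / "tree.nwk")
        assert sorted(tree.leaf_ids) == sorted(sc.tables)
        assert read_lineage_map(outdir / "lineages.tsv") == sc.tree.lineage_map
        truth = json.loads((outdir / "truth.json").read_text())
        assert truth["n_qualifying"] == len(sc.qualifying_families)

    def test_single_genome_bundle_valid(self, tmp_path):
        cfg = SimConfig(
            n_genomes=1, n_lineages=1, n_families=40, n_cassettes=0,
            fraction_root_present=0.9,
        )
        sc = write_scenario(cfg, tmp_path / "tiny", seed=11)
        assert len(sc.tables) == 1
        assert read_tree(tmp_path / "tiny" / "tree.nwk").leaf_ids == ["G1"]
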