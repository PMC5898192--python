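"""Operons, neighbor windows, conservation scores, permutation null,
cassette mining."""

import numpy as np
import pytest

from paleomem.io_formats import GeneRecord, GenomeTable, OrthologyMap
from paleomem.neighborhood import (
    find_cassettes,
    gene_neighbors,
    partner_frequencies,
    permutation_pvalue,
    predict_operons,
)


def make_genome(genome_id, families, gaps=None, strands=None, replicon="chr"):
    """Build a genome with the given family order; gaps[i] precedes gene i+1."""
    n = len(families)
    gaps = gaps or [50] * (n - 1)
    strands = strands or ["+"] * n
    records = []
    orth = {}
    pos = 0
    for i, fam in enumerate(families):
        pid = f"{genome_id}_p{i}"
        records.append(
            GeneRecord(
                genome_id=genome_id,
                replicon_id=replicon,
                start=pos,
                end=pos + 900,
                strand=strands[i],
                protein_id=pid,
            )
        )
        orth[pid] = fam
        pos += 900 + (gaps[i] if i < len(gaps) else 0)
    return GenomeTable(genome_id, records), orth


class TestOperons:
    def test_small_gap_merges(self):
        table, _ = make_genome("G", ["A", "B"], gaps=[50])
        operons = predict_operons(table, max_gap=100)
        assert len(operons) == 1 and len(operons[0]) == 2

    def test_boundary_gap_101_splits(self):
        table, _ = make_genome("G", ["A", "B"], gaps=[101])
        assert len(predict_operons(table, max_gap=100)) == 2

    def test_strand_flip_always_splits(self):
        table, _ = make_genome("G", ["A", "B"], gaps=[10], strands=["+", "-"])
        assert len(predict_operons(table)) == 2

    def test_partition_covers_every_gene_once(self, small_scenario):
        for table in small_scenario.tables.values():
            operons = predict_operons(table)
            pids = [g.protein_id for op in operons for g in op.genes]
            assert sorted(pids) == sorted(g.protein_id for g in table)


class TestGeneNeighbors:
    def test_single_gene_replicon(self):
        table, _ = make_genome("G", ["A"])
        assert gene_neighbors("G_p0", table) == []

    def test_replicon_end_one_sided(self):
        table, _ = make_genome("G", list("ABCDEFG"))
        left_end = gene_neighbors("G_p0", table, k=3)
        assert [g.protein_id for g in left_end] == ["G_p1", "G_p2", "G_p3"]

    def test_middle_seed_k5_returns_all_ten(self):
        table, _ = make_genome("G", [f"F{i}" for i in range(11)])
        neighbors = gene_neighbors("G_p5", table, k=5)
        assert len(neighbors) == 10
        assert "G_p5" not in [g.protein_id for g in neighbors]

    def test_unknown_gene_error(self):
        table, _ = make_genome("G", ["A"])
        with pytest.raises(KeyError):
            gene_neighbors("nope", table)


def _pair_scenario(n_genomes=20, n_adjacent=18, filler=30):
    """Genomes all carrying SEED and PART; adjacent in the first n_adjacent."""
    tables, orth = [], {}
    rng = np.random.default_rng(0)
    for i in range(n_genomes):
        fams = [f"X{j}" for j in range(filler)]
        if i < n_adjacent:
            at = int(rng.integers(0, filler - 1))
            fams[at:at] = ["SEED", "PART"]
        else:
            fams.insert(2, "SEED")
            fams.insert(filler - 2, "PART")
        table, o = make_genome(f"G{i:02d}", fams)
        tables.append(table)
        orth.update(o)
    return tables, OrthologyMap(orth)


class TestPartnerFrequencies:
    def test_planted_pair_scores_point_nine(self):
        tables, orth = _pair_scenario(20, 18)
        df = partner_frequencies("SEED", tables, orth, k=5)
        row = df[df.partner_family == "PART"].iloc[0]
        assert row.n_genomes_both == 20
        assert row.n_genomes_adjacent == 18
        assert row.score == pytest.approx(0.9)

    def test_partner_out_of_window_absent(self):
        tables, orth = _pair_scenario(20, 0)
        df = partner_frequencies("SEED", tables, orth, k=5)
        assert "PART" not in set(df.partner_family)

    def test_paralogs_count_genome_once(self):
        table, orth = make_genome("G1", ["S", "A", "S"])
        t2, o2 = make_genome("G2", ["S", "A"])
        t3, o3 = make_genome("G3", ["S", "A"])
        df = partner_frequencies(
            "S", [table, t2, t3], OrthologyMap({**orth, **o2, **o3}),
            k=5, min_genomes_both=1,
        )
        row = df[df.partner_family == "A"].iloc[0]
        assert row.n_genomes_adjacent == 3

    def test_seed_absent_everywhere_error(self):
        tables, orth = _pair_scenario(3, 3)
        with pytest.raises(ValueError, match="absent"):
            partner_frequencies("NOPE", tables, orth)

    def test_score_monotone_in_window(self):
        tables, orth = _pair_scenario(20, 12)
        wide = partner_frequencies("SEED", tables, orth, k=8)
        narrow = partner_frequencies("SEED", tables, orth, k=2)
        wide_scores = dict(zip(wide.partner_family, wide.score))
        for fam, s_narrow in zip(narrow.partner_family, narrow.score):
            assert s_narrow <= wide_scores[fam] + 1e-12

    def test_adjacency_never_exceeds_copresence(self, small_scenario):
        seed = small_scenario.cassettes[0][0]
        df = partner_frequencies(
            seed, list(small_scenario.tables.values()), small_scenario.orthology
        )
        assert (df.n_genomes_adjacent <= df.n_genomes_both).all()
        assert ((df.score >= 0) & (df.score <= 1)).all()


class TestPermutationPValue:
    def test_planted_pair_significant(self):
        tables, orth = _pair_scenario(20, 18)
        p = permutation_pvalue("SEED", "PART", tables, orth, n_perm=199, rng=1)
        assert p <= 0.05

    def test_reproducible_given_seed(self):
        tables, orth = _pair_scenario(10, 8)
        p1 = permutation_pvalue("SEED", "PART", tables, orth, n_perm=99, rng=5)
        p2 = permutation_pvalue("SEED", "PART", tables, orth, n_perm=99, rng=5)
        assert p1 == p2

    def test_self_pair_rejected(self):
        tables, orth = _pair_scenario(5, 5)
        with pytest.raises(ValueError, match="itself"):
            permutation_pvalue("SEED", "SEED", tables, orth)

    def test_low_resolution_rejected(self):
        tables, orth = _pair_scenario(5, 5)
        with pytest.raises(ValueError, match="at least 19"):
            permutation_pvalue("SEED", "PART", tables, orth, n_perm=10)

    def test_null_calibration_valid(self):
        """Under shuffled gene orders P(p <= alpha) stays near or below alpha."""
        rng = np.random.default_rng(12)
        pvals = []
        for rep in range(60):
            tables, orth = [], {}
            for i in range(8):
                fams = [f"X{i}_{j}" for j in range(28)] + ["SEED", "PART"]
                order = rng.permutation(len(fams))
                table, o = make_genome(f"G{i}", [fams[j] for j in order])
                tables.append(table)
                orth.update(o)
            pvals.append(
                permutation_pvalue(
                    "SEED", "PART", tables, OrthologyMap(orth),
                    n_perm=49, rng=int(rng.integers(2**31)),
                )
            )
        pvals = np.array(pvals)
        assert (pvals <= 0.05).mean() <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 60)


class TestFindCassettes:
    def _cassette_tables(self, n_with=5, n_without=2):
        tables, orth = [], {}
        rng = np.random.default_rng(3)
        for i in range(n_with + n_without):
            fams = [f"X{j}" for j in range(20)]
            if i < n_with:
                at = int(rng.integers(0, 18))
                fams[at:at] = ["CA", "CB", "CC"]
            table, o = make_genome(f"G{i}", fams)
            tables.append(table)
            orth.update(o)
        return tables, OrthologyMap(orth)

    def test_planted_cassette_recovered(self):
        tables, orth = self._cassette_tables(n_with=5)
        cassettes = find_cassettes("CB", tables, orth, min_support=3)
        assert cassettes
        assert cassettes[0].families == ("CA", "CB", "CC")
        assert cassettes[0].support == 5

    def test_below_min_support_excluded(self):
        tables, orth = self._cassette_tables(n_with=2, n_without=4)
        cassettes = find_cassettes("CB", tables, orth, min_support=3)
        assert all(set(c.families) != {"CA", "CB", "CC"} for c in cassettes)

    def test_nested_subsets_not_reported(self):
        tables, orth = self._cassette_tables(n_with=6)
        cassettes = find_cassettes("CB", tables, orth, min_support=3)
        tops = [set(c.families) for c in cassettes]
        assert {"CA", "CB", "CC"} in tops
        # pairs inside the planted triple share its support -> dominated
        assert {"CA", "CB"} not in tops
        assert {"CB", "CC"} not in tops

    def test_orientation_insensitive(self):
        tables, orth = [], {}
        for i, order in enumerate(
            [["CA", "CB", "CC"], ["CC", "CB", "CA"], ["CB", "CA", "CC"]]
        ):
            # flanks differ per genome so only the planted triple recurs
            table, o = make_genome(f"G{i}", [f"X{i}"] + order + [f"Y{i}"])
            tables.append(table)
            orth.update(o)
        cassettes = find_cassettes("CB", tables, OrthologyMap(orth), min_support=3)
        assert any(set(c.families) == {"CA", "CB", "CC"} for c in cassettes)
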