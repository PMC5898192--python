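"""Gene-context analysis: operons, neighbors, conservation, cassettes.

The guilt-by-association machinery. Given a seed family, the module
enumerates its genomic neighbors across genomes, scores how often a
partner family sits within a window of k genes of a seed gene relative
to how often the two families co-occur at all, attaches a permutation
p-value (null: gene order shuffled independently within each replicon,
which preserves gene content and replicon sizes), and mines contiguous
multi-family cassettes recurring across genomes.

Counting is genome-level throughout: a genome contributes at most one
adjacency regardless of paralog number, and the number of distinct
lineages among adjacent genomes is reported to expose phylogenetic
redundancy of the support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneRecord, GenomeTable, OrthologyMap

logger = logging.getLogger(__name__)

PARTNER_COLUMNS = (
    "partner_family",
    "n_genomes_adjacent",
    "n_genomes_both",
    "score",
    "n_lineages_adjacent",
)


@dataclass(frozen=True)
class Operon:
    """Run of adjacent same-strand genes with short intergenic gaps."""

    genome_id: str
    replicon_id: str
    strand: str
    genes: tuple[GeneRecord, ...]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class Cassette:
    """Family set recurrently found as a contiguous run across genomes.

    ``families`` is stored in lexicographic order; matching is order- and
    orientation-insensitive.
    """

    families: tuple[str, ...]
    genomes: tuple[str, ...]

    @property
    def support(self) -> int:
        return len(self.genomes)


def predict_operons(table: GenomeTable, max_gap: int = 100) -> list[Operon]:
    """Partition each replicon into same-strand runs split at gaps > max_gap.

    Every gene ends up in exactly one operon (singletons allowed).
    """
    operons: list[Operon] = []
    for replicon, genes in table.by_replicon().items():
        current: list[GeneRecord] = []
        for gene in genes:
            if current and (
                gene.strand != current[-1].strand
                or gene.start - current[-1].end > max_gap
            ):
                operons.append(
                    Operon(table.genome_id, replicon, current[0].strand, tuple(current))
                )
                current = []
            current.append(gene)
        if current:
            operons.append(
                Operon(table.genome_id, replicon, current[0].strand, tuple(current))
            )
    return operons


def gene_neighbors(
    protein_id: str, table: GenomeTable, k: int = 5
) -> list[GeneRecord]:
    """Up to k genes on each side of a gene on its replicon, seed excluded."""
    for replicon, genes in table.by_replicon().items():
        for pos, gene in enumerate(genes):
            if gene.protein_id == protein_id:
                lo = max(0, pos - k)
                hi = min(len(genes), pos + k + 1)
                return [g for g in genes[lo:hi] if g.protein_id != protein_id]
    raise KeyError(
        f"protein {protein_id!r} not found in genome {table.genome_id!r}"
    )


def _family_layout(
    table: GenomeTable, orthology: OrthologyMap
) -> list[list[str]]:
    """Per-replicon ordered family lists for one genome."""
    return [
        [orthology.family_of(g.protein_id) for g in genes]
        for genes in table.by_replicon().values()
    ]


def _adjacent_families(
    layout: Sequence[Sequence[str]], seed_family: str, k: int
) -> set[str]:
    """Families within k positions of any seed gene, seed family excluded."""
    found: set[str] = set()
    for fams in layout:
        for pos, fam in enumerate(fams):
            if fam != seed_family:
                continue
            lo = max(0, pos - k)
            for other in fams[lo : pos + k + 1]:
                if other != seed_family:
                    found.add(other)
    return found


def partner_frequencies(
    seed_family: str,
    tables: Iterable[GenomeTable],
    orthology: OrthologyMap,
    k: int = 5,
    lineage_map: Mapping[str, str] | None = None,
    min_genomes_both: int = 3,
) -> pd.DataFrame:
    """Cross-genome neighborhood partner table for a seed family.

    For each partner family: ``n_genomes_adjacent`` counts genomes where
    at least one seed gene has a partner gene among its k neighbors,
    ``n_genomes_both`` counts genomes carrying both families, and
    ``score = n_genomes_adjacent / n_genomes_both``. Sorted by
    descending score, then adjacency support. The seed family itself is
    not a row.

    ``min_genomes_both`` floors the co-presence support: with a handful
    of co-present genomes the ratio is dominated by chance adjacency (a
    family seen once, once next to the seed, scores a meaningless 1.0),
    so partners co-present in fewer genomes are not reported. Set to 1
    to disable.
    """
    tables = list(tables)
    adjacency: dict[str, set[str]] = {}
    family_presence: dict[str, set[str]] = {}
    seed_genomes: set[str] = set()
    for table in tables:
        layout = _family_layout(table, orthology)
        fams_here = {f for fams in layout for f in fams}
        for fam in fams_here:
            family_presence.setdefault(fam, set()).add(table.genome_id)
        if seed_family not in fams_here:
            continue
        seed_genomes.add(table.genome_id)
        for fam in _adjacent_families(layout, seed_family, k):
            adjacency.setdefault(fam, set()).add(table.genome_id)
    if not seed_genomes:
        raise ValueError(f"seed family {seed_family!r} absent from all genomes")
    rows = []
    for fam, adj_genomes in adjacency.items():
        both = family_presence[fam] & seed_genomes
        if len(both) < min_genomes_both:
            continue
        lineages = (
            len({lineage_map[g] for g in adj_genomes}) if lineage_map else 0
        )
        rows.append(
            (fam, len(adj_genomes), len(both), len(adj_genomes) / len(both), lineages)
        )
    df = pd.DataFrame(rows, columns=PARTNER_COLUMNS)
    df = df.sort_values(
        ["score", "n_genomes_adjacent", "partner_family"],
        ascending=[False, False, True],
    ).reset_index(drop=True)
    df.attrs["seed_family"] = seed_family
    df.attrs["k"] = k
    df.attrs["n_seed_genomes"] = len(seed_genomes)
    return df


def _pair_adjacency_count(
    positions: Sequence[tuple[str, np.ndarray, np.ndarray, int]], k: int
) -> int:
    """Genomes where any seed/partner position pair is within k."""
    genomes: set[str] = set()
    for genome_id, seed_pos, partner_pos, _size in positions:
        if genome_id in genomes or seed_pos.size == 0 or partner_pos.size == 0:
            continue
        diff = np.abs(seed_pos[:, None] - partner_pos[None, :])
        if diff.min() <= k:
            genomes.add(genome_id)
    return len(genomes)


def permutation_pvalue(
    seed_family: str,
    partner_family: str,
    tables: Iterable[GenomeTable],
    orthology: OrthologyMap,
    k: int = 5,
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Permutation p-value for the seed-partner adjacency count.

    Null: gene order permuted independently within each replicon of each
    genome; the statistic is the number of genomes with at least one
    within-window seed/partner pair. p = (1 + #{null >= observed}) /
    (n_perm + 1). Reproducible given an integer seed or Generator.
    """
    if partner_family == seed_family:
        raise ValueError("p-value undefined for a family against itself")
    if n_perm < 19:
        raise ValueError(f"n_perm must be at least 19, got {n_perm}")
    rng = np.random.default_rng(rng)
    # per-replicon (genome, seed positions, partner positions, n genes)
    layout_positions: list[tuple[str, np.ndarray, np.ndarray, int]] = []
    seed_seen = partner_seen = False
    for table in list(tables):
        for fams in _family_layout(table, orthology):
            arr = np.array(fams)
            seed_pos = np.flatnonzero(arr == seed_family)
            partner_pos = np.flatnonzero(arr == partner_family)
            seed_seen |= seed_pos.size > 0
            partner_seen |= partner_pos.size > 0
            layout_positions.append(
                (table.genome_id, seed_pos, partner_pos, len(fams))
            )
    if not seed_seen:
        raise ValueError(f"seed family {seed_family!r} absent from all genomes")
    if not partner_seen:
        raise ValueError(f"partner family {partner_family!r} absent from all genomes")
    observed = _pair_adjacency_count(layout_positions, k)
    n_ge = 0
    for _ in range(n_perm):
        permuted = []
        for genome_id, seed_pos, partner_pos, size in layout_positions:
            if seed_pos.size and partner_pos.size:
                perm = rng.permutation(size)
                permuted.append(
                    (genome_id, perm[seed_pos], perm[partner_pos], size)
                )
            else:
                permuted.append((genome_id, seed_pos, partner_pos, size))
        if _pair_adjacency_count(permuted, k) >= observed:
            n_ge += 1
    return (1 + n_ge) / (n_perm + 1)


def attach_pvalues(
    partners: pd.DataFrame,
    tables: Iterable[GenomeTable],
    orthology: OrthologyMap,
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Add a ``p_value`` column to a partner table (top rows only if asked)."""
    tables = list(tables)
    rng = np.random.default_rng(rng)
    seed_family = partners.attrs["seed_family"]
    k = partners.attrs["k"]
    out = partners.copy()
    out["p_value"] = np.nan
    limit = len(out) if top_n is None else min(top_n, len(out))
    for i in range(limit):
        out.loc[out.index[i], "p_value"] = permutation_pvalue(
            seed_family,
            out.iloc[i]["partner_family"],
            tables,
            orthology,
            k=k,
            n_perm=n_perm,
            rng=rng,
        )
    out.attrs.update(partners.attrs)
    return out


def find_cassettes(
    seed_family: str,
    tables: Iterable[GenomeTable],
    orthology: OrthologyMap,
    min_support: int = 3,
    max_len: int = 6,
) -> list[Cassette]:
    """Maximal contiguous family sets containing the seed.

    A candidate set of size s (2..max_len) is supported by a genome when
    s consecutive genes on one replicon carry exactly those s distinct
    families, regardless of order or strand. Candidates supported by at
    least ``min_support`` genomes are reported; a set is dropped when a
    reported superset has the same (or larger) supporting genome set.
    """
    support: dict[frozenset[str], set[str]] = {}
    for table in list(tables):
        genome_sets: set[frozenset[str]] = set()
        for fams in _family_layout(table, orthology):
            n = len(fams)
            for pos, fam in enumerate(fams):
                if fam != seed_family:
                    continue
                for size in range(2, max_len + 1):
                    for w0 in range(pos - size + 1, pos + 1):
                        if w0 < 0 or w0 + size > n:
                            continue
                        window = fams[w0 : w0 + size]
                        fs = frozenset(window)
                        if len(fs) == size:
                            genome_sets.add(fs)
        for fs in genome_sets:
            support.setdefault(fs, set()).add(table.genome_id)
    kept = {
        fs: gset for fs, gset in support.items() if len(gset) >= min_support
    }
    results: list[Cassette] = []
    for fs, gset in kept.items():
        dominated = any(
            other > fs and oset >= gset
            for other, oset in kept.items()
            if other != fs
        )
        if not dominated:
            results.append(Cassette(tuple(sorted(fs)), tuple(sorted(gset))))
    results.sort(key=lambda c: (-c.support, -len(c.families), c.families))
    return results
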