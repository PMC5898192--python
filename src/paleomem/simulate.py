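"""Synthetic genome-evolution scenarios with recorded ground truth.

The generator produces everything the analysis pipeline consumes --
species tree with lineages, gene presence evolved by a gain/loss CTMC,
gene orders with planted conserved cassettes, protein sequences with
planted hydrophobic TM stretches and optional signal peptides, and
annotation strings with planted "hypothetical" families -- together with
the ground truth needed for recovery tests, so every stage is testable
without external downloads.

Sequences are compositionally synthetic: TM blocks are drawn from
hydrophobic residues and linkers from hydrophilic ones with weights
chosen so that a planted 21-residue TM reliably produces an
above-threshold hydropathy run for the predictor, while linkers can
never do so (every linker residue has negative hydropathy). There is no
evolutionary sequence model; the TM predictor only consumes hydropathy,
so composition is the only property that must be realistic.

All randomness flows from a single integer seed; identical seeds give
byte-identical scenario bundles.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .io_formats import (
    GeneRecord,
    GenomeTable,
    OrthologyMap,
    SpeciesTree,
    write_fasta,
    write_gene_table,
    write_gene_tables,
    write_lineage_map,
    write_orthology,
    write_tree,
)

logger = logging.getLogger(__name__)

#: Hydrophobic residues used for TM blocks and signal cores, with weights
#: biased to strongly hydrophobic residues so a 21-mer survives window-19
#: smoothing against its flanking linkers.
TM_RESIDUES = tuple("LIVFAM")
TM_WEIGHTS = (0.40, 0.30, 0.20, 0.06, 0.02, 0.02)

#: Hydrophilic linker residues (all negative Kyte-Doolittle values, so a
#: linker can never reach the TM threshold), biased to mildly hydrophilic
#: S/T/G so that smoothing does not erode genuine TM runs below the
#: predictor's minimum length.
LINKER_RESIDUES = tuple("DEKRSTNQGP")
LINKER_WEIGHTS = (0.04, 0.04, 0.04, 0.01, 0.30, 0.30, 0.03, 0.03, 0.20, 0.01)

DEFAULT_VOCABULARY = (
    "ABC transporter permease",
    "DNA-directed RNA polymerase subunit",
    "ribosomal protein",
    "aminotransferase",
    "glycosyltransferase",
    "ATP synthase subunit",
    "preprotein translocase subunit",
    "cation efflux pump",
    "oxidoreductase",
    "S-layer glycoprotein",
    "methyltransferase",
    "aldehyde ferredoxin oxidoreductase",
    "transcriptional regulator",
    "serine protease",
    "tRNA modification enzyme",
)

HYPOTHETICAL_LABEL = "hypothetical protein"


@dataclass
class SimConfig:
    """Scenario parameters.

    Defaults define the desk-scale study condition: 20 genomes in 5
    lineages on an ultrametric height-1 tree, 1000 families with half
    present at the root, slow gain (0.10) and moderate loss (0.15) per
    unit branch length, 8 planted cassettes retained with probability
    0.8, 30% membrane families (two or more TMs), 10% single-TM
    families, and 35% hypothetical annotation.
    """

    n_genomes: int = 20
    n_lineages: int = 5
    tree_shape: str = "balanced"  # or "random"
    tree_height: float = 1.0
    n_families: int = 1000
    fraction_root_present: float = 0.5
    gain_rate: float = 0.10
    loss_rate: float = 0.15
    n_cassettes: int = 8
    cassette_sizes: tuple[int, ...] = (3, 4)
    cassette_retention: float = 0.8
    shuffle_fraction: float = 0.0
    prob_paralog: float = 0.03
    fraction_membrane: float = 0.30
    tm_count_weights: tuple[tuple[int, float], ...] = (
        (2, 0.30),
        (3, 0.25),
        (4, 0.20),
        (5, 0.10),
        (6, 0.10),
        (7, 0.05),
    )
    fraction_single_tm: float = 0.10
    fraction_signal: float = 0.15
    fraction_secreted_signal: float = 0.05
    fraction_hypothetical: float = 0.35
    annotation_noise: float = 0.10
    annotation_vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY
    gene_length_range: tuple[int, int] = (300, 1500)
    intergenic_gap_range: tuple[int, int] = (20, 400)
    cassette_gap_range: tuple[int, int] = (10, 40)
    linker_length_range: tuple[int, int] = (20, 40)
    tm_length: int = 21

    def __post_init__(self) -> None:
        for name in (
            "fraction_root_present",
            "cassette_retention",
            "shuffle_fraction",
            "prob_paralog",
            "fraction_membrane",
            "fraction_single_tm",
            "fraction_signal",
            "fraction_secreted_signal",
            "fraction_hypothetical",
            "annotation_noise",
        ):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        for name in ("n_genomes", "n_lineages", "n_families"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.fraction_membrane + self.fraction_single_tm > 1.0:
            raise ValueError("membrane and single-TM fractions exceed 1")
        if self.n_lineages > self.n_genomes:
            raise ValueError("more lineages than genomes")
        if not self.annotation_vocabulary:
            raise ValueError("annotation vocabulary must be non-empty")

    @property
    def family_ids(self) -> list[str]:
        width = len(str(self.n_families))
        return [f"FAM{i:0{width}d}" for i in range(1, self.n_families + 1)]

    @property
    def genome_ids(self) -> list[str]:
        width = len(str(self.n_genomes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genomes + 1)]


@dataclass
class Scenario:
    """A generated input bundle plus its ground truth."""

    config: SimConfig
    tree: SpeciesTree
    presence: pd.DataFrame  # families x genomes, bool
    root_states: pd.Series  # family -> 0/1
    roles: pd.DataFrame  # membrane, true_tm, signal, hypothetical
    cassettes: list[tuple[str, ...]]
    tables: dict[str, GenomeTable]
    orthology: OrthologyMap
    members: dict[str, list[str]]  # family -> protein ids
    proteins: dict[str, str] = field(default_factory=dict)
    true_segments: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    annotations: dict[str, str] = field(default_factory=dict)

    @property
    def qualifying_families(self) -> list[str]:
        """Ground-truth funnel targets: root-present, membrane, hypothetical."""
        mask = (
            self.root_states.astype(bool)
            & self.roles["membrane"]
            & self.roles["hypothetical"]
        )
        return sorted(self.root_states.index[mask])

    def truth_dict(self) -> dict:
        fams = {}
        qualifying = set(self.qualifying_families)
        for fam in self.presence.index:
            fams[fam] = {
                "root_present": bool(self.root_states[fam]),
                "membrane": bool(self.roles.loc[fam, "membrane"]),
                "true_tm": int(self.roles.loc[fam, "true_tm"]),
                "signal": bool(self.roles.loc[fam, "signal"]),
                "hypothetical": bool(self.roles.loc[fam, "hypothetical"]),
                "qualifying": fam in qualifying,
            }
        return {
            "families": fams,
            "cassettes": [list(c) for c in self.cassettes],
            "n_qualifying": len(qualifying),
        }


# ---------------------------------------------------------------------------
# tree


def _balanced_node(
    taxa: list, remaining: float, levels: int, namespace
) -> dendropy.Node:
    node = dendropy.Node()
    if len(taxa) == 1:
        node.taxon = taxa[0]
        node.edge.length = remaining
        return node
    step = remaining / max(levels, 1)
    left = taxa[: len(taxa) // 2]
    right = taxa[len(taxa) // 2 :]
    for part in (left, right):
        child = _balanced_node(part, remaining - step, levels - 1, namespace)
        if len(part) > 1:
            child.edge.length = step
        else:
            child.edge.length = remaining  # stretch terminal edge to height
        node.add_child(child)
    return node


def simulate_tree(
    config: SimConfig, rng: np.random.Generator
) -> SpeciesTree:
    """Ultrametric rooted tree of the configured height, plus lineages.

    ``balanced`` recursively bisects the genome list with equal level
    steps; ``random`` draws a coalescent-style random topology with
    exponential height increments rescaled to the target height. Lineages
    are the ``n_lineages`` clades obtained by repeatedly splitting the
    largest clade from the root down.
    """
    gids = config.genome_ids
    ns = dendropy.TaxonNamespace(gids)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = True
    taxa = [ns.get_taxon(g) for g in gids]
    if config.tree_shape == "balanced":
        levels = max(1, math.ceil(math.log2(len(taxa)))) if len(taxa) > 1 else 1
        root = _balanced_node(taxa, config.tree_height, levels, ns)
        root.edge.length = None
        tree.seed_node = root
    elif config.tree_shape == "random":
        nodes = []
        for t in taxa:
            node = dendropy.Node(taxon=t)
            node.height = 0.0
            nodes.append(node)
        height = 0.0
        increments = rng.exponential(1.0, size=max(len(nodes) - 1, 1))
        increments = increments / increments.sum() * config.tree_height
        order = list(range(len(nodes)))
        step = 0
        while len(nodes) > 1:
            height += increments[step]
            step += 1
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            parent = dendropy.Node()
            parent.height = height
            for child in (nodes[i], nodes[j]):
                child.edge.length = height - child.height
                parent.add_child(child)
            nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
            nodes.append(parent)
        tree.seed_node = nodes[0]
    else:
        raise ValueError(f"unknown tree shape {config.tree_shape!r}")
    tree.update_bipartitions(suppress_unifurcations=False)
    lineage_map = _assign_lineages(tree, config.n_lineages)
    return SpeciesTree(tree, lineage_map)


def _assign_lineages(tree: dendropy.Tree, n_lineages: int) -> dict[str, str]:
    clades: list[dendropy.Node] = [tree.seed_node]
    while len(clades) < n_lineages:
        clades.sort(key=lambda n: -len(n.leaf_nodes()))
        biggest = clades[0]
        children = biggest.child_nodes()
        if not children:
            break  # all clades are single leaves
        clades = clades[1:] + children
    # name lineages in leaf order for stable output
    leaf_order = {
        lf.taxon.label: i for i, lf in enumerate(tree.leaf_node_iter())
    }
    clades.sort(key=lambda n: min(leaf_order[l.taxon.label] for l in n.leaf_nodes()))
    width = len(str(len(clades)))
    out: dict[str, str] = {}
    for i, clade in enumerate(clades, start=1):
        for leaf in clade.leaf_nodes():
            out[leaf.taxon.label] = f"L{i:0{width}d}"
    return out


# ---------------------------------------------------------------------------
# gene content


def simulate_gene_content(
    config: SimConfig,
    rng: np.random.Generator,
    tree: SpeciesTree | None = None,
) -> tuple[SpeciesTree, pd.DataFrame, pd.Series]:
    """Evolve binary presence down the tree under the gain/loss CTMC.

    Root states are Bernoulli(``fraction_root_present``); along each
    branch of length t the state flips with the two-state CTMC
    transition probabilities at (``gain_rate``, ``loss_rate``).
    Returns (tree, presence DataFrame families x genomes, root states).
    """
    if tree is None:
        tree = simulate_tree(config, rng)
    fams = config.family_ids
    n = len(fams)
    g, l = config.gain_rate, config.loss_rate
    r = g + l
    root_states = (rng.random(n) < config.fraction_root_present).astype(int)
    states: dict[int, np.ndarray] = {id(tree.tree.seed_node): root_states}
    leaf_states: dict[str, np.ndarray] = {}
    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            current = root_states
        else:
            parent_states = states[id(node.parent_node)]
            t = node.edge.length if node.edge.length is not None else 1.0
            if r > 0:
                f = 1.0 - np.exp(-r * t)
                p_gain = g / r * f
                p_loss = l / r * f
            else:
                p_gain = p_loss = 0.0
            u = rng.random(n)
            current = np.where(
                parent_states == 1,
                (u >= p_loss).astype(int),
                (u < p_gain).astype(int),
            )
            states[id(node)] = current
        if node.is_leaf():
            leaf_states[node.taxon.label] = current
    presence = pd.DataFrame(
        {gid: leaf_states[gid].astype(bool) for gid in config.genome_ids},
        index=fams,
    )
    return tree, presence, pd.Series(root_states, index=fams)


def expected_leaf_presence(
    config: SimConfig, tree: SpeciesTree
) -> pd.Series:
    """Analytic P(present at leaf) under the configured CTMC and root prior."""
    g, l = config.gain_rate, config.loss_rate
    r = g + l
    dist: dict[int, np.ndarray] = {
        id(tree.tree.seed_node): np.array(
            [1 - config.fraction_root_present, config.fraction_root_present]
        )
    }
    out: dict[str, float] = {}
    for node in tree.tree.preorder_node_iter():
        if node is not tree.tree.seed_node:
            t = node.edge.length if node.edge.length is not None else 1.0
            f = 1.0 - np.exp(-r * t) if r > 0 else 0.0
            P = np.array(
                [[1 - g / r * f, g / r * f], [l / r * f, 1 - l / r * f]]
            ) if r > 0 else np.eye(2)
            dist[id(node)] = dist[id(node.parent_node)] @ P
        if node.is_leaf():
            out[node.taxon.label] = float(dist[id(node)][1])
    return pd.Series(out)


# ---------------------------------------------------------------------------
# family roles (membrane status, TM counts, signal, annotation class)


def assign_family_roles(
    config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw per-family membrane/TM/signal/hypothetical ground truth."""
    fams = config.family_ids
    n = len(fams)
    u = rng.random(n)
    membrane = u < config.fraction_membrane
    single = (~membrane) & (
        u < config.fraction_membrane + config.fraction_single_tm
    )
    counts, weights = zip(*config.tm_count_weights)
    weights = np.array(weights, dtype=float)
    weights /= weights.sum()
    true_tm = np.zeros(n, dtype=int)
    true_tm[membrane] = rng.choice(counts, size=int(membrane.sum()), p=weights)
    true_tm[single] = 1
    signal = np.zeros(n, dtype=bool)
    signal[membrane] = rng.random(int(membrane.sum())) < config.fraction_signal
    soluble = ~membrane & ~single
    signal[soluble] = (
        rng.random(int(soluble.sum())) < config.fraction_secreted_signal
    )
    hypothetical = rng.random(n) < config.fraction_hypothetical
    return pd.DataFrame(
        {
            "membrane": membrane,
            "true_tm": true_tm,
            "signal": signal,
            "hypothetical": hypothetical,
        },
        index=fams,
    )


# ---------------------------------------------------------------------------
# gene orders


def choose_cassettes(
    presence: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> list[tuple[str, ...]]:
    """Pick cassette compositions among widely present families."""
    n_genomes = presence.shape[1]
    widespread = presence.index[
        presence.sum(axis=1) >= 0.6 * n_genomes
    ].tolist()
    sizes = [
        config.cassette_sizes[i % len(config.cassette_sizes)]
        for i in range(config.n_cassettes)
    ]
    need = sum(sizes)
    if len(widespread) < need:
        raise ValueError(
            f"only {len(widespread)} widespread families for {need} cassette slots"
        )
    picked = rng.choice(len(widespread), size=need, replace=False)
    pool = [widespread[i] for i in picked]
    cassettes = []
    pos = 0
    for size in sizes:
        cassettes.append(tuple(pool[pos : pos + size]))
        pos += size
    return cassettes


def simulate_gene_orders(
    presence: pd.DataFrame,
    cassettes: Sequence[tuple[str, ...]],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, GenomeTable], OrthologyMap, dict[str, list[str]]]:
    """Lay out one genome per presence column.

    Families present get one gene each (occasionally two paralogs); a
    planted cassette whose members are all present is laid out as a
    contiguous same-strand block with probability ``cassette_retention``
    (with operon-compatible intergenic gaps), otherwise scattered; the
    remaining genes are shuffled. Returns gene tables (annotations left
    blank), the orthology map, and family -> member protein ids.
    """
    cassette_families = {f for cas in cassettes for f in cas}
    orthology_entries: dict[str, str] = {}
    members: dict[str, list[str]] = {f: [] for f in presence.index}
    tables: dict[str, GenomeTable] = {}
    lo_len, hi_len = config.gene_length_range
    for gid in presence.columns:
        present = [f for f in presence.index if presence.at[f, gid]]
        blocks: list[tuple[list[str], bool]] = []  # (families, is_cassette)
        in_block: set[str] = set()
        for cas in cassettes:
            if all(f in present for f in cas if True) and all(
                presence.at[f, gid] for f in cas
            ):
                if rng.random() < config.cassette_retention:
                    order = list(cas)
                    if rng.random() < 0.5:
                        order.reverse()
                    blocks.append((order, True))
                    in_block.update(cas)
        loose: list[str] = []
        for fam in present:
            if fam in in_block:
                continue
            loose.append(fam)
            if fam not in cassette_families and rng.random() < config.prob_paralog:
                loose.append(fam)
        rng.shuffle(loose)
        layout: list[tuple[str, bool, bool]] = [
            (fam, False, False) for fam in loose
        ]  # (family, part of block, block continues after this gene)
        for fams_in_block, _ in blocks:
            at = int(rng.integers(0, len(layout) + 1))
            block_entries = [
                (f, True, i < len(fams_in_block) - 1)
                for i, f in enumerate(fams_in_block)
            ]
            layout[at:at] = block_entries
        if config.shuffle_fraction > 0 and layout:
            n_moves = int(config.shuffle_fraction * len(layout))
            for _ in range(n_moves):
                src = int(rng.integers(0, len(layout)))
                item = layout.pop(src)
                dst = int(rng.integers(0, len(layout) + 1))
                layout.insert(dst, (item[0], False, False))
        records: list[GeneRecord] = []
        pos = int(rng.integers(50, 500))
        strand = "+" if rng.random() < 0.5 else "-"
        prev_continues = False
        for i, (fam, in_cas, continues) in enumerate(layout):
            length = int(rng.integers(lo_len, hi_len + 1)) // 3 * 3
            if not (prev_continues and in_cas):
                strand = "+" if rng.random() < 0.5 else "-"
            pid = f"{gid}_{i + 1:05d}"
            records.append(
                GeneRecord(
                    genome_id=gid,
                    replicon_id="chr",
                    start=pos,
                    end=pos + length,
                    strand=strand,
                    protein_id=pid,
                    annotation="",
                )
            )
            orthology_entries[pid] = fam
            members[fam].append(pid)
            if continues:
                gap = int(rng.integers(*config.cassette_gap_range))
            else:
                gap = int(rng.integers(*config.intergenic_gap_range))
            pos += length + gap
            prev_continues = continues
        tables[gid] = GenomeTable(gid, records)
    members = {f: pids for f, pids in members.items() if pids}
    return tables, OrthologyMap(orthology_entries), members


# ---------------------------------------------------------------------------
# proteins


def _draw(rng, alphabet, weights, n) -> str:
    return "".join(rng.choice(alphabet, size=n, p=weights))


def simulate_proteins(
    members: Mapping[str, Sequence[str]],
    roles: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, str], dict[str, list[tuple[int, int]]], dict[str, bool]]:
    """Synthesize member sequences with recorded planted segments.

    Sequence = optional signal peptide (Met + K/R + hydrophobic core) +
    alternating hydrophilic linkers and 21-residue hydrophobic TM blocks.
    Membrane families jitter the member TM count by {-1, 0, +1} with
    probabilities {0.15, 0.70, 0.15}, floored at 1. Returns sequences,
    per-protein planted hydrophobic spans (signal core included), and
    per-protein signal flags.
    """
    tm_alpha = np.array(TM_RESIDUES)
    tm_w = np.array(TM_WEIGHTS)
    link_alpha = np.array(LINKER_RESIDUES)
    link_w = np.array(LINKER_WEIGHTS)
    lo_link, hi_link = config.linker_length_range
    seqs: dict[str, str] = {}
    spans: dict[str, list[tuple[int, int]]] = {}
    signal_flags: dict[str, bool] = {}
    for fam in sorted(members):
        role = roles.loc[fam]
        for pid in members[fam]:
            n_tm = int(role["true_tm"])
            if role["membrane"]:
                n_tm = max(1, n_tm + int(rng.choice([-1, 0, 1], p=[0.15, 0.7, 0.15])))
            parts: list[str] = []
            planted: list[tuple[int, int]] = []
            pos = 0
            if role["signal"]:
                charge = "K" if rng.random() < 0.5 else "R"
                mild = str(rng.choice(np.array(list("STG"))))
                core = _draw(rng, tm_alpha, tm_w, 17)
                sig = "M" + charge + mild + core
                parts.append(sig)
                planted.append((3, 3 + 17))
                pos = len(sig)
            else:
                parts.append("M")
                pos = 1
            for _ in range(n_tm):
                linker = _draw(
                    rng, link_alpha, link_w, int(rng.integers(lo_link, hi_link + 1))
                )
                parts.append(linker)
                pos += len(linker)
                tm = _draw(rng, tm_alpha, tm_w, config.tm_length)
                parts.append(tm)
                planted.append((pos, pos + config.tm_length))
                pos += config.tm_length
            tail = _draw(
                rng, link_alpha, link_w, int(rng.integers(lo_link, hi_link + 1))
            )
            if n_tm == 0:
                tail += _draw(rng, link_alpha, link_w, 80)
            parts.append(tail)
            seqs[pid] = "".join(parts)
            spans[pid] = planted
            signal_flags[pid] = bool(role["signal"])
    return seqs, spans, signal_flags


# ---------------------------------------------------------------------------
# annotations


def simulate_annotations(
    members: Mapping[str, Sequence[str]],
    roles: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Per-protein annotation strings.

    Hypothetical families are uniformly labelled "hypothetical protein";
    other families get a fixed function string from the vocabulary, with
    a configurable fraction of members mislabelled hypothetical
    (annotation noise).
    """
    if not config.annotation_vocabulary:
        raise ValueError("annotation vocabulary must be non-empty")
    vocab = list(config.annotation_vocabulary)
    out: dict[str, str] = {}
    for fam in sorted(members):
        if roles.loc[fam, "hypothetical"]:
            for pid in members[fam]:
                out[pid] = HYPOTHETICAL_LABEL
        else:
            label = vocab[int(rng.integers(0, len(vocab)))]
            for pid in members[fam]:
                if rng.random() < config.annotation_noise:
                    out[pid] = HYPOTHETICAL_LABEL
                else:
                    out[pid] = label
    return out


def _attach_annotations(
    tables: dict[str, GenomeTable], annotations: Mapping[str, str]
) -> dict[str, GenomeTable]:
    out = {}
    for gid, table in tables.items():
        out[gid] = GenomeTable(
            gid,
            [
                GeneRecord(
                    genome_id=r.genome_id,
                    replicon_id=r.replicon_id,
                    start=r.start,
                    end=r.end,
                    strand=r.strand,
                    protein_id=r.protein_id,
                    annotation=annotations.get(r.protein_id, ""),
                    family_id=r.family_id,
                )
                for r in table
            ],
        )
    return out


# ---------------------------------------------------------------------------
# full scenarios


def generate_scenario(
    config: SimConfig | None = None,
    seed: int = 0,
    with_proteins: bool = True,
    with_annotations: bool = True,
) -> Scenario:
    """Generate a complete scenario from a single seed.

    ``with_proteins=False`` skips sequence synthesis for analyses that
    only need gene content and order (much faster).
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    tree, presence, root_states = simulate_gene_content(config, rng)
    roles = assign_family_roles(config, rng)
    cassettes = choose_cassettes(presence, config, rng)
    tables, orthology, members = simulate_gene_orders(
        presence, cassettes, config, rng
    )
    scenario = Scenario(
        config=config,
        tree=tree,
        presence=presence,
        root_states=root_states,
        roles=roles,
        cassettes=cassettes,
        tables=tables,
        orthology=orthology,
        members=members,
    )
    if with_proteins:
        seqs, spans, _flags = simulate_proteins(members, roles, config, rng)
        scenario.proteins = seqs
        scenario.true_segments = spans
    if with_annotations:
        scenario.annotations = simulate_annotations(members, roles, config, rng)
        scenario.tables = _attach_annotations(tables, scenario.annotations)
    return scenario


def write_scenario(
    config: SimConfig | None,
    outdir: str | Path,
    seed: int = 0,
) -> Scenario:
    """Generate and write a full input bundle plus ground truth files.

    Emits per-genome GFF3 files, a combined TSV gene table, protein
    FASTA, orthology TSV, Newick tree, lineage map, the truth JSON, and
    the configuration used. Deterministic: identical seeds yield
    byte-identical bundles.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenario = generate_scenario(config, seed=seed)
    gff_dir = outdir / "genomes"
    gff_dir.mkdir(exist_ok=True)
    for gid in sorted(scenario.tables):
        write_gene_table(scenario.tables[gid], gff_dir / f"{gid}.gff3", "gff3")
    write_gene_tables(
        [scenario.tables[g] for g in sorted(scenario.tables)],
        outdir / "gene_tables.tsv",
    )
    write_fasta(scenario.proteins, outdir / "proteins.faa")
    write_orthology(scenario.orthology, outdir / "orthology.tsv")
    write_tree(scenario.tree, outdir / "tree.nwk")
    write_lineage_map(scenario.tree.lineage_map, outdir / "lineages.tsv")
    truth = scenario.truth_dict()
    truth["true_segments"] = {
        pid: [list(s) for s in spans]
        for pid, spans in sorted(scenario.true_segments.items())
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    with open(outdir / "config.json", "w") as fh:
        cfg = asdict(scenario.config)
        cfg["seed"] = seed
        json.dump(cfg, fh, indent=1, sort_keys=True, default=list)
    return scenario
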