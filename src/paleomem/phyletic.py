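"""Phyletic patterns: family x genome presence matrices and lineage codes.

A phyletic pattern is the presence/absence vector of an orthologous gene
family across genomes. The matrix keeps paralog *counts*, but all derived
quantities (lineage codes, complementarity) use presence only. Lineage
codes follow the conventional three-symbol scheme: ``1`` present in the
vast majority of a lineage's genomes, ``p`` partially present, ``–``
absent; "vast majority" is quantified as a configurable fraction
(default 0.8).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomeTable, OrthologyMap

logger = logging.getLogger(__name__)

PRESENT = "1"
PARTIAL = "p"
ABSENT = "–"  # en dash, as conventionally printed

#: Accepted spellings on input, normalized to the canonical three codes.
_CODE_ALIASES = {
    "1": PRESENT,
    "p": PARTIAL,
    "P": PARTIAL,
    "–": ABSENT,
    "-": ABSENT,
    "": ABSENT,
}


class PhyleticMatrix:
    """Family x genome member-count matrix.

    Thin wrapper over an integer DataFrame (families as rows, genomes as
    columns) providing presence views and TSV round-tripping.
    """

    def __init__(self, counts: pd.DataFrame):
        if (counts.values < 0).any():
            raise ValueError("negative counts in phyletic matrix")
        self.counts = counts.astype(int)

    @property
    def families(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genomes(self) -> list[str]:
        return list(self.counts.columns)

    def presence(self) -> pd.DataFrame:
        return self.counts > 0

    def __eq__(self, other) -> bool:
        if not isinstance(other, PhyleticMatrix):
            return NotImplemented
        return self.counts.equals(other.counts)

    def reorder(self, genomes: Sequence[str]) -> "PhyleticMatrix":
        return PhyleticMatrix(self.counts.loc[:, list(genomes)])

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="family")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhyleticMatrix":
        df = pd.read_csv(path, sep="\t", index_col="family")
        df.index = df.index.astype(str)
        return cls(df)


@dataclass(frozen=True)
class LineagePattern:
    """Per-lineage presence codes of one family (Table-style row)."""

    family_id: str
    codes: tuple[tuple[str, str], ...]  # (lineage, code), ordered

    @classmethod
    def from_codes(
        cls, family_id: str, lineages: Sequence[str], codes: Sequence[str]
    ) -> "LineagePattern":
        """Build from printed codes, normalizing aliases ('P', '-')."""
        if len(lineages) != len(codes):
            raise ValueError("lineages and codes differ in length")
        normalized = []
        for lin, code in zip(lineages, codes):
            if code not in _CODE_ALIASES:
                raise ValueError(f"unknown presence code {code!r}")
            normalized.append((lin, _CODE_ALIASES[code]))
        return cls(family_id, tuple(normalized))

    @property
    def lineages(self) -> tuple[str, ...]:
        return tuple(lin for lin, _ in self.codes)

    def code(self, lineage: str) -> str:
        for lin, c in self.codes:
            if lin == lineage:
                return c
        raise KeyError(lineage)

    @property
    def presence_set(self) -> frozenset[str]:
        """Lineages where the family is at least partially present."""
        return frozenset(lin for lin, c in self.codes if c != ABSENT)


def build_matrix(
    tables: Iterable[GenomeTable],
    orthology: OrthologyMap,
    include_singletons: bool = True,
) -> PhyleticMatrix:
    """Count family members per genome from gene tables and orthology.

    Unmapped proteins fall back to per-protein singleton families unless
    ``include_singletons`` is false, in which case they are dropped.
    Families observed nowhere are, by construction, not rows.
    """
    tables = list(tables)
    genome_ids = [t.genome_id for t in tables]
    if len(set(genome_ids)) != len(genome_ids):
        raise ValueError("duplicate genome ids in table set")
    cells: dict[str, dict[str, int]] = {}
    for table in tables:
        for rec in table:
            fam = orthology.family_of(rec.protein_id)
            if not include_singletons and OrthologyMap.is_singleton(fam):
                continue
            row = cells.setdefault(fam, {})
            row[table.genome_id] = row.get(table.genome_id, 0) + 1
    df = pd.DataFrame.from_dict(cells, orient="index", dtype=float)
    df = df.reindex(columns=genome_ids).fillna(0).astype(int)
    df = df.sort_index()
    return PhyleticMatrix(df)


def drop_singletons(matrix: PhyleticMatrix) -> PhyleticMatrix:
    keep = [f for f in matrix.families if not OrthologyMap.is_singleton(f)]
    return PhyleticMatrix(matrix.counts.loc[keep])


def collapse_by_lineage(
    matrix: PhyleticMatrix,
    lineage_map: Mapping[str, str],
    majority: float = 0.8,
    lineage_order: Sequence[str] | None = None,
) -> list[LineagePattern]:
    """Collapse the matrix to per-lineage presence codes.

    For a family and lineage with presence fraction phi (genomes with at
    least one member over genomes in the lineage): ``1`` if
    ``phi >= majority``, ``p`` if ``0 < phi < majority``, ``–`` if
    ``phi == 0``. Depends only on the presence fractions, hence
    idempotent under paralog-count changes.
    """
    missing = [g for g in matrix.genomes if g not in lineage_map]
    if missing:
        raise ValueError(f"genomes without lineage assignment: {missing}")
    if lineage_order is None:
        seen: list[str] = []
        for g in matrix.genomes:
            if lineage_map[g] not in seen:
                seen.append(lineage_map[g])
        lineage_order = seen
    groups = {
        lin: [g for g in matrix.genomes if lineage_map[g] == lin]
        for lin in lineage_order
    }
    empty = [lin for lin, gs in groups.items() if not gs]
    if empty:
        raise ValueError(f"lineages with zero genomes: {empty}")
    presence = matrix.presence()
    frac = pd.DataFrame(
        {lin: presence[gs].mean(axis=1) for lin, gs in groups.items()}
    )
    patterns = []
    for fam, row in frac.iterrows():
        codes = []
        for lin in lineage_order:
            phi = row[lin]
            if phi == 0:
                codes.append((lin, ABSENT))
            elif phi >= majority:
                codes.append((lin, PRESENT))
            else:
                codes.append((lin, PARTIAL))
        patterns.append(LineagePattern(str(fam), tuple(codes)))
    return patterns


def pattern_complementarity(a: LineagePattern, b: LineagePattern) -> float:
    """Complementarity of two lineage patterns.

    Presence means any non-absent code (``p`` counts as presence). With
    presence sets A and B, C = (|A or B| - |A and B|) / |A or B|: 0 for
    identical patterns, 1 for disjoint ones. Undefined (error) when both
    patterns are empty.
    """
    if set(a.lineages) != set(b.lineages):
        raise ValueError("patterns are over different lineage sets")
    pa, pb = a.presence_set, b.presence_set
    union = pa | pb
    if not union:
        raise ValueError("complementarity undefined: both patterns all-absent")
    return (len(union) - len(pa & pb)) / len(union)


def write_lineage_patterns(
    patterns: Sequence[LineagePattern], path: str | Path
) -> None:
    if not patterns:
        Path(path).write_text("family\n")
        return
    lineages = patterns[0].lineages
    with open(path, "w") as fh:
        fh.write("family\t" + "\t".join(lineages) + "\n")
        for pat in patterns:
            fh.write(
                pat.family_id
                + "\t"
                + "\t".join(pat.code(lin) for lin in lineages)
                + "\n"
            )
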