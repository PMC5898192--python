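"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are handled internally as 0-based, half-open
intervals; GFF3 (1-based, inclusive) is converted at the I/O boundary so
that gap and overlap arithmetic never needs an off-by-one correction.

Supported formats:

* gene tables -- GFF3 (attributes ``ID`` and ``product``) or a TSV dialect
  with header ``genome replicon start end strand protein_id annotation``
  (TSV coordinates are already 0-based half-open);
* orthology assignments -- two-column TSV ``protein_id family_id``;
* protein sequences -- FASTA (amino-acid alphabet, ``X`` allowed);
* species trees -- rooted Newick, read through dendropy;
* genome -> lineage maps -- two-column TSV ``genome_id lineage``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

#: Proteins absent from an orthology map are treated as families of one.
SINGLETON_PREFIX = "SINGLETON:"

#: 20 standard amino acids plus X for unknown residues.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWYX")

GENE_TABLE_COLUMNS = (
    "genome",
    "replicon",
    "start",
    "end",
    "strand",
    "protein_id",
    "annotation",
)


class FormatError(ValueError):
    """Raised for malformed input files; message names file and line."""


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene.

    ``start``/``end`` are 0-based half-open on the replicon; ``family_id``
    is empty until orthology has been assigned.
    """

    genome_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    protein_id: str
    annotation: str = ""
    family_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.protein_id!r}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(
                f"gene {self.protein_id!r}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )

    def with_family(self, family_id: str) -> "GeneRecord":
        return replace(self, family_id=family_id)


class GenomeTable:
    """Ordered gene table of a single genome.

    Records are kept sorted by ``(replicon_id, start, end)``; protein ids
    must be unique and no two genes on one replicon may share identical
    ``(start, end, strand)``.
    """

    def __init__(self, genome_id: str, records: Iterable[GeneRecord]):
        self.genome_id = genome_id
        self._records = sorted(
            records, key=lambda r: (r.replicon_id, r.start, r.end)
        )
        self._validate()

    def _validate(self) -> None:
        seen_pid: set[str] = set()
        seen_pos: set[tuple[str, int, int, str]] = set()
        for rec in self._records:
            if rec.genome_id != self.genome_id:
                raise ValueError(
                    f"record {rec.protein_id!r} belongs to genome "
                    f"{rec.genome_id!r}, not {self.genome_id!r}"
                )
            if rec.protein_id in seen_pid:
                raise ValueError(
                    f"duplicate protein id {rec.protein_id!r} in genome "
                    f"{self.genome_id!r}"
                )
            seen_pid.add(rec.protein_id)
            key = (rec.replicon_id, rec.start, rec.end, rec.strand)
            if key in seen_pos:
                raise ValueError(
                    f"two genes share coordinates {key} in genome "
                    f"{self.genome_id!r}"
                )
            seen_pos.add(key)

    @property
    def records(self) -> tuple[GeneRecord, ...]:
        return tuple(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self._records)

    def by_replicon(self) -> dict[str, list[GeneRecord]]:
        out: dict[str, list[GeneRecord]] = {}
        for rec in self._records:
            out.setdefault(rec.replicon_id, []).append(rec)
        return out

    def get(self, protein_id: str) -> GeneRecord | None:
        for rec in self._records:
            if rec.protein_id == protein_id:
                return rec
        return None

    def with_families(self, orthology: "OrthologyMap") -> "GenomeTable":
        """Return a copy with ``family_id`` filled in (singleton rule)."""
        return GenomeTable(
            self.genome_id,
            (r.with_family(orthology.family_of(r.protein_id)) for r in self),
        )


class OrthologyMap:
    """Many-to-one map from protein ids to family ids.

    Lookup of an unmapped protein via :meth:`get` returns ``None``;
    :meth:`family_of` instead falls back to a per-protein singleton family
    ``SINGLETON:<protein_id>`` so downstream neighborhood analysis sees a
    complete gene complement.
    """

    def __init__(self, entries: Mapping[str, str]):
        for pid, fam in entries.items():
            if not fam:
                raise ValueError(f"empty family id for protein {pid!r}")
        self._entries = dict(entries)

    def get(self, protein_id: str) -> str | None:
        return self._entries.get(protein_id)

    def family_of(self, protein_id: str) -> str:
        fam = self._entries.get(protein_id)
        return fam if fam is not None else SINGLETON_PREFIX + protein_id

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def items(self):
        return self._entries.items()

    @staticmethod
    def is_singleton(family_id: str) -> bool:
        return family_id.startswith(SINGLETON_PREFIX)


@dataclass
class SpeciesTree:
    """Rooted species tree with an optional genome -> lineage map."""

    tree: dendropy.Tree
    lineage_map: dict[str, str] | None = None

    @property
    def leaf_ids(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def validate_genomes(self, genome_ids: Iterable[str]) -> None:
        """Cross-check leaf labels against a genome set; raise on mismatch."""
        leaves = set(self.leaf_ids)
        genomes = set(genome_ids)
        if leaves != genomes:
            missing = sorted(genomes - leaves)
            extra = sorted(leaves - genomes)
            raise ValueError(
                "species tree leaves do not match genome set "
                f"(genomes without leaf: {missing}; leaves without genome: {extra})"
            )


# ---------------------------------------------------------------------------
# gene tables


def _parse_gff3_attributes(raw: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            continue
        key, value = chunk.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def _read_gff3(path: Path, genome_id: str) -> GenomeTable:
    records: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            seqid, _src, _ftype, start_s, end_s, _score, strand, _phase, attrs_s = fields
            try:
                start1 = int(start_s)
                end1 = int(end_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            start = start1 - 1  # GFF3 1-based inclusive -> 0-based half-open
            end = end1
            if end <= start:
                raise FormatError(
                    f"{path}:{lineno}: end <= start after conversion "
                    f"([{start}, {end}))"
                )
            if strand not in STRANDS:
                raise FormatError(
                    f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}"
                )
            attrs = _parse_gff3_attributes(attrs_s)
            pid = attrs.get("ID")
            if not pid:
                raise FormatError(f"{path}:{lineno}: missing ID attribute")
            records.append(
                GeneRecord(
                    genome_id=genome_id,
                    replicon_id=seqid,
                    start=start,
                    end=end,
                    strand=strand,
                    protein_id=pid,
                    annotation=attrs.get("product", ""),
                )
            )
    return GenomeTable(genome_id, records)


def _read_tsv_records(path: Path) -> list[GeneRecord]:
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            return []
        header = header_line.split("\t")
        if tuple(header) != GENE_TABLE_COLUMNS:
            raise FormatError(
                f"{path}:1: bad header {header!r}; expected "
                f"{list(GENE_TABLE_COLUMNS)!r}"
            )
        records: list[GeneRecord] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(GENE_TABLE_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(GENE_TABLE_COLUMNS)} "
                    f"columns, got {len(fields)}"
                )
            row = dict(zip(GENE_TABLE_COLUMNS, fields))
            try:
                start = int(row["start"])
                end = int(row["end"])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            try:
                records.append(
                    GeneRecord(
                        genome_id=row["genome"],
                        replicon_id=row["replicon"],
                        start=start,
                        end=end,
                        strand=row["strand"],
                        protein_id=row["protein_id"],
                        annotation=row["annotation"],
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def read_gene_table(
    path: str | Path, dialect: str = "gff3", genome_id: str | None = None
) -> GenomeTable:
    """Read a single-genome gene table.

    ``dialect`` is ``"gff3"`` (1-based inclusive, converted) or ``"tsv"``
    (the documented 0-based half-open dialect). For GFF3, ``genome_id``
    defaults to the file stem.
    """
    path = Path(path)
    if dialect == "gff3":
        return _read_gff3(path, genome_id or path.stem)
    if dialect == "tsv":
        records = _read_tsv_records(path)
        genomes = {r.genome_id for r in records}
        if not records:
            return GenomeTable(genome_id or path.stem, [])
        if len(genomes) > 1:
            raise FormatError(
                f"{path}: contains {len(genomes)} genomes; use read_gene_tables"
            )
        gid = genomes.pop()
        if genome_id is not None and genome_id != gid:
            raise FormatError(
                f"{path}: genome column says {gid!r}, expected {genome_id!r}"
            )
        return GenomeTable(gid, records)
    raise ValueError(f"unknown dialect {dialect!r}")


def read_gene_tables(path: str | Path) -> dict[str, GenomeTable]:
    """Read a multi-genome TSV gene table into per-genome tables."""
    records = _read_tsv_records(Path(path))
    by_genome: dict[str, list[GeneRecord]] = {}
    for rec in records:
        by_genome.setdefault(rec.genome_id, []).append(rec)
    return {gid: GenomeTable(gid, recs) for gid, recs in sorted(by_genome.items())}


def write_gene_table(
    table: GenomeTable, path: str | Path, dialect: str = "gff3"
) -> None:
    path = Path(path)
    if dialect == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for rec in table:
                attrs = f"ID={rec.protein_id}"
                if rec.annotation:
                    attrs += f";product={rec.annotation}"
                fh.write(
                    "\t".join(
                        (
                            rec.replicon_id,
                            "paleomem",
                            "CDS",
                            str(rec.start + 1),
                            str(rec.end),
                            ".",
                            rec.strand,
                            "0",
                            attrs,
                        )
                    )
                    + "\n"
                )
    elif dialect == "tsv":
        write_gene_tables([table], path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def write_gene_tables(
    tables: Iterable[GenomeTable], path: str | Path
) -> None:
    """Write one or more genomes to the combined TSV dialect."""
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for table in tables:
            for rec in table:
                fh.write(
                    "\t".join(
                        (
                            rec.genome_id,
                            rec.replicon_id,
                            str(rec.start),
                            str(rec.end),
                            rec.strand,
                            rec.protein_id,
                            rec.annotation,
                        )
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# orthology


def read_orthology(path: str | Path) -> OrthologyMap:
    """Read a two-column ``protein_id family_id`` TSV.

    Consistent duplicate rows collapse to one entry; conflicting
    assignments for one protein are an error.
    """
    path = Path(path)
    entries: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            pid, fam = fields
            if not fam:
                raise FormatError(f"{path}:{lineno}: empty family id for {pid!r}")
            if pid in entries and entries[pid] != fam:
                raise FormatError(
                    f"{path}:{lineno}: conflicting families for {pid!r}: "
                    f"{entries[pid]!r} vs {fam!r}"
                )
            entries[pid] = fam
    return OrthologyMap(entries)


def write_orthology(orthology: OrthologyMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, fam in sorted(orthology.items()):
            fh.write(f"{pid}\t{fam}\n")


# ---------------------------------------------------------------------------
# trees and lineage maps


def read_tree(
    path: str | Path, lineage_map: Mapping[str, str] | None = None
) -> SpeciesTree:
    """Read a rooted Newick tree.

    Missing branch lengths default to 1.0 and zero-length branches are
    accepted; both are logged.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"{path}: cannot parse Newick: {exc}") from exc
    tree.is_rooted = True
    n_defaulted = 0
    n_zero = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 1.0
            n_defaulted += 1
        elif edge.length < 0:
            raise FormatError(f"{path}: negative branch length {edge.length}")
        elif edge.length == 0:
            n_zero += 1
    if n_defaulted:
        logger.info(
            "%s: %d branch lengths missing; defaulted to 1.0", path, n_defaulted
        )
    if n_zero:
        logger.info("%s: %d zero-length branches accepted", path, n_zero)
    return SpeciesTree(tree, dict(lineage_map) if lineage_map else None)


def write_tree(species_tree: SpeciesTree, path: str | Path) -> None:
    species_tree.tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def read_lineage_map(path: str | Path) -> dict[str, str]:
    """Read a ``genome_id lineage`` TSV (header optional)."""
    path = Path(path)
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            if lineno == 1 and fields == ["genome_id", "lineage"]:
                continue
            out[fields[0]] = fields[1]
    return out


def write_lineage_map(lineage_map: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tlineage\n")
        for gid, lin in sorted(lineage_map.items()):
            fh.write(f"{gid}\t{lin}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein FASTA into an id -> sequence dict.

    Sequences are uppercased; characters outside the 20 amino acids plus
    ``X`` are an error naming the offending record.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} has non-amino-acid characters "
                f"{sorted(bad)}"
            )
        out[rec.id] = seq
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="")
        for pid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
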