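"""The candidate-selection funnel and its report.

Composes the pipeline: phyletic matrix -> gain/loss rate fit -> ancestral
projection (root posterior >= threshold) -> membrane filter (family
lower-median effective TM count >= 2, signal-corrected) -> annotation
filter (majority of members annotated with a "hypothetical"-type
keyword) -> per-candidate neighborhood partner tables and lineage codes.
Stage counts are logged as a funnel summary
(n_families -> n_projected -> n_membrane -> n_hypothetical).

Partner annotations are reported for each candidate as association
evidence; the funnel never asserts a function.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ancestral import GainLossModel, TreeIndex, fit_rates, project_to_ancestor
from .io_formats import GenomeTable, OrthologyMap, SpeciesTree
from .membrane import FamilyTMSummary, predict_membrane, summarize_families
from .neighborhood import attach_pvalues, partner_frequencies
from .phyletic import (
    ABSENT,
    build_matrix,
    collapse_by_lineage,
    drop_singletons,
)

logger = logging.getLogger(__name__)

DEFAULT_KEYWORDS = (
    "hypothetical",
    "uncharacterized",
    "unknown function",
    "duf",
)


@dataclass
class FunnelConfig:
    """Thresholds and window sizes of the selection funnel."""

    projection_threshold: float = 0.9
    min_effective_tm: int = 2
    hypothetical_keywords: tuple[str, ...] = DEFAULT_KEYWORDS
    annotation_majority: float = 0.5
    lineage_majority: float = 0.8
    window_k: int = 5
    n_perm: int = 99
    top_partners: int = 5
    max_gap: int = 100
    gain_rate: float | None = None  # None -> fit from the data
    loss_rate: float | None = None
    tm_window: int = 19
    tm_threshold: float = 1.6
    min_tm_len: int = 16
    split_len: int = 38

    def __post_init__(self) -> None:
        if not self.hypothetical_keywords:
            raise ValueError("keyword list must be non-empty")
        if not (0.0 <= self.annotation_majority <= 1.0):
            raise ValueError("annotation_majority must lie in [0, 1]")
        if self.min_effective_tm < 0:
            raise ValueError("min_effective_tm must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FunnelConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "hypothetical_keywords" in data:
            data["hypothetical_keywords"] = tuple(data["hypothetical_keywords"])
        return cls(**data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["hypothetical_keywords"] = list(self.hypothetical_keywords)
        return out


@dataclass
class CandidateRow:
    """One family passing every funnel filter, with its evidence."""

    family_id: str
    root_posterior: float
    dollo_root_present: bool
    tm_median: int
    tm_range: tuple[int, int]
    n_members: int
    hypothetical_fraction: float
    lineage_codes: tuple[tuple[str, str], ...]
    partners: tuple[tuple[str, float, float], ...]  # (family, score, p)
    partner_annotations: tuple[str, ...] = ()


@dataclass
class FunnelResult:
    candidates: list[CandidateRow]
    stage_counts: dict[str, int]
    projection: pd.DataFrame
    model: GainLossModel
    tm_summaries: dict[str, FamilyTMSummary] = field(default_factory=dict)

    @property
    def candidate_families(self) -> list[str]:
        return [c.family_id for c in self.candidates]


def filter_membrane(
    projected_families: Sequence[str],
    tm_summaries: Mapping[str, FamilyTMSummary],
    min_effective_tm: int = 2,
) -> list[str]:
    """Keep families whose lower-median effective TM count passes.

    Signal peptides were already discounted per protein, so a family
    whose members' only hydrophobic stretch is a flagged signal peptide
    has effective count 0 and is dropped, as are single-TM families.
    """
    missing = [f for f in projected_families if f not in tm_summaries]
    if missing:
        raise KeyError(f"no TM summary for families: {missing}")
    return [
        f
        for f in projected_families
        if tm_summaries[f].median_effective_tm >= min_effective_tm
    ]


def hypothetical_fraction(
    annotations: Sequence[str], keywords: Sequence[str] = DEFAULT_KEYWORDS
) -> float:
    """Fraction of members whose annotation matches any keyword.

    A member matching several keywords counts once. Families whose
    members carry no annotation at all are treated as fully hypothetical.
    """
    if not annotations:
        raise ValueError("no members")
    lowered = [a.lower() for a in annotations]
    if not any(a.strip() for a in lowered):
        return 1.0
    hits = sum(1 for a in lowered if any(kw.lower() in a for kw in keywords))
    return hits / len(annotations)


def filter_hypothetical(
    families: Sequence[str],
    annotations: Mapping[str, Sequence[str]],
    keywords: Sequence[str] = DEFAULT_KEYWORDS,
    majority: float = 0.5,
) -> list[str]:
    """Keep families where the keyword-matching fraction exceeds majority."""
    kept = []
    for fam in families:
        anns = list(annotations[fam])
        if not any(a.strip() for a in anns):
            logger.info(
                "family %s has no annotated members; treated as hypothetical",
                fam,
            )
            kept.append(fam)
            continue
        if hypothetical_fraction(anns, keywords) > majority:
            kept.append(fam)
    return kept


def _family_members(
    tables: Mapping[str, GenomeTable], orthology: OrthologyMap
) -> dict[str, list[str]]:
    members: dict[str, list[str]] = {}
    for table in tables.values():
        for rec in table:
            members.setdefault(
                orthology.family_of(rec.protein_id), []
            ).append(rec.protein_id)
    return members


def run_funnel(
    tables: Mapping[str, GenomeTable],
    orthology: OrthologyMap,
    proteins: Mapping[str, str],
    tree: SpeciesTree,
    config: FunnelConfig | None = None,
    seed: int = 0,
) -> FunnelResult:
    """Run the full selection funnel.

    Deterministic given ``seed`` (used only for neighborhood permutation
    p-values). Singleton families take part in neighborhoods but not in
    projection. Stage errors propagate with the stage name prefixed.
    """
    config = config or FunnelConfig()
    tree.validate_genomes(tables.keys())
    rng = np.random.default_rng(seed)
    table_list = [tables[g] for g in sorted(tables)]

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"funnel stage {name!r} failed: {exc}") from exc

    matrix = stage(
        "build_matrix", lambda: build_matrix(table_list, orthology)
    )
    proj_matrix = drop_singletons(matrix)
    idx = TreeIndex(tree)
    if config.gain_rate is not None and config.loss_rate is not None:
        model = GainLossModel(config.gain_rate, config.loss_rate)
    else:
        model = stage("fit_rates", lambda: fit_rates(proj_matrix, idx))
    projection = stage(
        "project_to_ancestor",
        lambda: project_to_ancestor(
            proj_matrix, idx, model, threshold=config.projection_threshold
        ),
    )
    projected = sorted(projection.index[projection["projected"]])

    members = _family_members(tables, orthology)
    tm_params = dict(
        window=config.tm_window,
        threshold=config.tm_threshold,
        min_tm_len=config.min_tm_len,
        split_len=config.split_len,
    )

    def tm_stage():
        calls = {}
        for fam in projected:
            for pid in members[fam]:
                calls[pid] = predict_membrane(pid, proteins[pid], **tm_params)
        return summarize_families(
            calls, {f: members[f] for f in projected}
        )

    tm_summaries = stage("tm_prediction", tm_stage)
    membrane_families = stage(
        "filter_membrane",
        lambda: filter_membrane(
            projected, tm_summaries, config.min_effective_tm
        ),
    )

    annotations_by_protein = {
        rec.protein_id: rec.annotation
        for table in tables.values()
        for rec in table
    }
    family_annotations = {
        f: [annotations_by_protein[p] for p in members[f]]
        for f in membrane_families
    }
    hypothetical_families = stage(
        "filter_hypothetical",
        lambda: filter_hypothetical(
            membrane_families,
            family_annotations,
            config.hypothetical_keywords,
            config.annotation_majority,
        ),
    )

    patterns = collapse_by_lineage(
        matrix, tree.lineage_map, majority=config.lineage_majority
    ) if tree.lineage_map else []
    pattern_by_family = {p.family_id: p for p in patterns}

    candidates: list[CandidateRow] = []
    for fam in hypothetical_families:
        partners = partner_frequencies(
            fam, table_list, orthology, k=config.window_k,
            lineage_map=tree.lineage_map,
        )
        partners = attach_pvalues(
            partners,
            table_list,
            orthology,
            n_perm=config.n_perm,
            rng=rng,
            top_n=config.top_partners,
        )
        top = partners.head(config.top_partners)
        partner_tuples = tuple(
            (row.partner_family, float(row.score), float(row.p_value))
            for row in top.itertuples()
        )
        partner_anns = tuple(
            _summarize_annotation(
                [annotations_by_protein[p] for p in members.get(row.partner_family, [])]
            )
            for row in top.itertuples()
        )
        summary = tm_summaries[fam]
        anns = family_annotations[fam]
        pat = pattern_by_family.get(fam)
        candidates.append(
            CandidateRow(
                family_id=fam,
                root_posterior=float(projection.loc[fam, "root_posterior"]),
                dollo_root_present=bool(
                    projection.loc[fam, "dollo_root_present"]
                ),
                tm_median=summary.median_effective_tm,
                tm_range=summary.tm_range,
                n_members=len(members[fam]),
                hypothetical_fraction=hypothetical_fraction(
                    anns, config.hypothetical_keywords
                ),
                lineage_codes=pat.codes if pat else (),
                partners=partner_tuples,
                partner_annotations=partner_anns,
            )
        )

    stage_counts = {
        "n_families": int(proj_matrix.counts.shape[0]),
        "n_projected": len(projected),
        "n_membrane": len(membrane_families),
        "n_hypothetical": len(hypothetical_families),
    }
    logger.info(
        "funnel: %(n_families)d families -> %(n_projected)d projected -> "
        "%(n_membrane)d membrane -> %(n_hypothetical)d hypothetical",
        stage_counts,
    )
    return FunnelResult(
        candidates=candidates,
        stage_counts=stage_counts,
        projection=projection,
        model=model,
        tm_summaries=tm_summaries,
    )


def _summarize_annotation(annotations: Sequence[str]) -> str:
    informative = [a for a in annotations if a.strip()]
    if not informative:
        return ""
    values, counts = np.unique(informative, return_counts=True)
    return str(values[np.argmax(counts)])


def format_tm_range(tm_range: tuple[int, int]) -> str:
    """Render a TM-count range: "7" for 7-7, "3,4" for adjacent, "7–9" else."""
    lo, hi = tm_range
    if lo == hi:
        return str(lo)
    if hi == lo + 1:
        return f"{lo},{hi}"
    return f"{lo}–{hi}"


def render_report(
    result: FunnelResult | Sequence[CandidateRow],
    outdir: str | Path,
    lineage_order: Sequence[str] | None = None,
) -> dict[str, Path]:
    """Write the candidate report as TSV plus a human-readable table.

    Lineage-code columns appear in tree order; absent lineages render as
    "–". Returns the paths written.
    """
    rows = result.candidates if isinstance(result, FunnelResult) else list(result)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if lineage_order is None and rows:
        lineage_order = [lin for lin, _ in rows[0].lineage_codes]
    lineage_order = list(lineage_order or [])
    records = []
    for row in rows:
        codes = dict(row.lineage_codes)
        rec = {
            "family": row.family_id,
            "root_posterior": f"{row.root_posterior:.4f}",
            "dollo_root": str(row.dollo_root_present).lower(),
            "n_tm": format_tm_range(row.tm_range),
            "n_members": row.n_members,
            "hypothetical_fraction": f"{row.hypothetical_fraction:.2f}",
        }
        for lin in lineage_order:
            rec[lin] = codes.get(lin, ABSENT)
        rec["top_partners"] = ";".join(
            f"{fam}:{score:.2f}:{p:.3g}" for fam, score, p in row.partners
        )
        rec["partner_annotations"] = ";".join(row.partner_annotations)
        records.append(rec)
    columns = [
        "family",
        "root_posterior",
        "dollo_root",
        "n_tm",
        "n_members",
        "hypothetical_fraction",
        *lineage_order,
        "top_partners",
        "partner_annotations",
    ]
    df = pd.DataFrame(records, columns=columns)
    tsv_path = outdir / "candidates.tsv"
    df.to_csv(tsv_path, sep="\t", index=False)
    txt_path = outdir / "candidates.txt"
    with open(txt_path, "w") as fh:
        fh.write(df.to_string(index=False) + "\n")
    paths = {"tsv": tsv_path, "txt": txt_path}
    if isinstance(result, FunnelResult):
        summary_path = outdir / "funnel_summary.json"
        with open(summary_path, "w") as fh:
            json.dump(result.stage_counts, fh, indent=1, sort_keys=True)
        paths["summary"] = summary_path
    return paths


def write_manifest(
    path: str | Path, config: FunnelConfig, seed: int, extra: dict | None = None
) -> None:
    """Run manifest: package version, seed, and every threshold used."""
    manifest = {
        "package": "paleomem",
        "version": __version__,
        "seed": seed,
        "config": config.to_dict(),
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
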