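"""Hydropathy-based transmembrane-segment and signal-peptide prediction.

This is a deliberately simple, fully documented hydropathy-plot predictor
(Kyte-Doolittle scale, sliding window), not a reimplementation of an
HMM-based topology predictor. Transmembrane (TM) helices are called as
maximal runs of window-averaged hydropathy above a threshold; a coarse
heuristic flags probable N-terminal signal peptides, which otherwise
masquerade as a first TM helix, and the "effective" TM count discounts
them. Family-level summaries (lower-median and range of effective TM
counts) feed the membrane filter of the candidate funnel.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as _KYTE_DOOLITTLE

#: Kyte-Doolittle hydropathy values; unknown residue X is neutral.
KD_SCALE = dict(_KYTE_DOOLITTLE, X=0.0)

#: First TM segments starting before this residue may be signal peptides.
SIGNAL_START_CUTOFF = 10

#: ... and must end by this residue to look like a cleavable signal.
SIGNAL_END_CUTOFF = 40

#: Window of N-terminal residues searched for the positive charge (K/R).
SIGNAL_CHARGE_WINDOW = 5


@dataclass(frozen=True)
class TMSegment:
    """Predicted membrane-spanning segment, 0-based half-open residues."""

    start: int
    end: int
    mean_hydropathy: float

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass(frozen=True)
class MembraneCall:
    """Per-protein membrane prediction.

    ``effective_tm_count`` discounts the first segment when it is flagged
    as a probable signal peptide.
    """

    protein_id: str
    segments: tuple[TMSegment, ...]
    signal_peptide: bool
    effective_tm_count: int


@dataclass(frozen=True)
class FamilyTMSummary:
    """Lower-median and min-max range of effective TM counts in a family."""

    family_id: str
    median_effective_tm: int
    tm_range: tuple[int, int]


def hydropathy_profile(sequence: str, window: int = 19) -> np.ndarray:
    """Sliding-window mean Kyte-Doolittle hydropathy per residue.

    Positions within ``window // 2`` of either terminus average over the
    truncated window. Empty input yields an empty profile.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    n = len(sequence)
    if n == 0:
        return np.empty(0)
    try:
        values = np.array([KD_SCALE[c] for c in sequence.upper()])
    except KeyError as exc:
        raise ValueError(f"non-amino-acid residue {exc.args[0]!r}") from exc
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(values)))
    idx = np.arange(n)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n, idx + half + 1)
    return (csum[hi] - csum[lo]) / (hi - lo)


def predict_tm_segments(
    sequence: str,
    window: int = 19,
    threshold: float = 1.6,
    min_tm_len: int = 16,
    split_len: int = 38,
) -> list[TMSegment]:
    """Call TM segments as maximal above-threshold hydropathy runs.

    Runs shorter than ``min_tm_len`` are discarded; runs of at least
    ``split_len`` residues are split into ``ceil(run / split_len)`` equal
    parts to approximate multi-helix hairpins fused by the smoothing
    window. Returned segments are disjoint and ordered.
    """
    profile = hydropathy_profile(sequence, window=window)
    above = profile >= threshold
    segments: list[TMSegment] = []
    n = len(profile)
    i = 0
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        run = j - i
        if run >= min_tm_len:
            n_parts = max(1, math.ceil(run / split_len))
            bounds = np.linspace(i, j, n_parts + 1).round().astype(int)
            for a, b in zip(bounds[:-1], bounds[1:]):
                segments.append(
                    TMSegment(int(a), int(b), float(profile[a:b].mean()))
                )
        i = j
    return segments


def predict_signal_peptide(
    sequence: str, segments: Sequence[TMSegment]
) -> bool:
    """Heuristic signal-peptide call given the predicted segments.

    True iff a lysine or arginine occurs within the first
    ``SIGNAL_CHARGE_WINDOW`` residues (the positively charged n-region)
    and the first TM-like segment starts before residue
    ``SIGNAL_START_CUTOFF`` and ends by residue ``SIGNAL_END_CUTOFF``.
    """
    if not segments:
        return False
    first = segments[0]
    n_term = sequence[:SIGNAL_CHARGE_WINDOW].upper()
    has_charge = "K" in n_term or "R" in n_term
    return (
        has_charge
        and first.start < SIGNAL_START_CUTOFF
        and first.end <= SIGNAL_END_CUTOFF
    )


def predict_membrane(
    protein_id: str,
    sequence: str,
    window: int = 19,
    threshold: float = 1.6,
    min_tm_len: int = 16,
    split_len: int = 38,
) -> MembraneCall:
    """Full per-protein prediction: segments, signal flag, effective count."""
    segments = predict_tm_segments(
        sequence,
        window=window,
        threshold=threshold,
        min_tm_len=min_tm_len,
        split_len=split_len,
    )
    signal = predict_signal_peptide(sequence, segments)
    effective = len(segments)
    if signal and segments and segments[0].start < SIGNAL_START_CUTOFF:
        effective -= 1
    return MembraneCall(protein_id, tuple(segments), signal, effective)


def predict_many(
    sequences: Mapping[str, str], **params
) -> dict[str, MembraneCall]:
    return {
        pid: predict_membrane(pid, seq, **params)
        for pid, seq in sequences.items()
    }


def family_tm_summary(
    family_id: str, members: Iterable[MembraneCall]
) -> FamilyTMSummary:
    """Summarize effective TM counts over family members.

    Uses the lower median (``statistics.median_low``), which is robust to
    fragmentary members, and the min-max range.
    """
    counts = sorted(m.effective_tm_count for m in members)
    if not counts:
        raise ValueError(f"family {family_id!r} has no members")
    return FamilyTMSummary(
        family_id,
        int(statistics.median_low(counts)),
        (counts[0], counts[-1]),
    )


def summarize_families(
    calls: Mapping[str, MembraneCall], members: Mapping[str, Sequence[str]]
) -> dict[str, FamilyTMSummary]:
    """Family summaries from per-protein calls and family -> member ids."""
    return {
        fam: family_tm_summary(fam, [calls[pid] for pid in pids])
        for fam, pids in members.items()
    }
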