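# Methods

`paleomem` automates a comparative-genomics workflow for finding
evolutionarily conserved but functionally uncharacterized membrane-protein
families in a set of prokaryotic (typically archaeal) genomes, and for
generating functional hypotheses about them from conserved gene
neighborhoods ("guilt by association"). This note documents the models,
the tunable parameters that matter, the synthetic-data generator that
backs the test suite, and the numerical and design choices that were
genuinely open.

## Phyletic patterns

The basic object is the family × genome member-count matrix built from
per-genome gene tables and an orthology map (arCOG-style `protein_id →
family_id` assignments). Proteins missing from the orthology map are kept
as per-protein singleton families (`SINGLETON:<protein_id>`), so that the
per-genome column sum equals the number of genes and neighborhoods stay
complete; singletons are excluded from rate fitting and ancestral
projection, because a family observed in one genome carries no signal
about the root and would bias the global rate estimates.

For reporting, the matrix is collapsed to per-lineage codes: with presence
fraction φ of a family in a lineage's genomes, the code is `1` (present in
the vast majority) when φ ≥ 0.8, `p` (partial) when 0 < φ < 0.8, and `–`
when φ = 0. The 0.8 quantification of "vast majority" is configurable; the
collapse depends only on presence fractions, so paralog counts never
change a code. Pattern complementarity between two families is computed
over lineages, treating any non-absent code as presence:
`C = (|A ∪ B| − |A ∩ B|) / |A ∪ B|`, which is 0 for identical and 1 for
disjoint patterns and is undefined when both patterns are empty.

## Ancestral projection

Presence/absence of each family evolves along a rooted species tree under
a two-state continuous-time Markov chain with gain rate g (0→1) and loss
rate l (1→0) per unit branch length. Over a branch of length t,

    P(0→1) = g/(g+l) · (1 − e^{−(g+l)t}),
    P(1→0) = l/(g+l) · (1 − e^{−(g+l)t}).

Family log-likelihoods use Felsenstein's pruning algorithm (vectorized
over families); the root combines the conditional likelihoods with a
prior that defaults to the stationary distribution (g/(g+l)) and is
configurable. A family "projects" to the root ancestor when the posterior
probability of presence at the root is at least 0.9 (configurable). A
Dollo parsimony call is reported alongside: the single gain is placed at
the MRCA of all genomes carrying the family, losses are the maximal empty
subtrees below it, and the family is Dollo-root-present iff the MRCA is
the root. Both calls are verified against exhaustive enumeration oracles
in the test suite.

A single global (g, l) pair is shared by all families and fitted by
maximizing the summed log-likelihood with coordinate ascent (log-spaced
grid search per coordinate followed by bounded scalar refinement,
deterministic, with a convergence trace). Only (g·T, l·T) relative to the
tree's time scale is identifiable: doubling all branch lengths and halving
both rates leaves the likelihood unchanged.

Known limitation: a family that is present at the root but loses one
entire root-child clade is statistically indistinguishable from a family
gained once on the other root-child stem; its posterior sits near 0.5 and
it cannot pass a 0.9 threshold. Under the generator's default rates this
affects roughly 5–7% of root-present families and is the dominant recall
loss of the whole funnel. Per-branch rate variation and richer root
priors are out of scope.

## Membrane prediction

The transmembrane predictor is a classical hydropathy-plot method, not an
HMM: per-residue Kyte–Doolittle values are averaged in a sliding window of
19 residues (truncated at the termini), and TM segments are maximal runs
of window mean ≥ 1.6 that are at least 16 residues long; runs of ≥ 38
residues are split into ⌈run/38⌉ equal parts to approximate helix
hairpins fused by the smoothing. These are the classical hydropathy-plot
settings; topology (inside/outside) and cleavage sites are not predicted.

Because window smoothing borrows up to 9 flanking residues from each side,
a 21-residue hydrophobic helix flanked by strongly charged residues (D/E/K/R
at −3.5 … −4.5) erodes to an above-threshold run of ~13 residues and is
*not* called; the same helix flanked by mildly hydrophilic residues
(S/T/G) yields a run of 17–19 residues and is called reliably. This
window-mean arithmetic drives both the predictor's limits and the
generator's sequence composition (below).

Signal peptides are flagged by a deliberately coarse heuristic, reflecting
the well-known failure mode that a cleavable N-terminal signal is predicted
as a first TM: a protein is flagged when a K or R occurs in residues 0–4
(the positively charged n-region) and the first predicted segment starts
before residue 10 and ends by residue 40. The *effective* TM count
discounts the first segment of flagged proteins. Families are summarized
by the lower median of member effective counts (robust to fragmentary or
jittered members) and the min–max range.

## Gene neighborhoods

Operons are predicted as runs of same-strand adjacent genes with
intergenic gaps ≤ 100 bp; the run partition covers every gene exactly
once. Neighborhoods use gene order by start coordinate (nested genes are
kept; no special nesting rule).

For a seed family, each partner family F is scored across genomes:
`n_genomes_adjacent` counts genomes in which some seed gene has an F gene
within k = 5 genes on either side (one count per genome, so paralogs do
not inflate support), `n_genomes_both` counts genomes carrying both
families, and the conservation score is their ratio. Partners co-present
in fewer than 3 genomes are not reported by default: with one or two
co-present genomes the ratio saturates at 1.0 by chance and carries no
evidence of conservation. The number of distinct lineages among adjacent
genomes is reported to expose phylogenetic redundancy of the support.

Significance uses a permutation null that shuffles gene order
independently within each replicon of each genome — the minimal null that
preserves gene content, replicon sizes, and family copy numbers while
destroying synteny. The statistic is the genome-level adjacency count and
`p = (1 + #{null ≥ observed}) / (n_perm + 1)`; at least 19 permutations
are required for any resolution, and the p-value is exactly reproducible
from an integer seed. Calibration under the null is verified empirically
(P(p ≤ α) ≤ α within Monte-Carlo error).

Cassettes are maximal sets of 2–6 families that occur as contiguous runs
containing the seed, order- and orientation-insensitive, in ≥ 3 genomes;
a set is suppressed when a reported superset has the same (or larger)
supporting genome set.

## The candidate funnel

The funnel composes: matrix → rate fit → projection (posterior ≥ 0.9) →
membrane filter (family lower-median effective TM ≥ 2; this excludes
single-TM families and proteins whose only hydrophobic stretch is a
flagged signal peptide) → annotation filter (fraction of members whose
annotation contains a "hypothetical"-type keyword, case-insensitively,
strictly exceeds 0.5; keywords default to hypothetical / uncharacterized /
unknown function / DUF; a family with no annotated members counts as
hypothetical and is logged) → per-candidate partner tables with
permutation p-values and lineage codes. Stage counts are logged as a
funnel summary (n_families → n_projected → n_membrane → n_hypothetical).
The funnel is monotone — relaxing any one threshold can only add
candidates — and its output is independent of genome input order.
Partner annotations are reported as association evidence only; no
function is asserted automatically.

## Synthetic scenarios and what they do (not) show

The generator emulates the statistical structure the analysis assumes,
at desk scale. Defaults (the study condition used throughout the tests):
20 genomes in 5 lineages on a balanced ultrametric tree of height 1.0;
1000 families; root presence Bernoulli(0.5); gain 0.10 and loss 0.15 per
unit branch length (slow gain relative to loss, so presence across both
root subtrees is strong evidence of ancestral presence); 8 planted
cassettes of 3–4 widely distributed families, laid out contiguously with
probability 0.8 (same strand, 10–40 bp internal gaps, i.e. always within
one predicted operon), otherwise scattered; one gene per present family
with 3% paralog probability; 30% membrane families with TM counts drawn
from {2:0.30, 3:0.25, 4:0.20, 5:0.10, 6:0.10, 7:0.05} and member counts
jittered by {−1, 0, +1} with probabilities {0.15, 0.70, 0.15} (floored at
1); 10% single-TM families; signal peptides on 15% of membrane families
and 5% of soluble ones; 35% hypothetical families and 10% annotation
noise (informative families mislabelled "hypothetical protein"). With
these marginals the expected number of ground-truth qualifying families
(root-present ∧ membrane ∧ hypothetical) is 1000 × 0.5 × 0.30 × 0.35 ≈ 52
per scenario. Every draw flows from one integer seed and bundles are
byte-identical across runs.

Protein sequences are compositionally synthetic: a sequence is an optional
signal peptide (Met, then K/R, then a 17-residue hydrophobic core)
followed by alternating hydrophilic linkers (20–40 residues) and
21-residue hydrophobic TM blocks. TM blocks are drawn from {L, I, V, F,
A, M} with weights {0.40, 0.30, 0.20, 0.06, 0.02, 0.02} (mean hydropathy
≈ +3.95) and linkers from {D, E, K, R, S, T, N, Q, G, P} with weights
biased toward S/T/G (mean ≈ −1.24, every residue negative). These weights
come from the window-mean argument above: they guarantee that a planted
TM produces an above-threshold run of ≥ 16 residues while a linker can
never reach the threshold, making the planted truth recoverable by
design. There is no evolutionary sequence model, no compositional
drift, no marginal hydrophobicity — so passing tests show that the
pipeline recovers structure *of the kind it assumes*, not that the
hydropathy predictor rivals an HMM on real proteomes, nor that real
annotation noise is binomial. Gene content likewise evolves strictly by
the same CTMC the projection model assumes (no horizontal-transfer
bursts, no rate variation), so projection accuracy on synthetic data is
an upper bound for real data.

## Numerical and degenerate-input choices

* Lower median (`statistics.median_low`) for family TM counts; ties at
  the annotation majority are exclusive (fraction must strictly exceed).
* All-absent phyletic patterns: Dollo returns (False, 0); complementarity
  of two all-absent patterns is an error.
* Missing branch lengths default to 1.0 (logged); zero-length branches
  are accepted (logged); g = l = 0 is rejected as degenerate.
* Rate fitting searches g, l ∈ [10⁻³, 10] on a 25-point log grid per
  coordinate, refines with bounded minimization, and raises with its
  ascent trace if the summed log-likelihood has not stabilized (Δ < 10⁻⁴)
  within 12 cycles.
* Permutation p-values use the add-one estimator, so p ∈ (0, 1] and can
  never be zero; the seed family as its own partner is rejected.
* Table codes accept `P` as an alias of `p` and `-` as an alias of `–`.
* GFF3 is 1-based inclusive on disk and converted at the boundary; the
  TSV gene-table dialect is already 0-based half-open. Both round-trip
  exactly.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the pipeline at the default
desk scale: oracle equivalences on trees of ≤ 7 leaves (exhaustive
enumeration), rate recovery on 16 genomes × 500 families, the TM contract
on 200 generator proteins, neighborhood recovery over 50–100 independent
scenarios, and the funnel closed loop aggregated over four default
scenarios (~200 ground-truth qualifying families, enough that the recall
estimate's Monte-Carlo error is well below the 0.9 acceptance bound).
The "168 genomes" scale is reachable through `SimConfig` but is not part
of the routine checks.
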