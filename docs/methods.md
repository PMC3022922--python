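# Methods

This note documents the models and procedures implemented in `ap2erf`,
the parameters that matter, and the design choices made where the
underlying workflow left them open.

## Domain detection

Domains are detected with per-kind (AP2, B3) position-specific scoring
matrices. Given a gap-free seed alignment of `n` domain instances, the
weight of residue `a` at column `c` is

    w[c][a] = log2( ((n_ac + κ·bg_a) / (n + κ)) / bg_a )   [bits]

with pseudocount `κ` (default 4) and background `bg` (default uniform
1/20). Every window of profile length is scored by summing weights; a
window is a hit when its score is at least `min_relative_score` times
the profile's maximum attainable score (sum of per-column maxima).
Overlapping candidate hits of the same kind are resolved greedily by
descending score, ties to the leftmost start. There is no gapped
matching inside the window: the domain length is fixed by the profile,
which is adequate for the strongly conserved, indel-poor AP2/B3 cores
but would miss domains with internal insertions — a known limitation.

**Threshold calibration.** The relative-score scale is harsh: losing a
single conserved column costs both the consensus reward and the unseen-
residue penalty, so ~0.6 of the maximum corresponds to ~90% identity to
the consensus. Random 20-letter windows, by contrast, peak far *below
zero* on this scale (measured maxima ≈ −0.4 over thousands of windows).
The default `min_relative_score = 0.45` was therefore calibrated so
that genuine domains up to ~20% divergence from the seed consensus are
retained — the sensitivity regime of SMART-style domain annotation —
while remaining separated from background by a wide margin. The
threshold and pseudocount are both exposed in the API and CLI.

## Gene-model quality control

Three reliability rules are applied to predicted gene models:

* **Long introns**: any intron strictly longer than 10 kb (`max_intron`,
  config-exposed) flags the model; intron lengths are the gaps between
  consecutive exons (1-based inclusive GFF3 coordinates).
* **Fused models**: a protein with ≥ 2 AP2 domains whose nearest
  reference is ERF-family (single-domain architecture) is split into
  one product per domain. Cut points are the midpoints between adjacent
  domain hits — deterministic and conservative; template-guided
  trimming against the nearest homolog is intentionally out of scope.
  Products are suffixed `_a`, `_b`, … in N→C order. A protein whose
  nearest reference is AP2-family keeps its legitimate tandem double
  domain.
* **Pseudogenes**: protein < 100 aa AND ≥ 2 introns > 10 kb. The length
  floor is a package choice (any single-domain ERF protein comfortably
  exceeds 100 aa) and is config-exposed. Pseudogenes are excluded from
  the catalogue.

Splitting conserves domains (each product carries exactly one) and is
idempotent: products re-entering QC are not split candidates.

## Classification

Family follows architecture: one AP2 → ERF; ≥ 2 AP2, no B3 → AP2;
AP2 + B3 → RAV; no AP2 → unclassified (excluded). ERF genes take the
group of their nearest ERF-family reference by global-alignment
identity (Needleman–Wunsch, BLOSUM62, gap open −10 / extend −0.5);
identity counts identical residues over aligned columns excluding any
column with a gap in either sequence, the same "pairwise deletion"
convention used for tree distances. A similarity floor of 0.3 (config-
exposed) prevents forcing distant sequences into groups. A single-AP2
gene whose nearest reference overall is the Soloist exemplar is
reassigned to the Soloist family — nearest-exemplar detection is usable
on arbitrary input, unlike the single-copy-in-genome observation.
Conserved motifs (CM) outside the domain are counted with ≤ 1 mismatch
per motif as corroborating evidence only; they never veto a group call.

## Phylogeny

Distances are p-distances under pairwise deletion, computed from
pairwise global alignments (or from a supplied MSA). Progressive
multiple alignment is deliberately not reimplemented; pairwise
alignment preserves the distance definition while keeping the module
dependency-free. Neighbor joining is the standard Saitou–Nei algorithm
(Q criterion, distance updates `d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2`),
with ties on Q broken by the lexicographically smallest pair of minimal
leaf labels, so trees are reproducible. Negative branch-length
estimates are clamped to zero and counted, with a warning. Bootstrap
supports resample alignment columns with replacement using one shared
column index per replicate; support is the percentage of replicate
trees containing each internal bipartition of the full-data tree.
The implementation is cross-checked in the test suite against a
brute-force re-implementation and against scikit-bio's `nj`.

## Chromosomal landscape

Gene position is the midpoint of the model span. Tandem clusters are
maximal runs of same-group genes on one chromosome with adjacent gaps
≤ 100 kb (config-exposed; the workflow this mirrors gives no numeric
definition of "close distances"). Paralogous segments are consumed as a
BED file (half-open intervals) and genes are assigned by midpoint
containment; segment inference from synteny is out of scope.

## qPCR expression

Relative expression is ΔCt = Ct_HK − Ct_gene, where Ct_HK is the
arithmetic mean Ct of the four housekeeping genes in the same
sample-replicate (arithmetic averaging of Ct is the log-scale
equivalent of geometric averaging of linear abundances). A replicate in
which any housekeeping gene failed is dropped for all genes. A gene is
detectable if any sample has Ct below the detection cutoff (default 40,
config-exposed; a standard plate cutoff). ΔΔCt between stages is the
difference of condition-mean ΔCt and equals the log2 fold change under
the perfect-efficiency (2.0) convention; its SD is that of
replicate-paired ΔΔCt values. Primer efficiencies are consumed as
input (estimated upstream by amplification-curve fitting) and checked
against the inclusive window [1.7, 2.0].

Expression clustering uses Euclidean distance on condition-mean ΔCt
vectors with pairwise-complete columns (minimum overlap 2 conditions,
distances rescaled by the fraction of usable columns; pairs below the
overlap floor are forced to join last) and average linkage.

## DEG calling and enrichment

Genes with |log2FC| ≥ 2 (4-fold) are called up/down; calls backed by a
single replicate pair carry a low-confidence flag rather than being
dropped, because published tables routinely print such rows without an
SD. Group overrepresentation among DEGs uses the one-sided (greater)
Fisher's exact test — the hypergeometric tail P(X ≥ k) for k in-group
DEGs among n DEGs against a catalogue of N genes with K in-group. No
multiple-testing correction is applied to the primary p-value (a single
planned contrast per tissue/direction); a Benjamini–Hochberg column is
emitted alongside for modern use. DEG set algebra uses exact,
case-sensitive gene-name matching: printed tables are inconsistent
about zero-padding (e.g. "VvERF94" vs "VvERF094"), and silently
coalescing such names would fabricate intersections; the bundled
fixtures keep the printed strings.

## Synthetic data generator

The generator emulates the study inputs that are not publicly
deposited. What it plants:

* **Reference panel** — per ERF group, an AP2-domain variant diverged 4%
  from a shared core (tandem/RAV domains 6%, the Soloist 12%) plus 1–3
  group-specific 7-aa motifs; members of a group share flank templates
  outside the domain (whole-protein similarity is what defines the
  groups), lightly mutated per member at a quarter of the target
  substitution rate — a curated panel is far less noisy than genome
  predictions. The Soloist body is a strongly diverged copy of the
  AP2-family template, so it attaches near the AP2 clade in trees, as
  observed for real Soloist genes. Profile seed alignments are the
  realized domain instances of the panel (gap-free by construction).
* **Target proteome** — substitution-only mutated copies of panel
  members (positions preserved, so planted domain coordinates remain
  exact); fused models concatenating 2–3 ERF proteins; models with one
  intron > 10 kb; pseudogenes (< 100 aa, two > 10 kb introns). The
  first up-to-four targets of each group form a tandem run with
  15–35 kb gaps on the group's home chromosome; some genes are left
  unplaced.
* **Ct tables** — housekeeping genes at Normal(24, σ_rep); per-gene and
  per-tissue baseline offsets; a planted log2FC `f` shifts the later
  stage's mean Ct by −f (one PCR cycle = one doubling); 3 replicates
  (the study design states "at least three"); σ_rep = 0.3 Ct, a
  well-run plate; 5 undetectable (all-NA) genes; Ct > 40 becomes NA.
  When no fold changes are supplied, 30 up-DEGs are planted with
  magnitudes uniform in [2.5, 6] log2, half drawn from the enriched
  group (default IX) of a 149-gene catalogue whose family/group
  proportions mirror the grapevine superfamily.

What it does **not** emulate: codon structure and real intron sequence,
insertions/deletions between homologs, alignment uncertainty,
efficiency-dependent amplification curves, or correlated replicate
noise. Passing tests therefore demonstrate correctness of the
computational rules and estimators under the stated noise model, not
robustness to every artifact of real data.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale: catalogues of
~50–200 genes, panels of 43 references, trees up to ~50 taxa, bootstrap
at tens of replicates in tests (the API default is 1000), and 100
simulation repeats for power estimates. All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; identical
seeds give byte-identical output files.

## Known limitations

* No profile-HMM insert/delete states; fixed-length domain windows.
* Split boundaries are inter-hit midpoints, not template-guided.
* Pairwise (not multiple) alignment underlies distances; for highly
  gappy homolog sets, pairwise-deletion p-distances from different
  pairs use different column sets.
* The Fisher test treats the catalogue as fixed and the DEG set as a
  simple random draw; it ignores gene-wise power differences.
* Group assignment assumes the reference panel spans the groups; a
  query from an unrepresented clade is forced to its nearest labeled
  neighbor or left ungrouped by the similarity floor.
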