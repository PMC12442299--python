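# Methods

`isoformetrics` quantifies how alternative splicing changes protein
structure and function by comparing a gene's reference isoform with its
alternate isoforms across six layers: splicing-event annotation, sequence
comparison, structural metrics on predicted models, PTM-site exposure,
expression switching in single cells, and predicted-function (GO) gain/loss.
This note records the models, parameter choices and numerical conventions,
and what the synthetic test data do and do not demonstrate.

## Inputs and assumptions

Structures are single-chain predicted models in PDB format with per-residue
confidence (pLDDT, 0–100) stored in the B-factor column; the CA atom's value
is taken as the residue's pLDDT. Multi-chain files are truncated to the
first chain with a warning; the first alternate location is kept. Transcript
annotations are GTF exon features (1-based inclusive coordinates); all
protein positions are 1-based. MSAs are consumed as aligned FASTA or A3M
(lowercase insertion columns removed), not as predictor-internal feature
files, so the pipeline has no dependency on any structure-prediction
implementation.

## Splicing-event classification

Exon chains of a reference/isoform pair are first normalized to
transcription orientation (on the '−' strand coordinates are negated and
swapped), so "donor" is always an exon's 3' boundary and "acceptor" its 5'
boundary. Exons identical in both transcripts are anchored by longest common
subsequence; the unmatched exons between consecutive anchors are then
classified 5'→3', each exon entering exactly one event:

* internal exons present in only one transcript with the other transcript's
  junction preserved → exon skipping (ES), with a `host` label saying which
  transcript carries the extra exon;
* one internal exon per transcript, mutually non-overlapping, sharing both
  flanking junctions → mutually exclusive exons (MXE);
* a single exon spanning exactly the other transcript's exon–intron–exon
  extent → intron retention (IR), host = the retaining transcript;
* a single overlapping exon pair with exactly one shifted boundary → ADS
  (donor shift) or AAS (acceptor shift), whether the exon is internal or
  terminal — the shifted junction, not the exon's position, decides;
* terminal gaps: mutually disjoint terminal exons joined to the same
  adjacent internal junction → MXE-AFE / MXE-ALE; any other terminal
  difference (shifted outer boundary, extra or missing terminal exons) →
  AFE / ALE. Complex internal substitutions fall back to a single MXE-type
  block, and fully disjoint chains to AFE; these fallbacks keep the
  classification total.

The nine types and the MXE-AFE/MXE-ALE split follow the observation that
alternative first/last exons can behave mutually exclusively and deserve
their own class. Event length is the signed nt change (isoform − reference);
conversion to residues divides by 3 ignoring reading frame (UTRs are not
modeled) and flags lengths that are not multiples of 3.

## Sequence comparison

Global Needleman–Wunsch alignment under BLOSUM62 with affine gaps (open −10,
extend −0.5, end gaps penalized) via Biopython's pairwise aligner; traceback
ties are resolved deterministically by taking the aligner's first optimum.
Sequence identity is identical columns over total alignment length, so end
gaps lower identity. Region labels are derived from the alignment: a run of
isoform-side gaps is "missing" unless adjacent to a run of reference-side
gaps, in which case the two runs form a substitution ("reference replaced" /
"isoform replaced"); aligned columns are "other". Effective MSA depth
down-weights redundancy: Neff = Σᵢ 1/(1 + #{j : I(i,j) ≥ 0.8}), with
pairwise identity counted over mutually non-gap columns and normalized by
the shorter ungapped length (the normalization is configurable; the
redundancy cutoff 0.8 is the standard choice).

## Structural metrics

**SASA.** Shrake–Rupley with a deterministic Fibonacci sphere (960 points,
probe 1.4 Å; element radii C 1.7, N 1.55, O 1.52, S 1.8, H 1.2 Å).
Coordinates are first rotated into a canonical molecular frame (principal
axes ordered by variance, signs fixed by the third central moment, det +1),
which makes the quadrature — and everything derived from it, notably the
integer surface charge — exactly invariant under rigid motions of the input.
Exactly coincident equal-radius atoms contribute one sphere. Relative
accessibility (RSA) divides residue SASA by the Tien et al. (2013)
theoretical maxima; residues with RSA > 0.25 are "surface"/"exposed" (0.25
is the field-standard cutoff; the same threshold is reused for PTM exposure
and isolated-helix detection).

**Surface charge.** Sum of integer formal charges at pH 7 over surface
residues: Asp/Glu −1, Lys/Arg +1, His and termini 0. A per-residue charge
table can be substituted. This is a deliberate simplification of force-field
charge assignment; it keeps the metric integer-valued and
orientation-independent.

**Radius of gyration.** Mass-weighted RMS distance of all atoms from the
mass-weighted centroid, in Å.

**Secondary structure.** A simplified Kabsch–Sander assignment: amide H
placed 1 Å from N along the preceding C=O direction, hydrogen bond where the
electrostatic energy 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) <
−0.5 kcal/mol; helices from consecutive i→i+4 (or i→i+3) turns, sheets from
parallel/antiparallel bridge patterns, everything else loop. Three states
only (G/H/I→H, B/E→E). Residues missing backbone atoms are loop.

**TM-score.** Sequence-guided: the residue correspondence is fixed by the
pair alignment, and only the rigid superposition is optimized, by
fragment-seeded iterative Kabsch refinement (fragment lengths n, n/2, n/4, 4;
inclusion cutoff grown from d0 until ≥3 residues; ≤20 refinement rounds per
seed). d0 = 1.24·(L−15)^⅓ − 1.8, floored at 0.5 Å. The score is computed
normalizing by the reference length and by the isoform length, and the mean
of the two is reported, making the pair score symmetric. On displaced-segment
fixtures the refinement matches a multi-start rigid-search oracle to <1e-6.

**Disorder and isolated helices.** A residue is disordered when the centered
25-residue window mean of pLDDT falls below 70; maximal runs of ≥20 residues
are reported and their coverage is the IDR fraction. These defaults follow
the window-averaged-pLDDT disorder convention and are configurable. Isolated
helices — an artifact of predicted models — are runs of more than 20
consecutive helical *and* exposed residues.

**Quality bands and cohort filters.** Mean pLDDT > 90 is "high", (70, 90]
"confident", (50, 70] "low", ≤ 50 "very low"; boundary values fall to the
lower class, matching the strict inequalities of the band definitions. The
cohort keeps pairs where both members have sequence length < 600 and mean
pLDDT > 70; the optional strict subset additionally removes structures with
any IDR or isolated helix. Filtering is pairwise (both members must pass) so
every retained pair is analyzable.

**Outliers.** Q1 − 1.5·IQR / Q3 + 1.5·IQR with linearly interpolated
quartiles, applied to the per-pair metric differences (isoform − reference);
event-type frequencies are then tallied separately among positive and
negative outliers.

## PTM-site classification

Sites are mapped through the pair alignment. Reference-side sites landing in
an isoform gap are "spliced out"; isoform-only sites that cannot be mapped
back are "spliced in"; mapped sites are compared by exposure (RSA > 0.25) and
become "unchanged", "buried to exposed" or "exposed to buried". The five
categories are exhaustive and mutually exclusive. A site whose stated residue
disagrees with the sequence is flagged and excluded from summary counts; a
mapped column whose two amino acids differ is classified normally but flagged
`residue_changed`, since substituted sites have no canonical treatment. Both
absolute (Å²) and relative accessibility are reported per site.

## Per-residue-effect regression

One row per pair; features are per-event-type length changes in residues
plus the pLDDT difference; the outcome (a standardized metric difference, or
the TM-score) is z-scored with sample SD. Signed mode splits ES and IR by
host transcript; the TM-score outcome, being non-directional, forces
absolute mode with ES/IR unsplit. Ordinary least squares with an intercept
(the default of R's `lm`, whose behavior this reproduces), classical t-test
p-values, no robust errors and no multiple-testing correction across the
effect grid — each cell is thresholded at 0.05, mirroring how such effect
grids are usually displayed. Rank-deficient designs raise an error naming the
collinear columns. Frame-ambiguous pairs are excluded with a warning.

## Isoform switching in single-cell expression

Counts are TPM-normalized (count/length, rescaled to 10⁶ per cell — cells
with no counts stay zero) and log2(TPM+1)-transformed. Cell groups with
fewer than 30 cells are removed before testing. For each gene with ≥2
modeled isoforms, each isoform is tested across groups — Welch's t-test for
two groups (unequal variances, the safer default where pooling is not
specified), one-way ANOVA otherwise — with Bonferroni correction whose
family is *all* isoform×gene tests in the run. The preferred group is the
argmax of mean log expression; fold change is the preferred group's mean TPM
over the mean TPM of the remaining groups; results are ranked by fold
change. A gene is a switch when ≥2 isoforms are significant with distinct
preferred groups; isoforms upregulated in the same group are excluded. The
cross-tissue variant runs identical machinery with tissue as the grouping
factor inside one cell type. Absolute log expression (not isoform
proportion) is tested; TPM's compositionality means a shared expression
shift across a gene's isoforms largely cancels.

## GO scoring

Four channels score each term: sequence (Σ identity·bitscore over hits
carrying the term / over all hits), structure (additionally TM-weighted), PPI
(STRING-score weighted), and Pfam (logistic over family-match indicators
with externally supplied weights — training them is out of scope). All
channel scores are scale-invariant in the raw scores and bounded in [0, 1].
The consensus combiner is a weighted mean over available channels with a
pluggable interface for a trained model; a gradient-boosted consensus can be
slotted in without changing the API. Terms with consensus strictly above 0.6
are "confident"; gains and losses are plain set differences between isoform
and reference confident sets, with no GO-hierarchy propagation (term sets
are compared as given). Enrichment of a term among isoforms of one splicing
type uses the hypergeometric distribution; the reported p-value is the
standard upper-tail sum, with the point probability also available since a
printed formula of this form is sometimes read as a point mass. Heatmap
panels keep terms gained ≥5 times (gain panel) or lost ≥15 times (loss
panel) and drop over-general terms with more than 5000 predictions.

## Synthetic data: what it shows and what it cannot

The generators produce every input class with machine-readable truth:
ideal-geometry backbones (Engh–Huber bond lengths/angles; α-helix φ=−57°,
ψ=−47°; strand φ=−119°, ψ=113°; coil = seeded random-walk dihedrals; N, CA,
C, O and CB except glycine), structure pairs rebuilt from edited per-residue
blueprints, exon chains for all nine event types on both strands, MSAs with
controlled per-row identity, negative-binomial expression (dispersion 0.1,
log-normal cell noise — single-cell full-length counts are overdispersed,
and the exact distribution is a generator parameter), Gaussian regression
designs, and homology-hit tables with exact annotation fractions. All
generators are deterministic given their seed.

Passing tests on these fixtures demonstrates algorithmic correctness —
classification rules, geometry, statistics and their calibration — not
biological fidelity: ideal backbones have no side chains beyond CB, no
packing optimization and no realistic loop conformations; planted burial
uses appended shell residues rather than a refolded interface; expression
noise is simpler than real library effects. Conclusions about real proteomes
require real structures and annotations.

## Problem sizes and tolerances

The default test and acceptance runs use 30–60-residue structures, 100-seed
invariance sweeps, 100 regression replicates at n=500, 150 permutation
replicates, 10 planted-switch seeds and 200 null genes — sizes chosen so the
whole suite completes in a couple of minutes while keeping binomial margins
meaningful (the null false-positive checks use a three-standard-deviation
margin). Rigid-motion invariance is exact (≤1e-6 observed drift ~1e-14)
because SASA uses the canonical frame and TM/Rg/SS depend only on internal
distances. The analytic-sphere SASA check is exact at 960 Fibonacci points
for an isolated atom. The TM-score oracle comparison tolerance is 1e-3;
observed agreement is ~1e-6.

## Known limitations

* nt→residue conversion ignores reading frame; frame-ambiguous events are
  flagged, not resolved.
* The adjacency rule for "replaced" regions is alignment-derived; curated
  isoform annotations may label the same columns differently.
* The simplified Kabsch–Sander assigner omits full DSSP bend/turn states and
  can differ from other assigners near chain ends; cohort-level percentages
  absorb this.
* The formal-charge model ignores pKa shifts, histidine protonation and
  termini.
* The greedy gap classifier guarantees a total, deterministic labeling but
  can collapse pathological multi-event gaps into a single block event.
* Only monomeric models are analyzed; complex interfaces, PTM-dependent
  conformations and ensembles are out of scope.
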