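# isoformetrics

Most genes express several protein isoforms through alternative splicing,
but structural databases usually carry one predicted model per gene.
`isoformetrics` is a Python library for asking, systematically, *what
splicing does to a protein*: it annotates the splicing events separating an
alternate isoform from its reference transcript, measures how the predicted
structures differ, classifies the fate of post-translational modification
(PTM) sites, regresses structural changes on per-residue event lengths,
detects cell-type-specific isoform switches in single-cell expression, and
scores predicted-function (GO term) gain and loss between isoforms. It is
aimed at structural bioinformaticians and transcriptomics groups who have
predicted isoform structures (e.g. AlphaFold-style models with per-residue
pLDDT) and want a tested, reproducible comparison pipeline.

## What it computes

For a reference/isoform pair with sequences, structures and (optionally)
transcripts:

* **Splicing events** — nine types (ES, ADS, AAS, MXE, IR, AFE, ALE,
  MXE-AFE, MXE-ALE) classified from the exon chains after orientation
  normalization and anchoring on shared exons, with signed nt length changes
  ΔL (isoform − reference).
* **Sequence layer** — global Needleman–Wunsch/BLOSUM62 alignment; identity
  I = N_identical / L_alignment; splicing-region labels (missing / replaced /
  other); effective MSA depth
  Neff = Σᵢ 1/(1 + Σ_{j≠i} 1(I_ij ≥ 0.8)).
* **Structure layer** — sequence-guided TM-score averaged over both
  normalization lengths (d0 = 1.24·(L−15)^⅓ − 1.8); three-state secondary
  structure (simplified Kabsch–Sander); Shrake–Rupley SASA and relative
  accessibility (Tien maxima, surface at RSA > 0.25); formal surface charge;
  radius of gyration √(Σmᵢ|rᵢ−r_c|²/Σmᵢ); window-averaged-pLDDT disorder;
  isolated-helix detection; residue contact maps; Q1−1.5·IQR / Q3+1.5·IQR
  outlier calls on metric differences.
* **PTM layer** — each site mapped through the alignment and classified as
  unchanged, spliced out, spliced in, buried→exposed or exposed→buried.
* **Effect regression** — OLS of standardized metric differences on
  per-event-type residue counts (per-residue effects, `lm`-style t-tests).
* **Expression layer** — TPM + log2 normalization, Welch t-test/ANOVA per
  isoform across cell types, Bonferroni over the run, switch calls for genes
  whose isoforms prefer distinct cell types; cross-tissue variant.
* **Function layer** — template-based GO channel scores (identity·bitscore,
  identity·TM·bitscore, STRING weights, Pfam logistic), pluggable consensus,
  0.6 confidence threshold, gain/loss sets, upper-tail hypergeometric
  enrichment.

A `synth` module generates every input class with planted ground truth
(ideal-geometry structures, event-typed transcript pairs, controlled MSAs,
negative-binomial expression with planted switches, hit tables), so the
whole pipeline is testable without external downloads.

## Worked example

`examples/03_pair_comparison.py` builds a 50-residue reference
(helix–coil–helix) and an isoform missing the 10-residue linker, then
compares them:

```
identity 0.800; missing region = residues 26-35 (planted: 26-35)
TM-score (mean of both normalizations): 0.565
d_helix +19.0%  d_charge -2  d_rg +4.19 A  d_pLDDT +2.4
```

The alignment recovers exactly the planted deletion as a "missing" region;
identity is 40/50 aligned columns. The TM-score of 0.565 reflects that the
two helices re-pack once the linker is gone; the isoform is 19 percentage
points more helical (the deleted region was coil), carries two fewer
positive surface charges, and — because the flexible linker dominated the
reference's spread — its radius of gyration differs by 4.19 Å. Differences
are always isoform minus reference.

The other scripts in `examples/` each exercise one capability (per-structure
metrics, splice events, PTM fates, isoform switching, GO gain/loss, the full
pipeline over a manifest). A thin CLI mirrors the pipeline stages:

```bash
isoformetrics splice  --gtf annot.gtf --pairs REF_TX,ISO_TX
isoformetrics compare --ref-pdb ref.pdb --iso-pdb iso.pdb
isoformetrics run     --manifest pairs.tsv --out-dir results/
```

## Layout

```
src/isoformetrics/   io, synth, align, splice, metrics, ptm,
                     regression, expression, go, pipeline, cli
tests/               unit + property + acceptance suites (pytest)
examples/            one narrative script per capability
docs/methods.md      models, parameters, conventions, limitations
```
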