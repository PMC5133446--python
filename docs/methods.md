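# Methods

## Scope and data model

The package analyses functional translational readthrough: suppression of
a stop codon, extension of the protein to the next in-frame stop, and the
functional consequences of the extension (here, a hidden C-terminal
peroxisomal targeting signal). Coordinates follow the stop-relative
convention used throughout the readthrough literature: the stop triplet
occupies +1..+3 and the first 3' base is +4. All sequences are normalized
to RNA on load; DNA input (T) is accepted and converted.

The stop-codon context (SCC) defaults to 10 nt of flank on each side of
the stop. A readthrough extension runs from +4 to the base before the
next in-frame stop; its translation is prefixed with a placeholder 'X'
for the readthrough-position residue, because that residue is decided by
near-cognate tRNA competition, not by the transcript. Transcripts without
a downstream in-frame stop are retained (second stop ABSENT) but excluded
from PTS1 scoring and product ranking: an unbounded extension exposes no
defined C-terminus.

## Readthrough-propensity (RTP) regression

RTP models log10(readthrough %) as an additive function of the nucleotide
identity at each modelled position. The response is logarithmic because
context effects span more than an order of magnitude (roughly 0.1% to
above 4%). Modelled positions default to {stop, +4..+9}; upstream
positions −1..−6 are supported but off by default, since the known
consensus involves only the stop and the +4..+7 window.

Fitting is ordinary least squares on one-hot indicators. Identifiability:
each position's coefficients are re-centred to sum to zero over the
symbols observed at that position, with the removed means absorbed into
the intercept (a pure reparametrization, since every observation
activates exactly one symbol per position). Positions with fewer than two
observed symbols are uninformative and receive all-zero coefficients. A
design that is rank-deficient beyond this structural degeneracy is refit
with a light ridge penalty (λ = 1e−6, intercept unpenalized) and flagged.

The packaged default model is fitted to a 15-row fixture modelled on the
dual-reporter wild-type/mutant SCC series of the MDH1 context: wild type
UGA CUA G at 4.34%, stop-swap and +4 mutants at the 0.07% background, and
+5/+6 mutants at 0.45–0.78%. Because no +7 mutants were assayed in that
series but the established consensus carries a weak G preference at +7,
the fixture includes a +7 calibration series at intermediate readthrough
(1.9–2.1%). This gives the +7 position a coefficient range of ~0.36 log10
units while the untested +8/+9 positions carry zero coefficients; the
design is exactly full-rank (15 observations, 15 identifiable
parameters), so the fit is exact and deterministic.

**Consensus extraction.** Per position the consensus symbol is the argmax
coefficient (ties broken alphabetically and flagged). The consensus
element is the maximal contiguous run of positions starting at the stop
whose coefficient range (max − min) reaches the threshold, default 0.2
log10 units — comfortably between the +7 range (~0.36) and zero, and
meaningful as "this position modulates readthrough by ≥1.6-fold". With
the default model this yields the 7-nt element UGACUAG.

The true LDHB stop-codon context sequence is not bundled; the packaged
`LDHB_LIKE_SCC` is a synthetic stand-in constructed off-consensus so that
the documented MDH1 > LDHB readthrough ordering holds as a model
property. Absolute RTP values are never used downstream — only orderings
and the consensus string.

## PTS1 scoring

No canonical closed-form PTS1 scoring function exists in the package's
scope, so it ships a transparent one: a log-odds position weight matrix
over the terminal tripeptide (positions −3, −2, −1; 20 residues each)
plus per-position residue-class weights (basic, acidic, hydrophobic,
polar/small) over context positions −12..−4. Weights are obtained by
L2-penalized logistic regression (C = 1, lbfgs) on a packaged fixture of
30 PTS1-class and 30 non-PTS1 12-mer termini — synthetic composites built
around the tripeptide classes [SAC][KRH][LM] with basic-leaning contexts
(positives) versus acidic cytosolic termini, ER-retention (KDEL/HDEL)
look-alikes and terminal-L deletions (negatives). Scores depend only on
the last 12 residues. A placeholder 'X' in the terminal tripeptide scores
the position's minimum weight and is flagged.

The functional threshold is the midpoint between the lowest positive and
the highest negative raw training score (falling back to 0 if the classes
were not separated); it is stored in the model object/JSON rather than
hard-coded. The fixture is constructed so the model reproduces the
biologically attested orderings — SKL and SRL above CRL, CRL functional,
terminal-L deletion non-functional — as calibration targets, which is
exactly what a terminal-tripeptide-dominated signal should do; the model
is not a substitute for experiment on novel termini far from the fixture
classes.

## Candidate ranking

RTP⁺ is cohort-relative min-max normalization of RTP into [0, 1] (the
cohort min and max travel with the run for reproducibility); the product
score is RTP⁺ × P(PTS1). Ranking is descending by product, with unbounded
extensions (no product) last, ties broken by RTP then id — fully
deterministic. A degenerate cohort with a single RTP value sets RTP⁺ = 1
for all with a warning. Consensus counting is an exact anchored string
match of the motif at the stop codon.

## Reporter, western and import quantification

Dual-reporter readthrough per replicate is 100 × (hRluc/Venus)_test
divided by the mean blank-subtracted control ratio; the control mean (not
per-replicate pairing) stabilizes the denominator. Blank subtraction
precedes ratio formation. Replicates with Venus at or below blank are
dropped with a warning; a construct losing all replicates is an error.
Summaries are mean ± SEM (ddof = 1). Western readthrough is
100·Ix/(Ix+I0); import efficiency is the background-subtracted post/pre
washout ratio clipped to [0, 1] with a warning when post exceeds pre.

Group comparison is the two-sided equal-variance Student's t-test with
significance at p < 0.05. The degenerate zero-pooled-variance case is
defined as t = 0, p = 1 for equal means (no evidence of difference) and
t = ±inf, p = 0 otherwise, rather than NaN.

## Mass-spectrometric residue identification

The variant database holds 21 entries: each proteinogenic residue, and a
one-residue gap, at the marked readthrough position (alphabetical, GAP
last). Digestion is tryptic with the Keil rule (cleave after K/R except
before P) and one missed cleavage by default; peptides carry parent
coordinates and missed-cleavage counts. Masses are monoisotopic, from a
versioned residue-mass table shipped as package data (water 18.010565,
proton 1.007276; carbamidomethyl-C +57.021464 and oxidation-M +15.994915
as variable modifications, enumerated over all placements). Fragment ions
are b/y only, no neutral losses, charge 1.

Matching: a peak list's precursor is tested against every
readthrough-spanning peptide of every variant, over allowed charges
{1,2,3} (restricted to the spectrum's charge when declared) and all
variable-mod combinations, within the precursor tolerance (stringent
default 3 ppm; a 20 ppm XIC-style window is carried in the config for
chromatogram-level work). The relaxed tier is a precursor match alone.
The stringent tier additionally requires fragment coverage of the
readthrough position: numbering inter-residue bonds 1..n−1, a matched b-
or y-ion at a bond at-or-left of the position and one at-or-right of it
(a side with no interior bond — position at a peptide terminus — is
bounded by the precursor mass itself and is waived, which is what makes
the C-terminal-Arg peptide of the Arg variant identifiable). Leu/Ile are
mass-identical and always reported as the ambiguity label "L/I"; Lys/Gln
(Δ0.036 Da) are resolvable at 3 ppm for tryptic-scale peptides and are
never pre-collapsed. Intensities are parsed and carried but never used
for identification; no W:R incorporation ratio is quantified.

## Conservation

Extensions are compared under C-terminal-anchored alignment (right
justify, pad left): the C-terminus is the biologically aligned end since
it carries the PTS1, and the extensions are short enough that a full MSA
heuristic would add parameters without information. Column conservation
is the modal-residue fraction over non-gap rows. The clade contrast
reports mean PTS1 probability for mammalian versus non-mammalian
vertebrate entries; entries flagged clade `other` (e.g. amphibian
exceptions to the SRL rule) are excluded. The packaged orthologue FASTA
is a synthetic fig-style set (CRL mammals, SRL non-mammals) — labelled
synthetic in its records — not database sequences.

## Synthetic data generators

One global seed fans out to independent per-generator streams
(`default_rng([seed, k])`), so each generator is deterministic and
byte-identical under a fixed seed, and every generator emits its ground
truth alongside its output.

* **Transcriptome** — random sense-codon CDS (default 40 codons) ending in
  a random stop with a random 60-nt tail, plus planted transcripts whose
  SCC and extension are specified; the planted default is a consensus
  UGA CUAG context with a 19-residue extension ending CRL. The planted
  downstream nucleotides and extension peptide are cross-validated
  (mismatches and internal stops are errors), and background stop
  contexts are resampled if they would match the consensus motif, so
  planted counts are exact ground truth. Background tails may or may not
  contain an in-frame stop — as in real 3'UTRs — so a fraction of the
  cohort exercises the ABSENT-extension path.
* **Reporter plates** — venus = baseline·e^N(0,σ²), hrluc =
  venus·(ρ/100)·control_ratio·e^N(0,σ²), with the 100% control always
  present; σ defaults to 0.1 (multiplicative log-normal noise, since
  readouts are positive arbitrary-unit intensities) and 5 replicates,
  within the 3–7 range typical of such assays. The noise cancels in
  expectation in the ratio-of-means estimator, which the tests verify at
  n = 1000 (bias < 5% of truth).
* **Peak lists** — for each requested variant, the shortest
  readthrough-spanning fully-cleaved peptide's precursor (charge 3 for
  the Trp variant, 2 for Arg, matching their tryptic sizes) plus its b/y
  ladder, all with Gaussian relative jitter (default 1 ppm, so the 3 ppm
  stringent tolerance recovers ~99.5% of seeds), uniform decoy peaks, and
  optional all-decoy spectra whose precursors are resampled away from
  every database peptide.
* **Orthologues** — clade-templated 19-residue extensions with per-site
  substitution noise everywhere except the terminal tripeptide, which is
  the conserved signal by construction.

What the generators do **not** emulate: transcript secondary structure
and any cis-element beyond the SCC, isotope envelopes, chromatography,
co-eluting peptides, real phylogenetic correlation structure, or plate
position effects. Tests passing on this synthetic data therefore
demonstrate the correctness of the computational pipeline under its own
model assumptions, not the biological performance of the models on new
transcripts.

## Problem sizes and numerical choices

The default synthetic cohort is 1 planted + 99 background transcripts;
digestion cross-validation runs 500 random sequences against a
brute-force enumerator; reporter consistency uses 1000 replicates;
jitter-recovery checks 60 seeds. These sizes give stable statistics while
keeping the full suite around a couple of seconds. Floating-point
comparisons in tests use explicit absolute tolerances; the RTP fit is
exact on the packaged fixture (residual RMSE ~1e−14), and model
serialization round-trips coefficients exactly via JSON.
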