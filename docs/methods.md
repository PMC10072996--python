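# Methods

## Problem and scope

`cpascan` implements a two-stage discriminative analysis of
cleavage-and-polyadenylation (CPA) sites. Stage one separates
constitutive CPA sites from the remainder of genic sequence using only
representations of the five core elements (UGUA, PAS, U-rich, CA/UA,
DSE). Stage two separates constitutive sites from *cryptic* sites — loci
the stage-one model scores as highly as real sites — using U1 snRNP
recognition proxies and a panel of RBP motifs. A synthetic pre-mRNA
generator with planted elements provides ground truth so that every stage
is testable without external downloads.

## Coordinates and sequence conventions

All coordinates are 0-based half-open (BED convention). Sequences are RNA
(`ACGU`) internally; DNA input is transcribed on read. A CPA *site* is a
single base, the cleavage position; a window of flank *f* spans
`[site − f, site + f)`, so the site base is the first base of the
downstream half (the convention is arbitrary — the literature writes
"−250 to +250" without fixing which half holds the site — but it is
applied consistently everywhere, including minus-strand extraction, which
returns the transcribed-strand sequence with the site base at offset
*f*).

## Motif scoring

**PWMs.** A PWM is scored per placement as the odds ratio against a
background composition: product over positions of
`(p(base) + ε, renormalised) / background(base)` with pseudocount
ε = 10⁻³ per cell and a uniform background by default (both
configurable). This equals `10^log10(odds)` — the linear-domain
"relative-affinity" representation — computed directly as the odds
product. A uniform PWM therefore scores exactly 1.0 everywhere, which the
tests pin down. Too-short bins score the PWM's worst-path odds (computed,
not hard-coded).

**k-mer counts.** The DSE k-mer feature counts all occurrences of
G, U, GG, GU, UG, UU inside a bin; overlapping occurrences count.

**PAS hexamer PWM.** Built by count-weighting the 13 PAS variants
(AAUAAA-dominated usage weights shipped as data); column *j* is the
weighted frequency of each base at position *j*.

**U1 scorers.** Two proxies for U1 snRNP recognition, both authored here
as deliberately simple, deterministic scorers: (i) a duplex score pairing
each 9-mer antiparallel against the U1 snRNA 5' terminus (ACUUACCUG) —
Watson–Crick pairs weigh 1.0, G:U wobbles 0.4, so the donor consensus
CAGGUAAGU attains the maximum of 9.0; (ii) a 5' splice-site log-odds
score from a 9 × 4 donor-site frequency table (standard human donor
position frequencies; an externally computed table, e.g. from a
maximum-entropy model, can be loaded from file). Splice-site scores stay
in log domain; thermodynamic hybridization models are out of scope, but
precomputed score tracks can be injected wherever a scorer is accepted.

## Feature geometry

Baseline: 500 nt windows, 30 nt bins, 10 nt step → 48 bins; with the
15-representation default registry, 720 features. Cryptic stage: 140 nt
windows, 20 nt bins, 10 nt step → 13 bins. Per bin and representation the
feature is the maximum score over placements lying **fully inside** the
bin. Placements never straddle bin borders — this keeps columns
independent, and the overlapping bins (step < bin) mitigate the boundary
loss; whether straddling should be allowed is genuinely open, and
full-containment is the package's choice. Feature names are
`repid@bin<k>[<start>..<end>)` and are stable across runs so importance
heatmaps are comparable.

The default registry's five RBP-style PWMs are synthetic stand-ins for an
externally supplied motif panel (tagged `source_tag="synthetic"`); real
CISBP-RNA/ENCORE-shaped panels arrive as plain-text PWM files through a
YAML registry. The exact 15-representation composition is registry data,
not code.

## Datasets

One constitutive site per gene: the maximal PSE × RPM site lying in (or
at the inclusive end of) the longest-isoform 3'UTR; significance ties
break toward the most 3'-distal site (strand-aware). Genes without a
qualifying site are dropped and reported. Negatives tile the same genes
(500 nt / 100 nt step, fully inside the span) and are removed iff their
overlap with any known site's ±250 nt region **strictly exceeds** 10% of
the window (50 nt); a 50 nt overlap is retained, 51 removed. The overlap
is computed against the ±250 nt site region rather than the single
cleavage base — a single-base criterion would make a 10% threshold
meaningless. Training negatives are subsampled (seeded, uniform) to 30:1.
Chromosomes 1–14 train, 15–22 + X test; chrY and unplaced contigs are
excluded, and both `chr1` and bare `1` dialects are normalised.

Cryptic sites: maximal runs of consecutive scanned bases with probability
strictly above D (default 0.69, the constitutive-mean convention), merged
at gap 0, discarded if the run overlaps any known site's ±250 nt region,
and represented by the run's peak-probability base.

## Classifiers

Random forest: `RandomForestClassifier` with minimum split 5 and balanced
class weights; 30 000 trees at full scale. Desk-scale runs (tests, CI,
the synthetic benchmark) use 300 trees — a documented scale-down; forest
size is a config value, not a constant. Logistic regression: L1 penalty,
C = 0.1 (baseline) or 0.0018 (cryptic stage), tolerance 0.01, saga,
balanced class weights.

The logistic family is fit on standardized features
(`StandardScaler → LogisticRegression` pipeline). The raw linear-domain
odds span ~10 orders of magnitude across representations, which leaves
the L1/saga problem badly conditioned: fully converged fits on raw
features plateau well below the forest's discrimination on identical
data, while standardization is scale-honest (feature ranking is done in
the standardized space) and converges in a few dozen epochs. The forest
consumes raw values — it is scale-invariant.

"Top" features are ranked by coefficient magnitude, ties broken by name.
`collapse_pas_dse` reduces the matrix to two columns (row-max over a
named PAS cell set and DSE cell set) for the deliberately impoverished
PAS/DSE model. Forest importances are impurity importances (non-negative,
summing to 1); heatmaps reshape importances to representation × bin, with
optional per-row max-abs normalization.

At desk scale the cryptic-stage strength C = 0.0018 drives all
coefficients to zero (it was tuned for ~10⁴–10⁵ training sites); the
package keeps it as the stage default, and the tests that need a
non-degenerate stage-two fit use the baseline strength 0.1 explicitly.
The only stage-two claims asserted at the default strength are structural
(column counts, sparsity monotonicity, determinism).

## Evaluation

AUROC (pairwise concordance, ties half) and AUPRC via the step estimator
(average precision), not trapezoidal interpolation — interpolated
precision is optimistically biased. Because AUPRC depends on prevalence,
evaluation subsamples negatives (seeded) to a fixed excess: 30:1 by
default, 50:1 as the precision-recall-plot convention. Both conventions
are config values.

## Whole-gene scanning

Scanning evaluates every window placement (one per base). The
per-representation per-offset scores are computed once along the gene and
the bin grid slides over them; this is bit-for-bit identical to
featurizing each extracted 500-mer (a tested contract, not an
approximation) and reduces cost from O(length × window) to O(length). A
track maps placements to putative CPA bases at `start + flank`,
strand-aware. "Top site is constitutive" uses a ±50 nt matching tolerance
between the argmax-implied base and the annotation (config; the matching
window is not something the headline fraction convention pins down), with
probability ties resolved toward the constitutive site. Mutation scoring
applies point edits to a window copy and rescores with the same model;
the two-stage score is the plain product of stage probabilities.

## Synthetic benchmark

The generator plants elements at literature-anchored offsets relative to
the cleavage base: UGUA start uniform in [−100, −30]; PAS start −30 ± 2;
a 6-base U-run starting within ±15; C/U+A at the cleavage base; an
8-base G/U run starting in [+20, +32] (ending by +40). Background
composition defaults to A/U-rich (A 0.30, C 0.20, G 0.20, U 0.30),
matching the genome's low G/C content. Element *strength* interpolates
consensus → background as a per-position corruption probability;
*inclusion* is the probability the element is planted at all.

Default element parameters (inclusion/strength): UGUA 0.60/0.85,
PAS 1.0/0.97, U-rich 0.80/0.75, CA/UA 1.0/1.0, DSE 0.95/0.92. The
asymmetry is deliberate: real constitutive sites carry a near-ubiquitous
PAS and strong DSE, while UGUA (a short word common in background) and
the degenerate U-rich element are weakly informative — the planted data
are meant to reproduce that importance structure, not give all five
elements equal weight. The PAS is planted as the canonical AAUAAA by
default; usage-weighted variant sampling is an option
(`pas_variant_sampling`) that makes a sizeable minority of sites carry
weakly scoring minor variants and recovery correspondingly harder.

Cryptic decoys are planted upstream of the site (≥600 nt from site and
edges, ≥350 nt apart, Poisson rate 0.3/kb) with a partial element set;
the default policy is `pas_only` (policies with other subsets, including
`no_pas`, exist for stage-two experiments). Optional weak alternative
annotated sites (lower PSE × RPM by construction, unless significance
scrambling is requested) exercise the constitutive-selection rule, and an
optional U1-planting mode inserts the donor 9-mer at a fixed −40 offset
from decoys so the positional profile contrast is visible in medians.

Scale defaults: 400 genes, log-normal lengths with median 5 kb (σ = 0.30)
on chr1–22+X round-robin, alternating strands, 300 nt spacers. Real
pre-mRNAs have a median nearer 23 kb; 5 kb is the package's desk-scale
choice — at 3 kb a gene yields only ~26 tiling windows of which ~13
survive the overlap filter, too few to sustain 30:1 subsampling, while
5 kb leaves comfortable headroom and keeps the full pipeline under a
minute of featurization.

**What passing synthetic tests do and do not show.** The generator
emulates element composition, positioning, usage metadata and decoy
structure. It does not emulate splice structure, conservation,
expression covariates, isoform heterogeneity, or realistic motif
degeneracy beyond per-position corruption. Synthetic AUROC ≈ 0.99 says
the pipeline recovers planted structure under its own assumptions — it
is a correctness check, not a forecast of real-data performance, and the
headline real-data figures in the literature (AUROC ≈ 0.97–0.98, ~59% of
genes topped by the constitutive site) require PolyA-DB-style
annotations, a real genome and real motif panels through the documented
real-data interfaces.

**Generator–analytic consistency.** In pure background sequence the
brute-force per-base rate of all-five-element co-occurrence (window
anchors: UGUA start in [i−100, i−1], PAS in [i−30, i−11], UUUU in
[i−15, i+14], CA/UA at i−1, G/U 8-run start in [i+10, i+49]) is compared
with the analytic product. Under the A/U-rich default background the
empirical rate lands within two-fold of the uniform-model product: the
A/U bias inflates per-placement match probabilities while occurrence
clumping of the self-overlapping patterns (UUUU, G/U runs) deflates
per-window hit probabilities, and the two effects largely cancel. Under
a strictly uniform background the clumping effect alone puts the ratio
near 0.30.

## Numerical and degenerate-input policy

Odds are computed as log-sums then exponentiated per offset (no running
products). Bins shorter than a motif score the representation's floor.
Empty window sets produce empty matrices with full column naming. Scores
outside [0, 1] where probabilities are expected, single-class training
labels, insufficient negatives, out-of-bounds windows and malformed files
raise typed errors rather than clipping or warning. Every stochastic step
(subsampling, shuffles, the generator) takes an explicit seed;
`run_pipeline` records parameters and SHA-256 checksums of outputs so
reruns are verifiable.

## The analytic specificity module

The expected-occurrence approximation `n_variants × W / A^k` uses W
placements (not W − k + 1), following the convention of the quoted
estimates it reproduces. Two modes exist because the headline joint value
is only reachable from the rounded per-element factors: `printed` mode
multiplies the conventionally quoted values (0.39 × 0.063 × 0.11 × 0.13 ×
0.156 = 5.5 × 10⁻⁵, one per ~18 kb; 0.022 for the usage-weighted PAS,
one per ~52 kb), `exact` mode carries full precision. Two quoted factors
are not plain roundings (0.1171875 is quoted truncated as 0.11; 0.125
rounded up as 0.13) and are stored as explicit quoted values. The
usage-weighted PAS probability 0.022 is an input constant. No G/C-content
correction is applied; the uniform-alphabet assumption understates
element frequency in A/U-rich sequence (see the consistency check above).

## Known limitations

- The U1 scorers are simple position-wise models; they rank donor-like
  sequences sensibly but are not calibrated against thermodynamic or
  maximum-entropy references.
- The default RBP panel entries are synthetic stand-ins; conclusions
  about specific RBPs require real motif files.
- The cryptic-stage default strength is only meaningful at real-data
  sample sizes (see above).
- Scanning scores every placement independently; no smoothing or peak
  deconvolution is applied to tracks beyond the run-merging rule.
- `select_constitutive` falls back to the full gene span for genes
  without a 3'UTR annotation rather than dropping them.
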