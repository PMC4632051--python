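# Methods

## Scope and model

The package implements the *comparison method* for detecting translational
selection: codon preferences are inferred from the difference in codon
usage between genes at the extremes of the expression distribution, rather
than from a correlation across all genes. The statistical units are genes;
every class-level quantity is a mean of per-gene values with its standard
error, so the Welch *t*-tests on ΔRSCU are tests over genes, not pooled
codon counts. Genes that lack an amino acid contribute nothing to that
amino acid's codon means.

## CDS validation

A sequence is accepted when it starts with ATG, has length a multiple of
three, contains only A/C/G/T (after uppercasing and U→T mapping), and has
no internal stop codon. A trailing stop is permitted and stripped before
counting; only internal stops disqualify. The start ATG is counted as an
ordinary Met codon — Met is one-fold degenerate and therefore invisible to
RSCU, ΔRSCU and Fop, so the choice only affects total codon-site tallies
and amino-acid frequencies (where counting the initiator Met is the
consistent treatment of "all residues"). Rejection is a return value with
a reason code (`not-multiple-of-3`, `no-start-codon`, `ambiguous-base`,
`internal-stop`), never an exception, so filter reports are exact
partitions of the input.

## Expression classes

RPM is read count over total mapped reads × 10⁶; RPKM divides further by
CDS length in kb (length = 3·n_codons). The default class metric is RPM,
with RPKM behind a flag. Class boundaries are rank-based: the lowest
`round(0.05·N)` genes are "low", the highest `round(0.05·N)` "high". Ties
are broken by gene id (stable sort), making the split deterministic and
exactly reproducing the class sizes in tests; zero-count genes are kept
and rank lowest. Because ranks are invariant under monotone transforms,
classes from RPM equal classes from raw counts.

## ΔRSCU, significance tiers and optimal-codon selection

Per codon, the two-sided Welch (unequal-variance) *t*-test compares the
per-gene RSCU values of the high and low classes. Welch is the default
because class variances genuinely differ (high-expression genes are more
biased, hence more variable family-wise); the equal-variance test is not
exposed. Tiers follow the conventional star annotation: *strong*
P < 0.001, *significant* P < 0.05, *putative* 0.05 ≤ P < 0.1, else *ns*.
When both samples are constant the Welch statistic degenerates; we report
t = 0, P = 1 for a zero shift and t = ±∞, P = 0 for a pure mean shift.
Raw P values drive tier assignment; a Benjamini–Hochberg q column is
emitted alongside for the reader but is never used for selection, since
the published analyses this mirrors report raw P over the 59 codon tests.

Optimal codons are those with positive ΔRSCU and a non-ns tier. The
primary optimal codon per amino acid is chosen among optimal codons
*restricted to the best tier present*: largest ΔRSCU, ties by smaller P,
then alphabetical codon. The tier restriction encodes the convention that
a better-supported codon outranks a larger but weaker effect (the
proline CCA-over-CCT case in the packaged fixture). Note the published
table this fixture transcribes is itself not perfectly consistent with
any single tie rule: for one valine entry it bolds the larger-Δ putative
codon over a significant one; our rule picks the significant codon there.
Counts and ending-nucleotide tallies are unaffected, and the fixture
records the published choice in its `bold` column. Candidate codons with
P at or slightly above 0.1 are honored only through an explicit override
list (tier `candidate`, ranked below putative), never promoted
automatically.

## Fop, ENC, GC3

Fop's denominator is the count of codons whose amino acid possesses a
primary optimal codon — Met/Trp and optimal-less amino acids are excluded,
following the classic frequency-of-optimal-codons construction; genes with
no eligible codon get NaN and are dropped from downstream correlations.

ENC uses Wright's estimator with six-fold families (Leu, Ser, Arg) kept
intact. Families with fewer than two observations are skipped; a missing
three-fold mean (Ile absent) is imputed as the average of the two- and
four-fold means, per Wright's recommendation; any other missing class
leaves ENC undefined for that gene. Estimates are clamped to [20, 61]
(finite genes with uniform usage overshoot 61 because F̄ₖ < 1/k at finite
m; the clamp makes the analytic bounds exact). A mean homozygosity of
exactly zero (possible only in tiny degenerate genes) is reported as 61 —
no usable bias signal.

GC3 defaults to degenerate codons only: ATG and TGG have no synonymous
choice at the third position, so including them (possible via a flag)
only dilutes the signal. AT3 = 1 − GC3 by construction.

## Size/complexity scores

The packaged S/C table anchors twelve values stated in the source
literature (Gly 1, Ala 4.8, Ile 16.0, Ser 17.8, Lys 30.1, Asp 32.7,
Asn 33.7, Glu 36.5, Phe 44.0, Arg 56.3, Tyr 57.0, Cys 57.2) and fills the
remaining eight (Val, Leu, Thr, Pro, Gln, Met, His, Trp) with synthetic
estimates constrained to preserve the high-S/C membership set
{Cys, Phe, His, Met, Arg, Trp, Tyr} at the >40 cutoff. The estimates are
flagged in the data file and the table is user-overridable
(`--sc-table`); Pr_HighSC and the high-set membership tests depend only on
the anchored values and the membership constraint, not on the estimated
magnitudes.

## Synthetic transcriptomes

The generator plants, per gene *g* with log-normal true expression *e_g*
(log-mean 3, log-sd 2) and cohort-standardized score *z_g*:

- **codon bias**: within each family, probability mass
  `b(e) = b_max · logistic(k·(log e − midpoint))` (defaults `b_max` 0.9,
  `k` 1, midpoint = the expression log-mean) moves from the background
  distribution to the planted optimal codon. The background weights
  third-position A/T at `at3_background` (presets 0.6177 / 0.6520 /
  0.5529 — the source species' overall AT contents, applied here to the
  third position, which is the quantity the analysis is sensitive to).
- **amino-acid tilt**: gene-level amino-acid probabilities
  ∝ baseline · exp(tilt·z); preset tilts give Glu/Asp/Asn/Lys positive and
  Arg (plus other negatives) coefficients scaled to the published
  correlation ordering. Residues are i.i.d. across positions — the
  analysis consumes only composition, not structure.
- **length**: `n_codons = round(exp(α − β·z + ε))` with α = ln 300,
  β = 0.25, ε ~ N(0, 0.65), floored at 30 codons. The log-sd 0.65 matches
  the breadth of real CDS-length distributions and ensures both expression
  extremes contain genes beyond the 500-codon threshold used by the
  long-gene robustness check.
- **reads**: Poisson with mean ∝ e_g · length, scaled to total depth
  2×10⁶.

Sequences are valid CDS by construction (forced ATG start, stops never
sampled internally, trailing TAA). One RNG stream per run makes output
byte-identical under a fixed (config, seed).

What the generator does **not** emulate: real protein sequences and their
covariance structure, isoforms, assembly artifacts, sequencing error,
mutation-selection population dynamics, or any linkage between genes.
Passing recovery tests therefore shows the *statistical machinery* is
correct and well-calibrated at realistic scale — not that real
transcriptomes satisfy the generative assumptions.

## Problem sizes and calibration checks

Recovery and null analyses use 2000 genes at 2×10⁶ reads — comparable in
class sizes (100 genes per 5% tail) to the source datasets, and chosen as
a scale at which class means are stable. The strong-bias preset
(`b_max` 0.9) yields complete (17/17) recovery of the planted set; the
null preset (no bias, no tilt, no length coupling) yields on average ~1
positive-Δ codon at P < 0.05 out of 59 — consistent with a two-sided 5%
level applied one-directionally — and near-zero Fop–RPM correlation.
Simulated effect sizes are intentionally stronger than the published
genome-scale correlations (planted recovery is a power check, not a
quantitative reproduction); the quantities reproduced exactly are the
fixture-derived ones: primary-codon counts, ending-nucleotide tallies,
mean |ΔRSCU| (to the ±0.0005 precision attainable from 3-decimal printed
inputs), the tie-break and override behavior, and the analytic ENC bounds.

## Known limitations

- The selection tie rule cannot reproduce every published bold choice
  (see above); disagreements are confined to within-amino-acid codon
  identity, never counts.
- Eight S/C scores are estimates; analyses leaning on individual
  non-anchored magnitudes should supply a complete table.
- ENC is undefined for genes observing fewer than two codons in every
  class other than the imputable three-fold; such genes are flagged, not
  silently dropped at generation.
- No multiple-testing correction is applied to tier assignment by design;
  the BH column supports readers who want it.
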