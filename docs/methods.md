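# Methods

## What the package computes

`savkit` compares distributions of predicted functional-effect scores for
single amino acid variants (SAVs) across variant classes. The score axis is
the SNAP2 convention: a raw score s in [-100, +100], with s > 0 projected to
"effect" and s <= 0 to "neutral"; other predictors (CADD raw score, SIFT on
[0, 1], PolyPhen-2 categories) attach to the same SAVs and are projected or
rescaled where needed. The classes compared are:

* within-human SAVs split by allele frequency (LDAF): rare (< 1%),
  uncommon (1% <= f < 5%), common (>= 5%); the boundaries are closed on the
  common side, so f = 0.05 is common and f = 0.01 uncommon;
* cross-species SAVs: residue differences between a human protein and its
  ortholog, evaluated in a back-mutated human context (see below);
* random mutational backgrounds: all 19 non-native substitutions per
  position (`all19`), or only substitutions reachable by a single
  nucleotide change of some codon pair (`snv_possible`).

The descriptive device is the cumulative effect curve — for every integer
threshold t, the fraction of a set's scores at or above t ("above a certain
value" is implemented as >= t; the neutral side uses <= t). Sets are
compared with the two-sample Kolmogorov-Smirnov test, and a set's effect
content is summarised by the effect AUC: the empirical fraction of scores
strictly above 0. The effect AUC is deliberately a plug-in mass, not a
kernel-density integral: it lives on the same scale as the binary effect
fractions and avoids an arbitrary bandwidth.

## Statistical machinery

**Bootstrap SEM.** Uncertainty of a set's score mean is the standard
deviation (ddof = 1) of 100 resample means (resamples of size n, with
replacement). The 99.7% confidence band of a cumulative curve is the curve
shifted by +-3 SEM *along the score axis*. All bootstrap randomness flows
from one explicit seed.

**KS test.** D is the supremum gap between the two ECDFs; the p-value comes
from the asymptotic Kolmogorov distribution with effective size
n·n'/(n+n') (scipy's `ks_2samp(method="asymp")`). p-values below 2.2e-16
are floored and formatted as "< 2.2e-16". D itself is verified in the test
suite against a brute-force ECDF scan over all pooled evaluation points.

**Correlations.** Pearson r between two methods' scores over complete pairs
(pairs with either score missing are dropped; listwise deletion only on
request), with the analytic standard error SE_r = sqrt((1 - r^2)/(n - 2)).
SIFT scores are inverted (1 - score) before correlation so that high always
means effect.

**Accuracy from the extremes.** On labelled reference data, effect accuracy
at threshold t is TP/(TP+FP) among scores >= t and neutral accuracy is
TN/(TN+FN) among scores <= t. Empty denominators yield "undefined" (NaN),
never a silent 0 or 1.

**Error-corrected fractions.** A binary classifier with false-positive rate
FPR and false-negative rate FNR distorts the observed effect/neutral split.
The corrected fractions move the misclassified mass back while conserving
the total:

    Neff* = Neff - FPR·Neff + FNR·Nneu
    Nneu* = Nneu - FNR·Nneu + FPR·Neff

Defaults FPR = 0.22 and FNR = 0.23 are one minus the reported positive
(78%) and negative (77%) accuracies of the effect classifier at its default
threshold; both are configurable since they are external performance
estimates, not quantities this package can measure. The correction notation
is read as multiplication by a rate (FPR·Neff), the only reading that
conserves mass.

## Alignment and cross-species extraction

Human/ortholog pairs are aligned globally with affine gap scoring in the
EMBOSS-needle convention: BLOSUM62, gap open 10, gap extend 0.5, a gap of
length k costing open + (k-1)·extend, and terminal gaps free by default
(flag to penalise them). The implementation is Biopython's
`PairwiseAligner`; optimality is cross-checked in the tests against an
exhaustive enumeration of all global alignments for short sequences. Equal
scoring alignments are resolved deterministically by taking the first
alignment of the library's ordered iterator — the choice of tie-break does
not matter as long as it is fixed.

Two identity measures are computed because they serve different roles:
PIDE "excluding gaps" (identical columns / gap-free columns) is the
pair-acceptance filter (default minimum 0.70), while *ungapped identity*
(identical columns / length of the shorter sequence) ranks candidate
orthologs; ties go to the lexicographically smallest candidate id. The
ungapped-identity denominator is a design choice — the shorter-sequence
convention penalises fragmentary candidates, which is the failure mode the
best-ortholog selection must guard against.

Every mismatching gap-free column yields one cross-species SAV under the
back-mutation convention: the ortholog residue o is introduced into the
human sequence at the human coordinate p (the *context* sequence), and the
SAV recorded is o -> h at p (notation e.g. `V42L`), so that applying the
alternate residue on the context reproduces the human sequence exactly.
Gap columns produce no SAV; masked human positions (ambiguity codes) are
skipped with a warning. The same operation serves hominid and more distant
comparisons; only the inputs differ. The "housekeeping" restriction keeps
only proteins present, with at least one SAV, in every species' set and in
the within-human set.

## SNV reachability

Reachability of an amino-acid substitution by a single nucleotide change is
derived from the standard genetic code (packaged as a TSV resource;
alternative tables can be supplied): (a, b) is reachable iff some sense
codon of a differs from some sense codon of b at exactly one position.
Stop codons never participate. The relation is *codon-agnostic* — it asks
whether any codon pair connects the residues, whereas the actual codon at a
genomic site could make fewer substitutions reachable. This is the right
null for a transcript-free analysis, but it slightly over-counts
reachability relative to a transcript-aware enumeration; a nucleotide-level
mutation model (transition/transversion weights, CpG effects) is out of
scope. Random background sets are drawn uniformly without replacement from
the pooled (protein, position, alternate) candidates of all proteins, so
long proteins contribute proportionally more.

## Synthetic data: what it emulates and what it does not

The generators stand in for exome-consortium variant calls and predictor
runs, which are external to this package. They emulate the *statistical
shape* of those inputs:

* **Proteome** — uniform-random sequences; 60 proteins of 100-400 residues
  by default. Real proteomes have composition bias and domain structure;
  none of the analyses here depend on that.
* **Variant sets** — sampled without replacement over (protein, position,
  alternate); default class counts 7,530 rare / 29 uncommon / 40 common,
  the published exome composition scaled by 1e-3 so rare dominance is
  preserved at desk scale. LDAFs are uniform on sub-ranges strictly inside
  each class, so classification always round-trips.
* **Scores** — a two-component Gaussian mixture per set label: neutral
  component N(-50, 15), effect component N(+50, 15), truncated to
  [-100, 100] by resampling (clipping would pile atoms on the boundaries
  and distort AUC checks). With this separation, the effect-component
  weight equals the score mass above 0 to about 1e-3, so the generating
  effect fraction is directly recoverable as the effect AUC. Default
  weights: common 0.61, rare 0.48 (the contrast the pipeline exists to
  detect), uncommon 0.55; random backgrounds 0.50/0.53; cross-species sets
  0.40 (hominid) down to 0.25 (fly), more neutral with distance. Real
  predictor score densities are not two-component Gaussians; passing the
  recovery tests shows the *pipeline* measures what it claims on known
  ground truth, not that real data has this shape.
* **Orthologs** — per-position substitutions at a configurable rate
  (defaults 0.001 hominid to 0.25 fly, all above the 70% identity filter),
  no indels; alignment therefore recovers exactly the substituted
  positions, which makes extraction exactly checkable.

Every generator is a pure function of (config, seed). Sub-seeds are derived
per entity by combining the seed with a CRC-32 hash of the entity's
identifier, so enlarging a proteome leaves previously generated sequences
unchanged.

## Pipeline and reproducibility

`run_comparison` (YAML config or mapping) executes load/simulate ->
classify -> curves/statistics -> enrichment, writing `report.json`, per-set
score/SAV tables and curve tables (threshold, fraction, +-3 SEM band). The
report contains no timestamps, so identical config + seed gives
byte-identical output. `verify_report` (CLI `--recompute`) re-derives every
per-set statistic and KS D from the persisted tables and checks agreement
to 1e-9. Filter counts are logged per stage and balance exactly
(records_in = records_out + drops). Plots are intentionally not produced;
no asserted number may depend on a figure.

Enrichment follows two slightly different published filters, kept distinct
rather than collapsed: "more than one SAV and *over* 50% strong" (strict
fraction) and ">= 2 SAVs and *at least* 50% strong" (non-strict); the
comparison mode is a spec switch (`fraction_strict`). Localization folds
are unweighted protein fractions (observed subset fraction / expected
background fraction over all SAV-bearing proteins); no statistical test is
attached, only the ratio. A coverage predicate (distinct SAV positions /
protein length) is available for the residue-coverage variants of the
filter.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: parameter
recovery uses 10,000 scores per class (binomial noise on an effect AUC is
~0.005 there, comfortably inside the +-0.02 recovery band); oracle
equivalence uses 500 KS pairs at n <= 12 and 200 alignment pairs at length
<= 6 (the exhaustive alignment enumeration grows as a Delannoy number and
is only feasible for short pairs). Proteins longer than 6,000 residues are
excluded by default, matching the length limit of the upstream predictor.
Degenerate inputs fail loudly: empty score sets, single-label references,
zero-variance correlations, fractions not summing to 1, undefined PIDE
(alignments with no gap-free column) all raise typed errors rather than
returning defaults.

## Known limitations

* Cross-species extraction trusts the given pairing; no orthology
  inference, codon-level alignment, or transcript selection.
* VCF handling trusts the CSQ annotation for protein coordinates; when
  several transcript blocks are annotated, the first block containing
  `missense_variant` is used (the upstream convention is not specified).
* Only unique-SAV counting is implemented; per-person (genotype-weighted)
  analysis is out of scope.
* The SNV-reachability relation is codon-agnostic (see above).
* FPR/FNR for error correction are user inputs, not estimated from data.
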