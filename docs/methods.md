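# Methods

## Model and procedure

`dicodex` maps a coding sequence to a scalar expressivity score, the
geometric mean of per-token contributions, computed in four schemes: tokens
are codons (arity 1) or overlapping adjacent codon pairs / dicodons
(arity 2), and contributions are estimated from plain token counts
(relative adaptiveness `a`) or expression-weighted counts (`f`). The
codon/unweighted corner of this 2×2 is the classic CAI.

Contribution estimation is per synonymy class. For codons a class is the
set of synonyms of one amino acid; for dicodons it is the set of pairs
encoding one *ordered* dipeptide (at most 400 classes over the 3721 sense
pairs of the standard nuclear code — the only code supported; the map is
table-driven via Biopython's translation table 1 so others could be added).
Within each class the counts are divided by the class maximum, so every
observed class has a top member at exactly 1 ("translationally optimal")
and all values lie in (0, 1].

Sequence handling follows the conventions of the CAI literature extended
to pairs: sequences with more than 50 sense codons pass QC (51 is the
minimum; the trailing stop does not count toward length); the first codon
and the first dicodon (positions 1–2) are discarded, since initiation
context obeys different constraints; stop codons and stop-containing
dicodons are never counted. Out-of-frame records and records with
ambiguity characters are dropped and logged; internal stop codons (rare
annotation artifacts) do not reject a record — only the affected tokens
are skipped. Duplicate gene IDs keep the longest CDS by default
(configurable: first/error). Dicodons are *overlapping* pairs (codon i
with codon i+1), the reading used in the codon-pair-bias literature; a
non-overlapping mode exists for sensitivity analysis.

The index is computed in the log domain, `exp(mean(log C))`: weighted
dicodon contributions reach the 1e-12 floor, so a naive product underflows
for sequences with thousands of tokens. `L` in the exponent is the
retained token count of the scheme's arity (L−1 codons, L−2 dicodons for
a clean L-codon CDS).

## Reference sets, weights, evaluation

Contributions are estimated on a reference set `S_p`: the genes (with both
sequence and expression data) whose expression is strictly above the p-th
percentile (linear-interpolation percentile); `S_0` is everything.
Percentiles {99, 97, 95, 90, 80, 0} are the conventional choices and are
defaults in the CLI; reference sets are built per sample. Weighted counts
use `w = exp(E)` when the profile is tagged log-normalized (microarray
pipelines deliver replicate-averaged log values; the exponential base is
configurable) and `w = E` for linear TPM. The stored weighted counts are
normalized by the total weight for interpretability; the normalization
cancels in the per-class ratio, and the ratio is formed from the raw
weighted sums so that constant weights reduce `f` to `a` bitwise.

Evaluation correlates indexes with expression per sample (Pearson or
Spearman). Pearson is computed against *linear* expression levels by
default — log-normalized values are exponentiated before being treated as
expression levels — with log and as-stored views available; Spearman is
invariant to that choice, and likewise invariant to squaring the
contributions. Schemes are compared across samples or replicates with a
two-sided paired t-test on the per-sample correlation vectors (identical
vectors are an error, not a NaN; no multiplicity correction by default, a
Bonferroni option exists). Length bias is probed by re-correlating within
the short (< 20th length percentile) and long (> 80th) strata.

Pair-level structure is probed two ways. `expected_vs_observed` joins the
directly estimated dicodon table with the products of codon contributions
(`C(c1)·C(c2)`), one row per sense dicodon; pairs with observed/expected
far below 1 are used more rarely than their codon composition predicts.
`low_contribution_screen` flags dicodons whose weighted contribution falls
below a threshold and reports the overlap with a supplied list of known
inhibitors (the 17 experimentally confirmed yeast pairs ship as a
constant). The screen is an explicit threshold filter, not a clustering
procedure.

## Numerical choices

* **Pseudo-counts (unweighted path only).** A zero count inside an
  observed class becomes 0.5 before division (the CAI tradition), keeping
  log-domain indexes finite without distorting observed ratios.
* **No pseudo-counts on the weighted path.** Weighted counts are real
  numbers and a weighted zero is informative — near-zero `f_d` values in
  highly expressed genes are the screening signal — so zeros are kept and
  floored at `epsilon`.
* **Epsilon = 1e-12** is the floor for members of wholly unobserved
  classes and for weighted zeros; it is orders of magnitude below any
  meaningful contribution, so it cannot mask real signal. Both epsilon and
  the pseudo-count are configurable.
* Contribution tables serialize to TSV at 17 significant digits and are
  parsed with round-trip float precision, making table → file → index
  pipelines bit-stable.

## The synthetic-data generator

The generator produces the study conditions for all recovery experiments;
real data are not required anywhere in the test suite. Each gene draws a
log-expression `E ~ Normal(2.0, 1.5)` and a length uniform in 100–600
codons (2000 genes by default); amino acids are i.i.d. uniform. Codon
choice is coupled to expression through a logistic link: with probability
`π = logistic(α (E − E0))` (α = 2, E0 = the expression mean, so the
most-expressed genes approach fully biased usage and the least-expressed
are unbiased) the amino acid's preferred codon is used, otherwise a
uniform synonym. The preferred codon per amino acid is a fixed map
(alphabetically first synonym by default). On top of this single-codon
bias, a set `D_inh` of 17 inhibitory dicodons is avoided specifically by
highly expressed genes: scanning left to right, a codon completing a pair
in `D_inh` is resampled away from pair-forming codons with probability
`π · strength` (strength 0.9). Sequences are `ATG + body + TAA`; every
emitted record passes QC. Identical parameters give byte-identical output,
and the exact truth (expression, π, preferred map, `D_inh`) is serialized
alongside.

**Composition of the default `D_inh`.** Each planted pair combines a
preferred codon with the non-preferred codon of a two-codon amino acid.
This composition is chosen for identifiability at genome scale: a pair of
two rare codons essentially never occurs in a high-expression reference
set of a few hundred genes, so its targeted depletion cannot be
distinguished from its baseline rarity, while a pair of two optimal codons
remains the maximum of its synonymy class even when depleted, which the
per-class normalization hides. Pairs with exactly one suboptimal codon
occur often enough to measure and are never class-optimal, so the planted
effect is detectable in principle — which is the property the recovery
tests are meant to exercise.

**What the generator does not emulate.** Real amino-acid composition,
length–expression correlation, GC/context effects, mRNA stability and
secondary structure, tissue-specific usage, and measurement noise in
expression values. Passing the recovery tests therefore shows that the
estimators detect coupled codon- and pair-level structure at realistic
sample sizes, not that any particular organism satisfies the model.

## Scales used by the checks

The automated checks run at the generator's default conditions
(2000 genes, ~700k tokens). Scheme comparisons use the S_97 weighted
reference mirroring the headline scheme, with correlations on linear
expression, repeated over five seeds for the paired test. The
observed/expected recovery of planted pairs uses unweighted tables on
S_80: with ~400 reference genes the counts are dense enough for stable
ratios, and the pseudo-count keeps never-observed pairs from collapsing to
degenerate zero ratios that would otherwise crowd the bottom of the
ranking (on the weighted tables, thousands of dicodons share the epsilon
floor at high percentiles, making a full-table rank statistic
uninformative there). The low-contribution screen itself runs on the
weighted S_90 table, where avoidance by highly expressed genes drives the
planted pairs to the floor.

## Known limitations

* Dicodon tables have 3721 parameters; at small reference sets (S_99 on a
  few thousand genes) many pairs are unobserved and the weighted dicodon
  index degrades — visible in the scheme comparisons as a widening gap
  between Spearman (robust) and Pearson-on-log correlations.
* The generator's uniform amino-acid usage makes dipeptide classes
  equally likely, which slightly flatters dicodon estimation relative to
  real proteomes.
* Only the standard nuclear genetic code is implemented.
* `expected_vs_observed` reports ratios for all 3721 pairs including those
  with near-floor expected values; downstream consumers should filter on
  `expected` when interpreting extreme ratios.
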