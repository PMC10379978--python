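# Methods

`haplodyn` reanalyzes haplotype-resolved bulk RNA-seq of a stress
time-course: ten pooled libraries (control at 0/24/48/72 h, 200 mM NaCl and
25% PEG at 24/48/72 h), quantified per gene and per allele.  This note
records the models, the parameter choices that matter, and what the
synthetic harness does and does not establish.

## Quantification

FPKM(g, j) = count(g, j) x 1e9 / (length_bp(g) x library_size(j)).  The
library size is the column sum of assigned fragments — raw sequenced-read
totals are not available downstream of counting.  Gene length from GFF3 is
the merged-exon length of the longest transcript, falling back to the
1-based inclusive gene span; both alleles of a pair use the gene length
unless per-allele models are supplied.  Expression classes use the
boundaries low <= 5 < medium-low <= 20 < medium <= 100 < high.  Sample
clustering uses Spearman correlation over genes with FPKM > 1 in at least
one sample ("any" is the permissive reading; an "all" switch exists) and
average linkage on 1 - rho; the linkage choice is ours, average being the
common default for sample dendrograms.

## Differential expression

With one pooled library per condition no dispersion is estimable, so the
negative-binomial dispersion is fixed at phi = BCV^2 with BCV = 0.1
("square-root dispersion" 0.1).  For a treated/control pair the counts are
rescaled to the geometric-mean library size (rounded half-to-even back to
integers; a documented simplification of the quantile-to-quantile
pseudo-count adjustment used by the package that popularized this test).
Conditional on the equalized sum s, the null law of the treated count is
the two-group NB conditional with equal size parameters 1/phi — a
beta-binomial with both shape parameters 1/phi — and the two-sided p-value
sums all outcomes no more likely than the one observed (minimum-likelihood
rule, capped at 1).  A 1e-6 absolute slack on the log-pmf absorbs gammaln
round-off when collecting tied outcomes; genuine pmf spacings are many
orders larger.

Effective library sizes default to median-of-ratios normalization: the
treated column sum is rescaled by the median treated/control ratio of
library-scaled counts over genes observed in both conditions.  Plain
column-sum scaling is available (`normalization="library"`), but strongly
asymmetric differential expression shifts the column sums (composition
bias) and measurably inflates the false discovery rate of the fixed-
dispersion test; the median-ratio default keeps the typical non-DE gene at
zero fold change, the same rationale as TMM/median-of-ratios in the
standard count-based DE frameworks.  TMM itself (trimmed weighted means) is
deliberately not implemented.

Significance is BH-adjusted within each comparison at alpha = 0.05;
direction needs q <= alpha and a non-zero shrunken log2 fold change
(prior count 0.5 on both sides).  The "multifactor" union set is the
direction-consistent union over the six pairwise comparisons: with one
library per condition no interaction term is estimable, so a pooled union
is the honest surrogate; genes called up in one comparison and down in
another are reported separately as conflicting.

A discrete exact test is conservative at small counts: its size at
p <= 0.05 is ~0.03 at conditional sums of ~50 and approaches 0.05 only
for sums in the thousands.  The calibration check therefore uses deeply
sequenced simulated libraries (log-mean 7.5), where the discreteness is
negligible; at shallow depth the test errs on the conservative side, never
the anticonservative one.

## Allele-specific expression and bias dynamics

A pair is biased in a condition when one allele's FPKM is at least twice
the other's (inclusive boundary: ratio exactly 2 counts as biased — the
boundary must be pinned for tests and is measure-zero on real data).  The
comparison is multiplicative (a >= 2b), so no division and hence no
pseudocount enters the call itself; the configurable epsilon = 0.001
guards only reported log-ratios.  Pairs whose higher allele stays below
0.5 FPKM are "not expressed" and excluded — the criterion is stated
without a floor, but an unfloored rule would call 0.002 vs 0.001 FPKM
biased.  Both knobs are configurable.

Per stressed time point the collapsed biased/no-bias triplet over
(control, NaCl, PEG) — treated samples compared to the control at the same
time, falling back to 0 h only when the matched control is absent — maps
to seven observable categories.  Responsiveness compares collapsed status
against control: conserved (no change), salt-specific (only NaCl differs),
drought-specific (only PEG differs), both.  The identities
salt = both + salt-specific, drought = both + drought-specific,
responsive = universe - conserved hold exactly by construction.  Bias that
flips direction between conditions (A-biased to B-biased) is conserved
bias for categorization — the category table is direction-blind — but is
counted in `direction_flip_*` diagnostic columns.  Percentages are
reported half-up to two decimals.

## Co-expression network

Unsigned weighted network: a_ij = |Pearson cor|^beta, beta the smallest
power with scale-free fit R^2 >= 0.85 (signed R^2 of the log-log degree
regression; fallback to the best-fitting power, preferring 6 on ties).
Topological overlap: TOM_ij = (sum_u a_iu a_uj + a_ij) /
(min(k_i, k_j) + 1 - a_ij) with zeroed diagonal internally, TOM_ii = 1.
Modules come from average-linkage clustering on 1 - TOM with a *static*
branch cut (default height 0.95); clusters under 80 genes go to grey.
This is a deliberate simplification of dynamic tree cutting, whose many
unstated parameters would make label-exact parity untestable; planted-
module recovery is the quality bar instead.  The module eigengene is the
first right-singular vector of the standardized member expression,
sign-aligned to correlate positively with the module mean profile (fixing
the PC sign makes results deterministic).  Modules with eigengene
dissimilarity 1 - cor < 0.3 are merged iteratively, closest pair first,
recomputing eigengenes after each merge.  Module-trait correlation uses
one-hot (treatment, time) indicators — the only construction readable off
a per-sample correlation heatmap — with two-sided t-tests at n - 2 df.
Hubs pass |GS| > 0.2 (any trait) and |MM| > 0.8 (own module), ranked by
within-module edge count at adjacency >= 0.3; per-gene edge counts also
feed the connectivity tiers (>= 5, >= 50 edges) used in the ASE
intersection.

For transcriptome-scale input the pipeline builds the network on the
most variable 2,000 genes passing the FPKM >= 5 filter (configurable), the
usual practice for weighted co-expression analysis at this scale.

## Enrichment and intersections

Over-representation only (the analysis asks for overrepresented terms):
one-sided hypergeometric upper tail per term, BH across terms, q < 0.05.
The universe defaults to genes passing the low-expression filter
(configurable; the choice between annotated and expressed universes is
data-dependent and left open).  Term maps are generic two-column
term/gene files; no ontology-graph propagation is attempted.  Upset
accounting reports exclusive-region cardinalities, which partition the
union by construction.

## Synthetic data generator

The generator emulates the ten-library design.  Per gene pair: baseline
mean fragment count log-normal (default log-mean 5, log-sd 1, about 10^6
fragments per library at 5,000 genes); a fraction pi_bias = 0.3 of pairs
carries a baseline allelic log2 ratio with magnitude in
`log2_bias_range` (lower bound >= 1 so truth-biased pairs meet the
twofold rule in expectation) and the allele-A share 2^r/(1+2^r);
per-treatment DE effects (pi_de = 0.1, |log2FC| in 1-3, constant across a
treatment's time points); optional latent-factor modules whose members
share a per-sample log-scale factor tuned to a target expression
correlation; log-normal size factors (sd 0.1).

Counts are gamma-Poisson: one biological factor G ~ Gamma(1/phi, phi) per
(gene, sample) shared by the two alleles, each allele Poisson(G x mean x
allele share).  Marginally both alleles and their sum are NB with
Var = mu + phi mu^2 at BCV 0.1, which is what the DE test assumes at gene
level; summing two *independent* NB alleles would instead halve the
effective gene-level dispersion and silently break calibration.  Sharing G
also means the allelic ratio carries only Poisson noise, matching the
biology (biological variation acts on the gene's expression, not
independently on its alleles).

Bias dynamics are switched per time point by drawing the joint (NaCl, PEG)
collapsed outcome conditional on the control state.  The joint form is
essential: in the observed tea-plant category table, losing bias under the
two osmotic stresses is strongly correlated (for control-biased genes the
keep/lose odds under NaCl differ by a factor of ~20 depending on the PEG
outcome), so independent per-treatment Bernoulli switches cannot reproduce
the observed seven-category proportions in expectation.  The independent
model remains available as `BiasSwitch.independent`.

`table1_preset()` calibrates the joint switches so the expected category
proportions, conditional on a pair being biased somewhere, equal the
observed proportions exactly at every time point (verified in closed form
by `expected_category_proportions`).  The preset sets pi_bias = 0.3 — the
observed tables constrain only the ratio of biased to gained-bias pairs,
and 0.3 keeps the required gain mass feasible — bias magnitudes in
log2 2-4, and deep baselines (log-mean 6.5, log-sd 0.8, ~1.8e7 fragments
per library at 20,000 pairs) so that twofold calling noise does not leak
across categories.

## What the harness does and does not show

Passing tests show: the accounting is exact on any input; the exact test,
TOM, BH, and hypergeometric tails agree with independent oracles; the
classifier recovers planted truth under the generator's assumptions.  The
generator omits mapping bias between haplotypes, SNP-level read
assignment, transcript-length changes, batch effects, and any dependence
of library composition beyond DE/bias effects, so recovery rates here do
not certify performance on real allele-resolved data — in particular the
twofold rule has no error control and inherits reference-mapping biases
whole.

Module recovery is evaluated on a replicated design (4 libraries per
condition, 40 samples; 3 planted 100-gene modules at target correlation
0.8 among 600 network genes inside a 3,000-gene transcriptome).  With
single pooled libraries (10 samples) the sampling sd of a pairwise
correlation is ~1/3, which caps achievable partition accuracy regardless
of algorithm; the replicated setting isolates the clustering machinery
from that design limit.  The surrounding transcriptome matters too:
planting half of a tiny transcriptome in modules distorts the library
sums and couples all genes through FPKM normalization, an effect that is
negligible at realistic module-to-transcriptome ratios.

## Degenerate inputs and numerical conventions

Empty count files, truncated rows, duplicate ids, negative or fractional
counts, unknown treatments, treated samples without matched controls, and
infeasible simulation configurations all raise typed errors.  Constant-
expression genes are excluded from correlation-based steps with a warning.
Zero-sum exact tests return p = 1.  Rounding of reported percentages is
decimal half-up; BH ties are preserved by stable sorting.  All stochastic
code draws from a single seeded generator, and identical configuration
plus seed reproduces every output byte-for-byte.
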