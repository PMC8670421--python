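# Methods

`stratiscope` implements the downstream statistics of a depth-stratified
marine prokaryotic metatranscriptome: from an ORF x sample count table with
taxonomy and raw functional predictions to consensus annotations,
normalized matrices, diversity estimates, ordination/permutation inference,
and taxon-resolved gene-system investment ratios. This note records the
models, the defaults and why, and the choices made where the design was
genuinely open.

## Input model and global filters

The counting unit is the ORF predicted on assembled transcript contigs.
Counts are non-negative integers with a positive length per ORF; taxonomy
is a domain-to-genus lineage (prefix rule: once a rank is `unclassified`,
all lower ranks are) plus a boolean rRNA-overlap flag computed upstream.
Two global filters run before any analysis: removal of rRNA-overlapping
ORFs and subsetting to Bacteria + Archaea. The two commute, and removed +
retained always equals the input count (asserted in tests).

## Consensus CAZyme classification

Three prediction tools contribute: an alignment tool (percent identity),
a profile-HMM tool (coverage) and a peptide-pattern tool (hits and hit
frequency). Single-tool ORFs are dropped when identity < 50 %, coverage
< 0.5 or hits < 10; metrics exactly at a threshold are retained (exclusion
uses strict `<`). For multi-tool ORFs, candidate families are ranked by
(1) the number of tools voting for the family, then (2) a summed
normalized quality score: identity/100, coverage, or
min(1, hits/`hits_cap`) x (frequency / the ORF's maximum frequency), with
`hits_cap` = 100. The top family is kept; exact ties break
lexicographically and are logged. The combination rule is monotone in
every metric and scale-free, but the precise arithmetic is a package
choice, so `hits_cap` is configurable and the provenance column records
which rule fired. The implementation is held equal to an independently
coded brute-force enumerator over an exhaustive boundary grid (126
tool-combination x metric-level cases).

Peptidases map Pfam profile hits to MEROPS families (best bit score per
ORF; unmapped accessions go to a side report, never fail the run).
Transporters take the best-scoring TCDB hit per ORF after profile-level
overrides; the shipped defaults correct the two Pfam domains with
known-bad TCDB mappings (PF00909 -> Amt ammonium channel, TC 1.A.11;
PF00654 -> ClC chloride channel, TC 2.A.49). Marker genes (radA, amoA,
hcd, amt) are gated on the profile database's gathering score; hcd labels
come from an upstream phylogenetic placement and pass through as given.
One ORF may carry labels in several systems (a transporter can also be
marker amt) but never two CAZyme families.

## Normalization

* `cpm`: count / library size x 1e6.
* `tpm`: per-kilobase rate / sample rate total x 1e6 (length unit:
  kilobases; the choice only moves a constant).
* Abundance filter: keep ORFs with >= 5 cpm in >= 2 samples, computed once
  on the full prokaryote matrix. The comparison is `>=` ("at least
  5 cpm"); a `strict` flag switches to `>`. The filter is deliberately
  not idempotent: re-filtering survivors would shrink cpm denominators.
* `hellinger`: sqrt of per-sample relative abundance; columns then have
  unit norm, making Euclidean geometry (PCA/RDA/Ward/PERMANOVA)
  appropriate for sparse counts.
* `srs` (scaling with ranked subsampling): counts are scaled to a common
  depth `C_min` (default: the smallest library), integer parts kept, and
  the remaining counts assigned one each to the largest fractional parts.
  Ties are resolved by a seeded uniform draw, the only stochastic element;
  totals are exactly `C_min` and every value sits within 1 of its scaled
  value. Because the rule is deterministic away from ties, seed-averaging
  reproduces the scaled counts only where fractional parts tie — the
  Monte-Carlo tests exercise exactly that regime.

## Diversity

Chao1 uses the bias-corrected form S_obs + F1(F1-1)/(2(F2+1)) (the classic
F1^2/2F2 form is available but undefined at F2 = 0). Pielou's J is Shannon
entropy (natural log) over ln(S_obs), undefined below two categories.
Both run on SRS-normalized matrices (equal column totals are asserted;
non-integer input is rejected with a pointer to SRS). Depth-layer
comparisons use one-way ANOVA with Tukey HSD; layers with a single sample
are excluded with a warning.

## Ordination and inference

PCA is the SVD of the column-centered sample x ORF Hellinger matrix;
explained fractions are eigenvalues over total variance and scores x
loadings reconstruct the centered data (asserted to 1e-8).

Predictor preparation replaces below-detection NH4+ with 0.001, z-scores
all covariates, and prunes collinearity greedily: while any pairwise
|r| >= 0.9, drop the member of the worst pair with the larger mean |r| to
the rest; then drop the largest VIF until all VIF < 10. The survivor set
matches exhaustive minimal-removal search on small fixtures.

RDA regresses the centered Hellinger matrix on the predictors by least
squares; the fitted matrix is eigen-decomposed, R^2 is the constrained
fraction and adjusted R^2 uses Ezekiel's formula (both verified against
R vegan to 1e-6 on a shared fixture). Permutation inference (default 999
permutations, explicit seed):

* global test — free permutation of sample rows;
* per-axis tests — the k-th eigenvalue of the re-fitted model under free
  row permutation (a deliberate simplification of sequential-partial axis
  testing; conservative for trailing axes);
* marginal (Type-III) variable tests — Freedman–Lane: rows of the
  reduced-model residuals are permuted on top of the reduced fit. Freely
  permuting raw responses instead collapses power whenever the remaining
  predictors carry strong signal; Freedman–Lane keeps the empirical
  type-I error at nominal level (0.03–0.07 at alpha = 0.05 in the
  acceptance simulations).

Holm's correction is applied within each family (axes; margins) and never
decreases a p-value; reported p never falls below 1/(n_perm + 1). In the
noiseless limit the residual mean square is floored at 1e-12 of the total
sum of squares.

Variance partitioning computes adjusted R^2 for every predictor subset
(2–4 predictors) and converts them to exclusive Venn fractions by Moebius
inversion; fractions sum to the full-model adjusted R^2 identically.
Shared fractions can be legitimately negative, and even exactly orthogonal
predictors show an O((1-R^2)/n) shared term from the adjustment — a
small-sample property of adjusted R^2, not an implementation artifact.

PERMANOVA partitions squared Euclidean distances on the Hellinger matrix
(one-way; pseudo-F per Anderson, R^2 = SS_between/SS_total, free label
permutation). It is held equal to scikit-bio's implementation in tests.
Note that with perfectly separated groups the permutation p-value has an
effective floor above 1/(n_perm+1): label permutations reproducing the
same partition tie the observed F.

Hierarchical clustering standardizes ORFs (z-score; "scaled Hellinger"),
drops constant ORFs with a warning, and applies Ward.D2 linkage (scipy's
`ward`, squared distances inside the Lance–Williams update) on Euclidean
distances. Elbow (within-cluster SS) and mean-silhouette curves are
reported for k in 2..8 (capped at n-1); `chosen_k` maximizes the
silhouette — the elbow curve is informative output only. A gradient-length
suitability check (DCA) is not implemented; users porting the RDA to new
data should verify approximate linearity separately.

## Investment and marker ratios

Per (taxon, sample, system), member-ORF TPM values are summed; an ORF
contributes to every system it is assigned to. The investment log ratio of
systems A and B is computed per biological replicate as
log2(sum_A / sum_B) and then summarized as mean ± SD over replicates per
taxon x depth x month — never as a ratio of replicate means. Base 2 is
used for fold-change readability (configurable). A zero sum on one side is
replaced by half the smallest positive system sum in the table and
flagged; replicates with both sums zero are excluded and counted.
Antisymmetry and additivity (log C/P + log P/T = log C/T) hold exactly
when no pseudocount fires, and ratios are invariant to rescaling a
sample's TPM column. Investment ratios are TPM-based; taxon relative
transcription and marker percentages are raw-count percentages of total
transcripts (community basis). Marker ratios relate amoA and hcd to the
single-copy reference radA per replicate, mean ± SD per depth x month;
radA must be present.

## Synthetic generator

The generator emulates the study design: 9 order-level taxa, depths
5/15/50/75/100 m, July and September, 2 biological replicates, lognormal
library sizes with mean 2e5 (sd_log 0.2). Per taxon, activity follows a
logistic in depth (midpoint, slope, September factor) with a floor so no
taxon vanishes; transcription is allocated across CAZyme/PEP/TP/marker/
other, with the CAZyme:PEP log2 ratio following a programmed linear
trajectory in depth (e.g. the Flavobacteriales-like taxon runs +1 at 5 m
to −2 at 100 m). Counts are Dirichlet-multinomial: the expected ORF
composition is perturbed per replicate at concentration 2e4 — chosen so
dominant-group shares scatter by a few percent between duplicates, i.e.
tight biological duplicates — then sampled multinomially. ORF sampling
probability is allocation x length/1 kb, so TPM recovers allocation while
count shares carry the length weighting; the truth object records both.
Marker ORFs (radA, amoA at 4-fold, hcd at 2-fold) share a fixed 1000-bp
length so count-based marker ratios equal the programmed folds in
expectation. The archaeal Amt ORF takes 70 % of that taxon's transporter
allocation and is emitted with the Pfam profile whose upstream TCDB
mapping is wrong, so the override path is exercised end to end.

Environmental covariates follow fjord-like shapes (temperature/oxygen/DOC
decreasing, salinity/nitrate/phosphate increasing with phosphate affine in
nitrate as a deliberate collinear block, subsurface chlorophyll maximum in
July, July NH4+ below the 0.2 µM detection limit and flagged). Replicates
share one CTD cast. Noise is multiplicative lognormal (sd 0.03; 0 gives
exactly monotone profiles).

What the generator does **not** emulate: sequence-level artifacts
(assembly chimeras, mapping ambiguity), compositional zero-inflation
beyond the multinomial, taxon-correlated length biases, database
incompleteness, or month-restricted permutation structure. Passing
recovery tests therefore demonstrates correctness of the statistics under
the declared sampling model, not robustness to upstream artifacts.

## Problem sizes in routine runs

The shipped tests and the acceptance script run the generator at its
default size (≈595 ORFs x 20 samples), 199 permutations for permutation
tests, 500 simulated datasets for type-I error calibration, and 5–100
seeds for recovery checks — sizes chosen so a complete verification pass
stays in the minutes range on one core while keeping Monte-Carlo error
well inside the asserted bands.

## Known limitations

* The consensus ranking arithmetic beyond votes-then-quality is a package
  convention, not a community standard; results at rank boundaries can
  shift under a different quality normalization.
* Marginal RDA tests assume exchangeable residuals; with month blocks a
  restricted permutation scheme would be more faithful but is not
  implemented.
* The variance partition is capped at 4 predictors (2^4 submodels).
* Multi-domain peptidase ORFs are counted once (best domain), which can
  undercount relative to per-domain tallies.
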