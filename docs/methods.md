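# Methods

## Scope and model

`kinmotif` infers kinase activity changes from multiplexed isobaric
(TMTpro-style) phosphoproteomics. The analysis assumes: (i) reporter
intensities mix across channels according to a known reagent impurity
matrix; (ii) per-site abundances are approximately lognormal, so group
comparisons are done on the log2 scale; (iii) a kinase's substrates share a
flanking-sequence motif summarised by a position-specific scoring matrix
(PSSM) over positions −5…−1, +1…+5 around the phospho-accepting Ser/Thr;
and (iv) loss of a kinase depresses phosphorylation of its motif-matched
substrates, detectable as over-representation of that kinase's predicted
substrates among downregulated sites.

Raw spectral search, site-localization scoring, and peptide FDR estimation
are upstream of this package: records arrive with their quality metadata
(isolation specificity, summed signal-to-noise, missing-channel count,
localization score) already attached.

## Reporter processing

**Impurity correction** solves the full linear system `M·x = observed`
rather than sequentially subtracting leakage, because the stated mixing
model is exactly a matrix product; `numpy.linalg.solve` is used and singular
matrices raise. Solutions more negative than a small tolerance
(10⁻⁶ × total signal) are left intact for inspection; smaller negatives are
numerical noise and clamp to zero.

**Filtering** applies the quality thresholds strictly as printed: reject
when isolation specificity < 0.8 (phospho; 0.7 total proteome), summed
S:N < 160 (exactly 160 is kept), ≥ 12 of 16 channels missing (≥ 8 for total
proteome), or localization score < 13. A record failing several rules
reports the *first* failing reason in the fixed order missing_channels →
isolation_specificity → summed_sn → localization → no_quant, giving
deterministic, auditable rejection tables. Filtering is idempotent and
partitions the input. The single-phosphosite requirement is enforced where
it matters — at kinase-scoring site selection — rather than as a record
rejection, since it restricts the prediction analysis, not quantification.

**Normalization.** Equal loading scales each channel by
(mean column sum)/(column sum): the mean (not the max) is the target so the
grand total is preserved and the operation is symmetric and idempotent.
Phospho-to-protein normalization divides each site's profile by its
protein's *relative* profile (protein row / row mean); absolute division
would conflate site stoichiometry with protein abundance, and the relative
form has the desirable fixed point that a flat protein profile changes
nothing. Sites without a quantified protein pass through unchanged and are
flagged. The final dataset-level normalization is median centering of log2
columns — the simplest defensible surrogate for an external normalization
package whose internal transformations are not specified; it is a separate,
swappable step. Missing values stay missing throughout; nothing is imputed.

## Differential statistics

Group means and fold changes are computed on log2 values (geometric means
on the linear scale), matching the log2-ratio convention of volcano plots.
The test is Welch's unequal-variance two-sample *t*: with four replicates
per group and no replicate pairing, it is the robust default when the
original analysis names only "P value" and "FDR". No variance moderation or
empirical-Bayes shrinkage is applied (deliberately out of scope). Sites
with fewer than two non-missing values on a side are skipped with a reason.
Zero-variance sites with unequal means receive the smallest representable
positive p and a flag — with 4-fold effects and zero noise the statistic is
otherwise undefined; zero-variance equal-mean sites get p = 1.

FDR is Benjamini–Hochberg (the only multiple-testing procedure the analysis
family names), applied per contrast, implemented via
`statsmodels.stats.multitest.multipletests` and cross-checked in the test
suite against an independently hand-coded step-up procedure.

Stratum boundaries follow the printed inequalities exactly: regulated
requires |log2fc| ≥ 1 *and* FDR ≤ 0.1 (inclusive); unregulated requires
|log2fc| < 1 *and* FDR > 0.1 (strict). Sites meeting neither definition
(e.g. large fold change at high FDR) are "intermediate" and excluded from
both enrichment strata; their count is reported in the run report. Tier
labels (tier 1: P < 0.01, tier 2: P < 0.05, both at the twofold cutoff)
annotate the volcano output and do not feed the enrichment.

## Kinase scoring

The score of flank *f* against a PSSM is the log2-odds against a uniform
background: `Σ_j log2(20 · p_j(f_j))` over off-center, non-pad positions.
Terminal padding (`_`) contributes zero, and the central S/T does not score
(matrices are defined on flanking positions only). The formula lives behind
a single function so alternates can be swapped.

Percentiles are empirical: `100 · #(background ≤ score) / N`. The default
background for each kinase is its own score distribution over all scored
sites in the current dataset — self-contained and well-calibrated for
within-dataset ranking; a library-supplied background sample overrides it
when present (both modes exist because reference-phosphoproteome
backgrounds are not always available). Ranking uses percentile descending,
then raw score, then kinase id — percentiles, not raw scores, so ranks are
comparable across kinases with different score scales. The top-15 of the
library are a site's predicted kinases; putative substrates of a kinase are
sites with percentile strictly > 95.

Scoring is restricted to non-duplicate (by protein and position), singly
phosphorylated sites. Phospho-priming (pre-phosphorylated lowercase
residues) is not modelled; the alphabet is the 20 uppercase amino acids.

## Enrichment

Per kinase and side, the 2×2 table is tested one-sided for
over-representation via the exact hypergeometric upper tail
(`P(X ≥ a)` given margins; degenerate margins give p = 1 by convention).
BH runs across kinases separately within the down and up families. Kinases
with q ≤ α (inclusive, α = 0.1) on *both* sides are excluded as
uninterpretable; otherwise the smaller-q side is selected, ties resolving
deterministically to "down". The scatter effect size is
`log2[(a/(a+b)) / (c/(c+d))]` with a Haldane 0.5 pseudo-count on all four
cells whenever a zero cell or margin occurs — any monotone effect measure
would serve; this one is conventional and finite.

pLogo-style statistics: background probability of residue *r* at position
*j* is its background frequency with a 0.5 pseudocount per residue; the
height is `−log10 P(Bin(n,p) ≥ k)` for enrichment (k/n > p) and
`+log10 P(Bin(n,p) ≤ k)` (negative) otherwise, computed with log-scale
binomial tails for numerical safety. The default background is the study's
unregulated-site flanks (configurable).

## Synthetic data

The generator emulates the study conditions: a 16-channel design of
{WT, KO} × {untreated, inhibitor} groups in quadruplicate (group-to-channel
layout is an explicit table, not hard-coded, since real plex layouts vary),
~10³–10⁴ sites with ±5 flanks, lognormal reporter noise (Gaussian on log2,
homoscedastic — matching the log-scale *t* statistics downstream), and a
spiked kinase whose motif-derived sites are shifted by `effect_log2` in the
affected group's channels (default: the union of KO groups, a
genotype-driven effect). Ground truth records exactly the shifted sites.

PSSMs are sampled per position from a symmetric Dirichlet with
concentration 1/`sharpness`, so one parameter controls motif information
content and larger sharpness means a more peaked motif. The default
sharpness 4 (concentration 0.25) gives a few strongly preferred residues
per position — the qualitative shape of real Ser/Thr kinase motifs, which
concentrate specificity in a handful of flank positions. Probabilities are
floored at 10⁻⁶ and renormalized so log-odds stay bounded. A `motif_fraction`
of sites draw flanks from a uniformly chosen kinase's PSSM (generating
kinase recorded); the rest are uniform. Baseline log2 abundance is
N(8, 1) per site, giving summed signal-to-noise comfortably above the 160
filter in the artifact-free case.

The PSM layer mixes true intensities through a tridiagonal 2%-leak impurity
matrix by default and injects independent Bernoulli quality defects
(low isolation specificity, sub-threshold summed S:N, ≥ 12 missing channels,
localization < 13), each drawn to land on the failing side of its filter;
injection counts are returned as a ground-truth side channel.

Randomness: one root seed with documented stream splitting
(library = 0, sites = 1, quant = 2, psm = 3 via `SeedSequence` spawn keys),
so each sub-step is reproducible in isolation and identical configs give
byte-identical outputs.

What the generator does **not** emulate: mass spectra, retention time,
fractionation, peptide-spectrum matching, missing-not-at-random dropout,
site-dependent variance, correlated motifs between kinases, or
protein-abundance confounding (unless a protein table is supplied). Passing
the recovery tests therefore demonstrates the pipeline's statistical
machinery is correct and calibrated under its own model assumptions; it
does not certify performance on real instrument data, where co-isolation
bias, ratio compression, and motif overlap between paralogous kinases make
recovery harder.

## Validation experiments and problem sizes

The packaged experiments (test suite and `scripts/acceptance.py`) use
2,000 sites, 50 kinases, a −2 log2 spike at noise s.d. 0.25 with 4-vs-4
channels, motif fraction 0.5, top-15 predictions, α = 0.1, and 20 seeds per
experiment — sizes at which the binomial/hypergeometric oracles are exact
and each full pipeline pass takes a fraction of a second. Measured on these
conditions: the spiked kinase ranks first among downregulated-enriched
kinases in 20/20 seeds, and with permuted regulation labels essentially no
kinase reaches q ≤ 0.1.

## Numerical choices and degenerate inputs

- Impurity matrices must have positive diagonals and column sums ≤ 1;
  singular matrices raise rather than being pseudo-inverted.
- Equal loading refuses zero column sums, naming the channel; median
  centering refuses all-missing columns.
- BH validates p ∈ [0, 1]; Fisher on degenerate margins returns 1.
- Rank tie-breaks (percentile, then raw score, then kinase id) and the
  down-side tie-break in side selection are fixed so reruns are
  byte-identical.
- log2 of nonpositive abundances yields missing, not −∞.

## Known limitations

- The Welch test with n = 4 per group has limited power for sub-twofold
  effects; no variance shrinkage is applied.
- Dataset-derived percentile backgrounds shift when the analysed site set
  is strongly biased toward one kinase's substrates.
- The noise-free limit is exactly recoverable at the classification level,
  but median centering can leave order-statistic-sized offsets (~0.03 log2
  with 500 sites) on null sites, which the zero-variance p-floor then marks
  "intermediate"; with any realistic noise this effect vanishes.
- Multi-phosphorylated peptides are excluded from kinase prediction, not
  apportioned between sites.
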