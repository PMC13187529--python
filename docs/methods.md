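# Methods

`omicsmr` re-creates, as reusable and tested code, the statistical
machinery of a proteome-wide drug-target discovery study for a binary
skin-fibrosis trait (keloid): two-sample Mendelian randomization (MR)
from cis-pQTL instruments across several proteomic databases, SMR/HEIDI
colocalization as target validation, MR-PheWAS for side-effect
screening, and a transcriptomic stage (differential expression, weighted
co-expression modules, correlation screening, PPI hub scoring) that
traces the candidate protein's downstream biology.  Everything runs on
synthetic data with planted ground truth, so each stage's operating
characteristics are measurable.

## Summary-level simulation model

All genetic inputs are generated at the summary-statistic level.  For a
region of `m` SNPs with LD correlation matrix `R` (block-diagonal AR(1),
`r_ij = rho^|i-j|` within a block, which is positive semi-definite by
construction), the estimated effects are

    beta_hat = beta_true + D L z,   z ~ N(0, I),  L L' = R,
    D = diag(se),  se_j = 1 / sqrt(2 N f_j (1 - f_j)),

i.e. multivariate-normal estimation error whose correlation is the LD
matrix and whose scale is the standard analytic SE of a per-allele
effect on a standardized trait at allele frequency `f_j`.  Individual
genotypes are never simulated: the pipeline only ever consumes summary
statistics, and this construction reproduces exactly the sampling
structure the estimators assume.  For a binary outcome the `N` in the SE
is the effective sample size `4/(1/n_case + 1/n_control)`; the default
(2661) corresponds to a 668-case / 481,244-control GWAS, and effects are
on the log-odds scale so `exp(beta)` is an odds ratio.

True exposure (protein) effects are `N(0.15, 0.03^2)` with random signs
(strong cis-pQTLs; z about 18 at the default pQTL sample size of
35,000); the outcome's marginal effect per SNP is
`theta * beta_exposure + alpha_j` with `alpha_j` the per-SNP direct
(pleiotropic) effect.  The `oriented_effects` switch fixes all exposure
effects positive — the orientation to the exposure-raising allele under
which *directional* pleiotropy is a meaningful notion.

## Instrument selection

Genome-wide significance (`p < 5e-8`, strict), a 1 Mb cis window around
the caller-supplied transcription start site (inclusive, 1-based
coordinates), greedy p-value-ordered LD clumping (`r2 > 0.001` within
10 Mb removed) and an instrument-strength filter (`F = (beta/se)^2 < 10`
excluded; an `R^2 (n-2)/(1-R^2)` variant with `R^2 = 2f(1-f)beta^2` is
available behind a switch).  Every excluded SNP is logged with the first
filter it failed.

## MR estimators

Harmonization aligns the outcome to the exposure's effect allele:
swapped alleles negate the outcome beta and mirror its frequency, strand
complements are flipped first, palindromic (A/T, C/G) SNPs with
effect-allele frequency within 0.08 of 0.5 in either study are dropped
(the band is configurable; the source analyses state the rule but not
the band), and remaining palindromic SNPs are aligned by frequency
concordance.

With per-SNP ratios `r_j = by_j / bx_j` and first-order SEs
`s_j = sy_j / |bx_j|`, weights `w_j = 1/s_j^2`:

- **Wald ratio** (single SNP): `r`, SE `s` (second-order
  `sqrt(sy^2/bx^2 + by^2 sx^2 / bx^4)` optional).
- **IVW**: `sum(w r) / sum(w)`, identical to WLS of `by` on `bx` through
  the origin with weights `1/sy^2`.  Default is multiplicative random
  effects — SE inflated by `max(1, sqrt(Q/(n-1)))` — because
  proteome-wide scans routinely show heterogeneity; fixed-effect by flag.
- **MR-Egger**: WLS of `by` on `bx` with intercept after orienting
  `bx >= 0`, weights `1/sy^2`, SEs scaled by `max(1, sqrt(Q_e/(n-2)))`;
  the intercept estimates the mean direct effect.
- **Weighted median**: the ratio at standardized cumulative weight 0.5,
  linearly interpolated between knots `p_j = (S_j - w_j/2)/S`; SE by
  parametric bootstrap (ratios resampled from `N(r_j, s_j^2)`, 1000
  draws, fixed seed).
- **Weighted mode**: argmax of the weighted normal-kernel density over
  the ratios; bandwidth is the modified Silverman rule
  `0.9 min(sd, mad) n^(-1/5)` times a configurable factor; bootstrap SE.
- **Cochran's Q** about the IVW center (`df = n-1`) and the Egger fit
  (`df = n-2`); **leave-one-out** IVW per excluded SNP.

P-values are two-sided normal (t-based Egger behind a flag); 95%
intervals are `exp(beta -/+ 1.96 se)`.  Dispatch: one harmonized SNP →
Wald ratio; two → IVW; three or more → all four multi-SNP methods plus
the sensitivity report.  A protein is called causal at nominal `p < 0.05`
on the primary method (Wald/IVW); replication across independent
databases — the intersection — is the multiplicity control, mirroring
the source design.  A BH-FDR mode exists for single-database scans.

## SMR and HEIDI

`b_smr = b_gwas/b_eqtl` at the top cis-eQTL;
`T_smr = z_g^2 z_e^2/(z_g^2+z_e^2)` is chi-square with 1 df.  HEIDI
tests whether every SNP in the region implies the same `b_smr`:
deviations `d_i = b_smr(i) - b_smr(top)` over eligible SNPs (eQTL
`p < 1.57e-3`, `r^2` with the top SNP in `[0.05, 0.9]`, the 20 most
significant — the published tool's conventions, all configurable), with
the covariance of `d` from the first-order delta method using the LD
correlations of the effect estimates within each study (the two studies
are independent).  `T = sum (d_i/sd_i)^2` is a sum of correlated 1-df
chi-squares; its tail is approximated by Satterthwaite moment matching
on the eigenvalues of the correlation matrix of `d` — chosen over exact
Davies inversion for a dependency-free implementation, and verified
against a 1e5-draw Monte-Carlo null (agreement within 0.001 at the 5%
tail on random correlation fixtures).  Fewer than 3 eligible SNPs yields
the verdict `heidi-undetermined` rather than a failure.  A target
"passes" when SMR `p < 0.05` and HEIDI `p > 0.05`.

The region simulator distinguishes the two architectures SMR/HEIDI are
built to separate: *pleiotropy* (one central SNP drives both expression
and trait; every SNP's implied ratio is equal) and *linkage* (two causal
SNPs whose LD is exactly `r_linkage`, produced by solving the AR(1)
decay so `rho^gap = r_linkage`).  Marginal effects at tag SNPs are the
causal effect times the LD correlation (standardized-genotype algebra).

## MR-PheWAS

Each outcome in a catalog is harmonized against the exposure's
instruments and estimated by Wald ratio or IVW; outcomes sharing no SNPs
are reported as skipped, never silently dropped.  The phenome-wide
threshold is `5e-5` (`-log10 p > 4.301`).

## Transcriptomic stage

Expression is generated on a log2-like additive scale.  Module genes
follow a unit-variance factor model `x = l f + sqrt(1-l^2) e`, so a
gene's loading *is* its correlation with the module factor; loadings
fall off linearly across each module (hub-to-periphery gradient), and
unassigned background genes attach weakly (loadings 0.05-0.35 by
default) to a random module — real co-expression is graded, and that
graded spectrum is what produces a smoothly decaying connectivity
distribution.  Trait-associated module factors gain `delta = 2` times
the centered case/control indicator.  The trait module is coherently
up-regulated (all its genes shifted by `de_log2fc = 2` in cases),
emulating the heavy overlap between a disease module and the DEG list in
real case/control studies; background DEGs (rate 0.07) shift with random
sign.  Two batches receive additive offsets (0, 2) and multiplicative
scales (1, 1.3), interleaved within groups so batch is not confounded
with condition.  The default design is 7 cases vs 6 controls — the
merged two-cohort scale of the study the package emulates.

Processing: rank-based quantile normalization (columns mapped to the
mean order-statistic profile, ties averaged); per-gene location-scale
batch adjustment onto the pooled mean and pooled *within-batch* SD (a
deliberate simplification of empirical-Bayes batch correction — fully
deterministic and testable; note that with zero true offsets it still
equalizes the noisy batch means, so it is an exact no-op only for a
single batch); Welch t-tests with BH FDR and the call rule
`|log2fc| >= 1` (inclusive) *and* `fdr < 0.05` — a fold-change-only rule
is not a test, so the FDR condition is added and both thresholds are
configurable.  Genes with zero variance in both groups get `p = 0` if
the means differ, else 1, with a warning.

WGCNA-core: unsigned adjacency `|cor|^power`; the scale-free fit index
bins connectivity into 10 equal-width bins (empty bins dropped) and
regresses `log10(freq)` on `log10(mean k)`, reporting
`-sign(slope) * R^2`; the chosen power is the smallest candidate
reaching 0.80, else the best with a warning.  Topological overlap
`TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij)`;
modules by average-linkage clustering of `1 - TOM` with a static cut at
`(1 - 0.25)` of the maximum merge height (the merged-dendrogram scale;
dynamic tree cut is intentionally not re-implemented — recovery is
validated on well-separated synthetic modules where the static cut
suffices), minimum module size 30 in production, 5 in tests, smaller
clusters grey.  Module eigengenes are the first right singular vector of
the z-scored module submatrix, unit norm, sign fixed positive on the
module's mean profile.  Module-trait statistics are Pearson correlations
with the 0/1 trait (t-test, n-2 df) plus per-gene gene significance and
module membership.  The Spearman screen uses average ranks and the t
approximation.  Key genes are the exact-id intersection of the trait
module with the DEG list; Venn-region counts are reported for 2-3 sets.

Two reference regimes of the generator are frozen for validation
(`GRADED_NETWORK_KWARGS`, `SEPARATED_MODULE_KWARGS`): graded membership
for the scale-free/power-selection check, tight well-separated modules
(scored at the reference unsigned power 6, the conventional default) for
the recovery check.  These are deliberately different: the scale-free
property *comes from* graded membership, while an adjusted-Rand-index
target of 0.9 is only meaningful when the planted partition is crisp.
Within one regime the static-cut chain cannot exhibit both.  The
pipeline's own default candidate powers stop at 12: with 13 samples,
higher powers amplify correlation noise faster than structure.

## Hub scoring

Five cytoHubba-style centralities: MCC (sum over maximal cliques
containing `v` of `(|C|-1)!`, cliques via Bron-Kerbosch with pivoting;
an isolated node scores `0! = 1`), MNC (largest connected component of
the open neighborhood), degree, reciprocal-distance closeness
(`sum 1/d`, unreachable pairs contribute 0) and radiality
(`sum (diam + 1 - d) / (n_comp - 1)` per connected component).  Top-k
lists are *closed*: ties spanning rank k are all included, so the
intersection is permutation-invariant.  Self-loops and duplicate edges
are rejected at ingestion.  All five scorers are verified against
exhaustive brute-force oracles on every graph with up to 5 nodes and on
random 6-8-node graphs.

## Pipeline and validation studies

`run_all` executes: per-database proteome scan (30 proteins x 3
databases, one planted causal protein at `theta = 0.5`, 18 SNPs in
3-SNP LD blocks per protein, exposure sample sizes 35,000/35,000/10,000)
→ nominal-significance intersection with a consistent-direction
requirement → SMR/HEIDI on a pleiotropy-architecture region → MR-PheWAS
against 50 null outcomes → expression stage → key genes → Spearman
screen against a 27-gene panel containing one planted co-module partner
→ PPI hub scoring (5 planted hubs, boost 30) with the top-30
intersection.  Every stage seed derives deterministically from the run
seed, so a repeated run reproduces the report byte for byte.

`validation.py` packages the simulation studies behind the acceptance
numbers: IVW type-I error (1000 null scans), bias/coverage at
`theta = 0.3` (500 reps; fixed-effect IVW, since the data are
homogeneous and the multiplicative-random-effects SE can only widen),
Egger intercept recovery of planted directional pleiotropy 0.05 (500
reps, oriented effects with loading spread 0.08 — with random-signed or
near-constant instrument effects the intercept is not identified, see
the orientation note above), weighted-median-vs-IVW wins with 5/10
pleiotropic instruments carrying a minority of the weight (the regime in
which the median's guarantee applies), HEIDI discrimination (200
pleiotropy + 200 linkage regions), the Satterthwaite/Monte-Carlo tail
comparison, DEA null uniformity and planted recovery, the two WGCNA
regimes, and the end-to-end run.  `scripts/acceptance.py` recomputes all
of these from scratch at a given seed and writes them as JSON.

## Problem sizes and limitations

Simulated studies use desk-scale sizes (300-5000 genes, 10-30 SNPs per
region, 200-1000 replicates) chosen so each study still has clear
statistical resolution.  What passing tests show is that the machinery
is calibrated and recovers planted structure of the stated strength;
they do not certify performance on real GWAS/expression data, which has
allele-frequency-dependent LD, winner's-curse-selected instruments,
non-normal expression noise, and batch effects that are not pure
location-scale.  The generators also make no attempt at realistic
minor-allele spectra or imputation quality, and the expression model is
a linear factor model — features like count noise or outlier samples are
out of scope.  HEIDI's delta-method covariance is first-order; its
slight anticonservatism in small regions is visible in the ~95% (not
exactly 95%) pleiotropy retention rate.
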