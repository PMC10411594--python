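# Methods

## Observation model and design coding

The unit of analysis is the allele-level count: each hybrid sample
contributes one observation per parental allele, so a fully observed
sex × tissue × cross scope has 2 reciprocal directions × 2 replicates × 2
alleles = 8 observations per gene. Counts are accepted as nonnegative
reals, because upstream allele-specific quantifiers emit estimated
(fractional) counts; they are rounded (half-up) only where an exact test
requires integers, i.e. in Fisher's exact test. The binary covariates are
CR (allele A = 0, B = 1), PO (maternal = 0, paternal = 1; the maternal
allele is A exactly when the direction is A×B, since the mother is listed
first) and MG (direction A×B = 0, B×A = 1). Offsets are natural-log
library sizes computed over retained autosomal genes and shared by the two
allele rows of a sample; an X-linked or low-SNV gene is excluded via
per-gene flags rather than re-filtered here, because those filters belong
to upstream read processing. TMM-style normalization factors are not
applied by default: with balanced designs and within-sample allele
contrasts, the library-size offset is the minimal defensible choice.

Missing samples are supported throughout: models fit on the available
observations with a floor of 6 observations and both CR levels present;
below that the gene/scope is reported as skipped, never dropped silently.

## Negative-binomial engine

Fits use NB2 (variance μ + αμ²) GLMs with log link via statsmodels. The
per-effect tests are likelihood-ratio tests with a χ²(1) reference,
chosen over Wald for stability at n = 8. The dispersion α is estimated
once per gene on the full model and held fixed across the nested fits,
which guarantees nonnegative nested deviance differences; this is also
why the deviance explained by CR (deviance of the PO+MG model minus the
full model) is a well-defined nonnegative effect-size measure.

Per-gene dispersion at 2–4 residual degrees of freedom is hopeless on its
own (roughly 40 % of ML estimates collapse to zero), so dispersions are
moderated across genes: likelihood curves are evaluated on a shared
72-point log-spaced grid for the Cox–Reid adjusted profile likelihood
(subtracting ½·logdet(XᵀWX), which removes the downward bias the fitted
coefficients would impose), the common dispersion maximizes the pooled
curve, and each gene maximizes its own curve plus
(prior df / residual df) times the genewise-average curve. The prior df
is 20, an edgeR-scale choice fixed a priori; `common_dispersion=True`
forces the common value everywhere. Genes with an all-zero CR level get a
half-count continuity adjustment before fitting and are flagged.

Interaction models (`E ~ μ + CR + factor + CR·factor`) and reversal models
(`E ~ μ + CRfactor`, the recoded column equal to CR in one level and
1−CR in the other) use the same engine on up to 16 observations. The
reversal model deliberately omits the factor main effect, matching its
published form; in a balanced design the recoded column is orthogonal to
the factor mean difference, which the NB dispersion absorbs.

## Cis/trans classification

P (parental DE) and H (hybrid allelic imbalance) use the module's own
NB-LRT engine rather than an external DE package — the inferential role is
identical and the dispersion moderation above plays the role a dedicated
DE engine's shrinkage would. H pairs alleles within samples via sample
intercepts, so between-sample noise cannot mimic imbalance. T is
Fisher's exact test on the 2×2 table of summed counts
[[P1, P2], [A1, A2]] (replicates, and reciprocals in pooled mode, summed
first). Log ratios add a pseudocount of 0.5 to each cell; Fisher uses
rounded raw counts without pseudocounts. A ratio of exactly 1 — and the
degenerate log₂(A1/A2) = 0 case — resolve to cis+trans, closing the gap
the published "> 1" / "< 1" rule leaves at equality. BH-FDR is applied
per test within each scope, and categories follow the seven-way table,
which is total over the eight flag combinations.

**Known property, not a bug:** Fisher's T test models the summed counts as
multinomial and therefore ignores biological replicate variance. With
parental log-ratio noise of SD ≈ √(2α/n_rep), the T test's null rejection
rate grows with sequencing depth — at counts in the hundreds and α = 0.01
roughly a third of truly null genes are T-flagged after BH. Consequences:
(i) null genes leak into `ambiguous` (T alone) and, because the P test
shares the same parental noise, into `trans_only`; (ii) cis-only genes
whose T test fires move to cis+trans / cis×trans, capping cis-only
sensitivity near 0.7 under realistic noise. False *cis*-involving calls
remain rare (≲ 1 %), because the within-sample H test is properly
calibrated. This is a faithful property of the published test hierarchy;
the package does not attempt to repair it.

## Inheritance modes

Eligibility: parental fold ≥ 1.5 (after a TPM floor of 0.01) and summed
parental reads ≥ 20. With f = 1.25, lo = min(p1, p2), hi = max(p1, p2):
overdominant h ≥ f·hi; underdominant h ≤ lo/f; additive f·lo ≤ h ≤ hi/f;
conserved within f of both parents (non-empty only for parental folds up
to f² = 1.5625); dominant within f of exactly one parent. All bounds are
inclusive ("1.25-fold greater" ⇒ ≥), configurable via
`inclusive_fold_bounds`; precedence over/under → additive → conserved →
dominant makes the rule total and mutually exclusive, and boundary points
shared by two regions resolve to the earlier one. Parental TPM is
averaged across replicates and hybrid TPM across reciprocals before
classification (averaging normalized TPM, not raw counts). A
`method="statistical"` variant replaces fold rules with NB-LRT
hybrid-vs-parent contrasts at BH-FDR < 0.05.

Because TPM renormalizes every sample to a fixed total, widespread
asymmetric divergence shifts TPM scales between sample types
(compositional bias); with realistic divergent fractions (≲ 10–20 %) the
shift is small relative to the 1.25-fold margins, but fold rules on TPM
should not be trusted when most of the transcriptome diverges.

## Sex bias and comparison statistics

SB = log₂((exp_F + 1)/(exp_M + 1)) with mean TPM across replicates within
scope. Bins at −1, −0.3, 0.3, 1 give MS/MB/UB/FB/FS; the published
open-interval bins leave boundaries unassigned, so boundary values go to
the less-biased side (−1 → MB, ±0.3 → UB, 1 → FB), a conservative and
configurable convention. Mann–Whitney U comparisons are exact for
tie-free groups of ≤ 20, otherwise normal with tie correction and no
continuity correction; the two-proportion z test is pooled without
continuity correction; the CR-overlap χ² is uncorrected, on the 2×2 table
of shared/unshared CR calls over the intersected gene set (≥ 20 genes).
Degenerate inputs (zero margins, constant vectors, empty bins) return NA
with a reason rather than raising.

## Synthetic data

The generator emulates one reciprocal cross: two inbred lines, 2
directions × 2 replicates × 2 sexes × 2 tissues, plus parental samples
and an allele-agnostic "overall" hybrid layer for inheritance analysis.
Per gene and context, parent 1 has mean b, parent 2 b·2^(cis+trans), and
hybrid alleles b·2^(trans/2)·{1, 2^cis}·2^(po·[paternal])·2^(mg·[B×A]);
the hybrid trans environment is the geometric midpoint of the parental
backgrounds, so pure-trans genes diverge between parents while keeping
balanced hybrid alleles. Sex bias enters as b·2^(±sb/2). Counts are NB
with variance μ + αμ² (Poisson below α = 10⁻⁹); TPM is counts scaled to
10⁶ per sample.

Effect classes (cis-only, trans-only, cis+trans, cis×trans, compensatory
with trans = −cis exactly, PO, MG, sex-reversed with cis_F = −cis_M;
remainder null) are allocated exactly by largest remainder so recovery
tests have fixed denominators. Effect sizes are sign·|N(mean, 0.25)| with
mean 1 log₂ by default. Base means are log-normal with median 200 and
log-SD 1; dispersions log-normal with median 0.01 (BCV 10 %, the standard
value for pools of genetically identical individuals — samples here
emulate pools of many inbred flies) and log-SD 0.5. Inheritance modes
cycle deterministically through additive/dominant-P1/dominant-P2/over-/
underdominant among genes whose class gives parental divergence; other
classes are conserved (their parents coincide by construction). When a
target depth is set, per-sample expected totals are rescaled to it;
by default counts stay on the base-mean scale.

What the simulator does **not** emulate: correlated allele noise within a
library (alleles are drawn independently, matching the GLM's observation
model — real allelic ratios are closer to binomial within a sample);
gene length effects (TPM here is depth-normalized counts); mapping bias;
isoform structure; and the ≥ 3-SNV transcript filter (flags default to
true). Passing recovery tests therefore demonstrates correctness of the
inference given the model, not robustness to quantification artifacts.

## Verification sizes and seeds

The test suite validates: exact agreement of both classifiers with
brute-force oracles (all 8 × ratio-regime flag combinations; a ~16k-point
(p1, p2, h) lattice); type-I calibration of the CR test on 5,000 null
genes (mean 200, dispersion 0.1) with raw p < 0.05 rates in [0.03, 0.07]
and BH calls ≤ 0.5 %; recovery on 2,000 genes with 10 % cis-only at
|log₂fc| = 1 (mean 500); reversal power/specificity on 300 genes; and
simulator-vs-closed-form agreement on 2,000 genes within 3 SE per class.
Simulation sizes are chosen so the whole suite runs in a few minutes on
one CPU; seeds are fixed constants. `scripts/acceptance.py` recomputes
the same quantities at comparable sizes from any seed.
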