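# Methods

## The problem

Observational associations between two traits — say an adiposity measure X
and a cognitive measure Y — are confounded and the direction of causation is
ambiguous. Mendelian randomization (MR) uses genetic variants as
instrumental variables: a SNP that robustly shifts X, is independent of
confounders, and affects Y only through X identifies the causal effect of X
on Y. In the *two-sample* design the SNP–exposure associations
(β<sub>Xj</sub>, se<sub>Xj</sub>) and SNP–outcome associations
(β<sub>Yj</sub>, se<sub>Yj</sub>) come from different studies; when the
studies partially share participants the design is *pseudo* two-sample and
overlap bias must be assessed. Running the analysis in both directions
(X→Y and Y→X) resolves directionality.

## Estimators

With J harmonized instruments the per-SNP Wald ratio is
θ̂<sub>j</sub> = β<sub>Yj</sub>/β<sub>Xj</sub> with first-order delta SE
se<sub>Yj</sub>/|β<sub>Xj</sub>| (the exposure SE is ignored in the ratio SE
so that the IVW weights reduce to 1/se<sub>Yj</sub>² and IVW coincides with
weighted regression through the origin).

**IVW.** Weighted least squares of β<sub>Y</sub> on β<sub>X</sub> through
the origin with weights w<sub>j</sub> = 1/se<sub>Yj</sub>²:

    θ̂ = Σ w_j β_Xj β_Yj / Σ w_j β_Xj² ,   se_FE = (Σ w_j β_Xj²)^(-1/2).

Heterogeneity is Cochran's Q = Σ w<sub>j</sub>(β<sub>Yj</sub> − θ̂β<sub>Xj</sub>)²
and I² = max(0, (Q − (J−1))/Q). The reported SE follows a *multiplicative
random-effects* model: se = φ·se_FE with φ = max(1, √(Q/(J−1))). The
truncation at 1 means heterogeneity can widen but never narrow the interval;
under the null of no heterogeneity this makes tests mildly conservative
(observed null rejection ≈ 4% at the 5% level, within binomial tolerance in
the calibration suite).

**MR-Egger.** The same weighted regression with a free intercept, after
sign-flipping any row with β<sub>Xj</sub> < 0 so all instruments refer to
the trait-increasing allele. The slope estimates the causal effect under
InSIDE (instrument strength independent of direct effects); the intercept
estimates average directional pleiotropy, with its SE scaled by
φ = max(1, √(Q/(J−2))). I²<sub>GX</sub> = max(0, (Q<sub>GX</sub> − (J−1))/Q<sub>GX</sub>),
with Q<sub>GX</sub> the 1/se<sub>Xj</sub>²-weighted spread of the exposure
betas, quantifies regression-dilution attenuation of the Egger slope
(values near 1 = negligible).

**Weighted median.** Wald ratios ordered ascending with weights
w<sub>j</sub> = β<sub>Xj</sub>²/se<sub>Yj</sub>² normalized to sum 1;
standardized cumulative weight s<sub>j</sub> = cum(w)<sub>j</sub> − w<sub>j</sub>/2;
the estimate interpolates the ordered ratios at s = 0.5. It is consistent
while under 50% of total weight comes from invalid instruments. The SE is a
parametric bootstrap (default 1000 draws): β<sub>X</sub>, β<sub>Y</sub>
resampled from normals at the observed values with their SEs, the median
recomputed, and the standard deviation taken. Instruments are sorted by
variant ID before sampling so the result is independent of input order for
a fixed seed. Whether analytic or bootstrap SEs are preferable is an open
choice; the bootstrap is the package's convention and is flagged in fits.

Inference uses normal quantiles throughout (not t): J is typically
moderate, and the convention is pinned for reproducibility.

## Instrument construction

Associations pass a genome-wide significance filter (p < 5×10⁻⁸, strict
inequality) and greedy LD clumping: sort by ascending p (ties: position,
then variant ID), keep the best remaining SNP, drop remaining SNPs on the
same chromosome within ±250 kb with r² > 0.1 (strict). An absent LD pair is
treated as r² = 0, which is the conservative choice for retention given
sparse LD tables. Instrument strength uses the multi-SNP convention
F = R²(n − k − 1)/(k(1 − R²)) with k SNPs in the denominator, and R² the
squared correlation between the phenotype and the weighted allele score.

## Harmonization

Join on variant ID (rsID), not position. Outcome alleles are aligned to the
exposure's effect allele: identical → kept; swapped → beta negated and eaf
inverted (flipped); strand-complement labels → relabel then align.
Palindromic SNPs (A/T, C/G) are strand-ambiguous: if the effect-allele
frequency is missing or inside [0.42, 0.58] in either study the SNP is
dropped; otherwise strand is inferred from whether the two frequencies fall
on the same side of 0.5. The window is configurable; the windowed-drop rule
is conservative standard practice and is surfaced in reports through the
per-SNP status field.

## Sensitivity battery

*Confounder screen*: one marginal test per (SNP, confounder) pair — simple
linear regression for continuous confounders, a logistic score test for
binary ones — with Benjamini–Hochberg applied jointly across all pairs at
FDR 0.05; a SNP is flagged if any pair is rejected.

*Outliers*: Cook's distance on the weighted regression underlying IVW
(p = 1) or Egger (p = 2), threshold 4/J by default (conventional rule;
configurable), verified against leave-one-out refits. Funnel coordinates
(ratio, precision) are exported for plotting. Flagged SNPs trigger a rerun
of the full suite.

*Overlap / winner's curse*: with overlap fraction o, mean instrument F̄ and
confounded observational association b_conf, the approximation
bias ≈ o·b_conf/F̄ with type-1 error P(|Z + bias/se| > z₀.₉₇₅). This is the
standard weak-instrument/overlap approximation — an analytic screen, not a
bit-match to any particular published computation; the constant is surfaced
in the report.

*Split-sample*: a seeded permutation splits a cohort into halves of
⌈n/2⌉ and ⌊n/2⌋ (378 877 → 189 439/189 438); per-SNP associations are
estimated separately in each half, MR runs with exposure betas from one
half and outcome betas from the other in both directions, and the two
estimates are pooled by fixed-effect inverse-variance meta-analysis.

## Synthetic data: the stated world

Defaults: J = 50 instrument SNPs, MAF ~ U(0.05, 0.5), two cohorts of
20 000, no overlap, causal effect θ = 0.2, per-SNP exposure effects
γ ~ N(0.1, 0.05) (strong on average — per-SNP F mostly 25–100 — but
heterogeneous, as real GWAS effect sizes are), confounder effects 0.3 on
both traits, no pleiotropy. Pleiotropy regimes assign direct SNP–outcome
effects α to a configurable fraction of instruments: balanced N(0, σ²),
directional N(μ, σ²) with default σ = 0.01 (comparable to a per-SNP outcome
SE at n = 20 000, so heterogeneity is visible), or correlated with γ
(violating InSIDE). A disjoint set of SNPs with direct outcome effects
provides reverse-direction instruments, making a single simulated world
bidirectional: forward instruments recover θ, reverse instruments have a
null causal effect on the exposure. LD blocks copy a block-anchor genotype
with probability √r², giving pairwise genotype correlation √r² and hence
the target r²; block members share the anchor MAF and sit within one
clumping window. Allele labels are random non-palindromic pairs by default
(set `allow_palindromic` to exercise the drop rule).

What the generator does *not* emulate: realistic human LD maps and allele
frequency spectra, imputation uncertainty, relatedness, selection into the
cohort, or assortative mating. A green recovery test therefore establishes
correctness of the estimators under the stated structural model, not
robustness to everything real cohorts contain.

Known small-sample behaviours visible in the suite, left as-is because
they are properties of the methods rather than defects: same-cohort
instrument selection introduces mild winner's-curse attenuation (~2% at the
default configuration), and finite-J weak-instrument dilution attenuates
IVW by roughly Σγ²/(Σγ² + Σse²_X).

## Reporting conventions

Exposures are standardized to mean 0, SD 1 (population SD, dividing by n —
negligible vs n−1 at cohort scale but pinned for testability). Positively
skewed outcomes are analysed on the natural-log scale; a coefficient b
reported in 100×ln units converts to a percent difference
100(e^{b/100} − 1). Count-like outcomes with a floor at zero use ln(x + 1),
and the offset is recorded in the result. Bonferroni thresholds are shown
alongside raw p-values (level/n_tests, with n_tests the number of
exposure–outcome pairs across both directions) rather than rescaling the
p-values themselves. CIs are 95% throughout.
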