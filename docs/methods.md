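# Methods

This note documents the models implemented in `idscan`, the design
decisions taken where more than one reasonable choice existed, and what
the simulator does and does not emulate.

## The diallel mixed models

The data are trait measurements on selfed (S1) and outcrossed full-sib
progenies of a panel of outbred parents, grown over two years with field
nuisance structure. Four nested linear mixed models are fitted by REML:

1. **Model 1.** Fixed: year, progeny type, their interaction, neighbour
   shading, border indicators per year, and fourth-order row/column
   position polynomials per year. Random: mother/father GCA effects for
   outcrossed progeny (a father's effect constrained equal to the same
   parent's mother effect), S1-family effects for selfed progeny,
   SCA (cross-specific) effects, and year interactions of each
   (GCA×E and S1×E with an A ⊗ I covariance over parents × years).
   Residual variance separate per year.
2. **Model 2.** As model 1 with residual variances separated by progeny
   type × year (four cells), testing whether partly inbred plants are
   less environmentally buffered.
3. **Model 3.** As model 2 plus a covariance between a parent's GCA and
   S1-family effects, i.e. (GCA, S1) jointly N(0, Σ ⊗ A) with the
   off-diagonal of Σ unconstrained on the real line.
4. **Model 4.** As model 3 plus reciprocal GCA (mother − father,
   antisymmetric incidence) and reciprocal SCA terms with their year
   interactions.

A pedigree relationship matrix A over the parents can be supplied;
simulated founders are unrelated, so A defaults to identity.

**REML engine.** The restricted likelihood is evaluated through
Henderson's mixed-model equations: with W = [X Z] and per-residual-group
Gram blocks precomputed once, each evaluation assembles the coefficient
matrix C, and −2ℓ_R = Σ n_g log σ²_g + log|G| + log|C| + y'Py. Variances
are log-parameterized; the GCA–S1 covariance is a free real parameter
with positive-definiteness of Σ enforced by a barrier, so boundary
solutions appear as near-singular fits rather than failures.
Optimization uses L-BFGS-B from two starting points with a Nelder–Mead
fallback and a short Nelder–Mead polish; richer models are warm-started
from simpler ones (`fit_all_models`), which also makes the restricted
log-likelihoods respect the nesting order numerically. Standard errors
of variance components come from the inverse numerical Hessian of ℓ_R on
the natural scale; they are reported as NaN when the Hessian is not
positive definite (typically boundary estimates), and significance flags
use |estimate| > 2 SE.

**BIC.** −2ℓ_R + k·ln(n) with k the number of (co)variance parameters
and n the number of observations. Only model *ranking* is treated as
meaningful; ties break toward the simpler model. Exact bookkeeping of
boundary parameters differs between mixed-model packages, so BIC values
are not comparable across software.

**Marginal means and δ.** Progeny-type means are predicted at equal year
weights and observed covariate means; δ = 1 − (selfed mean)/(outcross
mean). A positive δ is a decline under selfing. Derived parameters
follow the standard diallel identities (σ²_A = 4σ²_GCA, σ²_D = 4σ²_SCA);
the inbreeding covariance components are recovered from
σ_ADI = 4(Cov(GCA,S1) − ½σ²_A) and
σ²_DI = 8(σ²_S1 − 4Cov(GCA,S1) + σ²_A − ¼σ²_D), which follow from the
expectations Cov(GCA,S1) = ½σ²_A + ¼σ_ADI and
E[σ²_S1] = σ²_A + ¼σ²_D + σ_ADI + ⅛σ²_DI.

## Regression on genomic inbreeding

Realized F is diag(A) − 1 from a VanRaden method-1 additive GRM (the
per-site-standardized Yang et al. 2010 estimator is available as an
option; which convention the field's studies used is often uncited, so
it is configurable). The
"1 minus the diagonal" convention that appears in parts of the
literature gives the wrong sign under diag = 1 + F; we use diag − 1 and
treat the other phrasing as transposed. F is regressed on the trait in a
mixed model with the model-1 fixed covariates minus the progeny-type
terms, F and F×year as fixed covariates, and random polygenic additive
(GRM A), dominance (GRM D) and year-block-diagonal additive G×E effects,
with per-year residuals (dense-V REML, same optimizer). The reported
slope is the main effect plus the average of its year interactions; the
quadratic model adds F² (negative F floored at zero before squaring) and
its year interactions. Wald F statistics with residual denominator
degrees of freedom approximate the conditional F-tests of dedicated
mixed-model software.

Under directional dominance without epistasis, the slope on the outcross
mean scale is twice δ, because one selfing generation only moves F to
0.5. This is reproduced in simulation to within ~3%; the small
attenuation comes from Mendelian noise in F̂, which is why the worked
pipeline builds the GRM from markers with MAF ≥ 0.05 (rare markers add
noise to F̂ faster than information).

## Linkage map

A marker is emitted whenever the cumulative number of progeny haplotypes
whose founder-haplotype identity changed since the last emitted marker
first reaches 0.01·(2N); the first site of each chromosome is always
emitted, and consecutive markers are assigned exactly 1 cM (the rule
*selects* markers at 1 cM expected spacing; it does not re-estimate
distances). Sites with missing identities beyond a configurable fraction
are skipped; missing haplotypes are dropped from a site's change count
with the threshold unscaled (pairwise-complete counting — the simplest
defensible rule).

## Rare allele scan

For each founder haplotype h and map marker, OLS of the trait on the
nuisance design (year, F with per-year slopes, shading, border, spatial
polynomials, marker principal components) plus x_ha (copies of h) and
x_hd (heterozygous for h), with LOD = (n/2)log10(RSS0/RSSmark) against
the nuisance-only fit on the same rows. The implementation residualizes
against the nuisance QR once per scan (Frisch–Waugh), which is exact and
two orders of magnitude faster than refitting; tests verify equality
with full statsmodels OLS fits to 1e−6. Cells with fewer than 5 carriers
are skipped (rank stability; configurable); when the dominance column is
aliased it is dropped and flagged.

Candidate QTL are local maxima with LOD ≥ 4; support intervals are the
maximal contiguous runs within 2 LOD of the peak; overlapping candidates
of the *same* haplotype collapse to the highest peak, while candidates
of different parents are kept separate. Forward selection starts at the
global maximum (ties: chromosome, then cM, then parent) and adds the
(a, d) pair that most lowers BIC = n·ln(RSS/n) + k·ln(n), evaluated on a
fixed complete-case row set so all comparisons share a sample; it stops
when no candidate lowers BIC. The final joint model reports effects,
drop-one ΔR² partitions (additive-only, dominance-only, both, PC
background), effects standardized to the outcross phenotypic SD, and the
predicted depression 2Fpqd per QTL (F = ½, q = 1/2N, d scaled to the
outcross mean). Cross-validation refits the entire pipeline inside each
training fold and reports predicted-observed correlations for the
null/PC/QTL/full models.

Because a test at LOD 4 corresponds to a nominal p ≈ 1e−4 and the BIC
penalty for two parameters is weaker than that at these sample sizes, an
occasional null-trait artifact that clears LOD 4 will also survive
stepwise selection; empirically null scans select ~0.1 QTL per trait.

## Segregation distortion

Selfed families with ≥ 20 analyzed progeny are scanned marker-by-marker
with a 2-df χ² against 1:2:1 (no continuity correction). The genome-wide
threshold is 0.05/ENT_total, with per-chromosome ENT from the
eigenvalues of the marker correlation matrix over all scanned progeny
(Li & Ji estimator by default; Cheverud–Nyholt and Galwey available; the
eigenvalues are rounded to 10 decimals because the Li–Ji step function
is discontinuous at integers). A region requires ≥ 3 consecutive
significant markers; its deficient genotype classes are read from pooled
counts, and het-deficient regions are flagged (gametophyte-factor-like
patterns) without a mechanistic call. Confirmation requires more than
half of the parent-heterozygous raw markers inside the region window to
reject 1:2:1 at 0.05; zero informative markers leaves the region
"unverifiable". Recombination context compares the region's cM/Mb with
its chromosome and genome means.

Note on the null: the ENT correction controls each family's genome scan
at α = 0.05, so ~5% of lethal-free families still show one region; the
run-length filter does not reduce this, because adjacent 1-cM markers
within a family are almost perfectly correlated. A fully linked
recessive lethal in a family of ~50 analyzed progeny is detected and
confirmed in ≥ 95% of simulations.

## Burden, load, overlap

Per-site burden is GERP × {0, ¼, 1} for ancestral-homozygous /
heterozygous / derived-homozygous genotypes, over sites that are
segregating, polarized by the ancestral allele, and positively scored;
missing calls are excluded per parent, unpolarized sites counted in a QC
total. Rare-allele load is the mean minor-allele carriage (0, ½, 1 per
site; homozygotes double-weighted) over MAF < 0.05 sites. Parent-level
load is correlated (Pearson) with family-specific depression, genome-wide
or restricted to a trait's QTL support intervals.

The overlap permutation test re-places each query window uniformly on
the genetic map preserving its cM length: a chromosome is chosen with
probability proportional to its count of valid start positions and the
start drawn uniformly, so windows never straddle chromosome ends.
Statistics are the mean overlaps per query and the count of zero-overlap
queries; two-sided empirical p-values use the doubled-tail
(x+1)/(B+1) rule capped at 1 (one defensible reading of "percentile of
the permuted distribution"; B = 5000 by default).

## The simulator

Founder genomes: evenly spaced sites per chromosome; neutral sites draw
a generating frequency from a 1/k (standard-neutral) spectrum and then
Bernoulli carriage per haplotype, so stored frequencies are true
base-population values (this removes the in-sample centering bias that
otherwise depresses realized F); polygenic deleterious loci draw
exponential effect magnitudes, dominance d = −dom·a (dom = 1 fully
recessive), and Beta-distributed frequencies; major loci and lethals can
be placed on one named founder haplotype (q = 1/2N exactly). bp
positions come from a configurable cM→bp rate map so low-recombination
regions can be simulated. Meiosis is Haldane: Poisson crossover counts
with uniform breakpoints, no interference (the data motivating the map
rule do not identify an interference model; Haldane matches the cM
bookkeeping and is standard). Lethal selection acts once,
pre-phenotyping; individuals homozygous for a lethal are censored from
phenotype and downstream genotype tables. Phenotype = trait mean + year
+ spatial polynomials + shading + border + Σ(a·g + d·[g=1]) + b·F² + ε
with ε SD per (type, year).

**Epistasis term.** The F² term uses *realized* genomic homozygosity
(F = 1 − het/E[het]) rather than pedigree F: with a single generation of
selfing, pedigree F takes only two values and b·F_ped² is perfectly
confounded with the progeny-type contrast, so a quadratic response would
be unidentifiable and biologically empty. Realized F varies continuously
within progeny types and carries the synergistic signal the quadratic
regression is meant to detect.

**Presets.** `maize_like_config` (landrace-style): 150 common, weak,
partially recessive variants (frequencies Beta(1.5, 4)), one lethal,
slightly inflated selfed residuals. `teosinte_like_config` (wild-style):
40 rarer, larger-effect variants (Beta(0.6, 10)), three lethals. These
reproduce the qualitative contrast — the bottleneck-style population has
higher per-parent total burden and higher δ despite fewer, weaker
deleterious variants individually — in ≥ 90% of seeds.

**Observation models.** Two optional layers sit between meiosis and
analysis, both off by default: a symmetric haplotype-call error that
swaps an inherited call to the parent's other haplotype at a configured
rate (a stand-in for phasing/imputation noise — the genotypes themselves
stay truth), and independent missingness that blanks calls (covering,
e.g., dormant-but-viable seed that was never sampled; dormancy is not
modeled as selection).

**What the simulator does not emulate.** Sequencing reads, GBS coverage
and imputation error (haplotype calls are truth; an error model would
sit between meiosis and analysis), population structure among founders,
selection across generations, seed dormancy (only as independent
missingness, not modeled by default), and crossover interference.
Passing tests therefore demonstrate correctness of the estimators under
the stated generative model, not robustness to genotyping artifacts.

## Problem sizes and numerical choices

Simulation-based tests use populations of roughly 500–900 progeny from
6–50 parents with 160–5,000 markers, and 50–100 replicates where rates
or biases are asserted — sizes at which the Monte-Carlo error bands
quoted in each test are meaningful for desk-scale validation. Tolerances:
exact algebraic identities at 1e−9…1e−12; oracle equivalences at 1e−6;
stochastic checks at 2–3 SE of the relevant Monte-Carlo mean. Degenerate
inputs (monomorphic GRMs, all-missing traits, zero-variance correlation
inputs, windows longer than every chromosome, zero-length regions) raise
errors rather than propagating NaN.

## Known limitations

* Variance-component SEs from the numerical Hessian are unreliable at
  boundary estimates (reported NaN) — the usual REML caveat.
* The conditional F-tests use residual degrees of freedom, not
  Kenward–Roger style adjustments; p-values near the threshold should
  not be over-read in small designs.
* SCA (hence σ²_D) is poorly resolved in designs with few crosses per
  pair; single-replicate estimates scatter widely even though they are
  unbiased across replicates.
* Map cM positions are selection-rule positions (exact 1 cM steps), not
  re-estimated genetic distances.
* The permutation test treats query windows as independent; overlapping
  observed windows are permuted independently too.
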