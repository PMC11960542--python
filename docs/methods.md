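# Methods

This note documents the statistical models, numerical choices and known
limitations of `omicqtl`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`; nothing is asserted that
the code does not itself measure.

## The mapping model

For each molecular element (gene, accessibility peak, or acetylation
peak) and each candidate cis variant *j*, the association model is a
linear mixed model

    y_i = beta_j x_ij + sum_m gamma_m PC_im + sum_n gamma_n F_in
          + sum_p gamma_p C_ip + u_i + e_ij

with `y` the inverse-normal-transformed TMM abundance, `PC` the genotype
principal components (5 by default, to absorb global ancestry), `F` the
hidden-confounder factors, `C` fixed covariates, and `u ~ N(0,
sigma_u^2 K)` a random effect whose covariance is the genetic
relatedness matrix K. K is built as `Z Z'/m` from LD-pruned (window 50,
step 5, r^2 0.2) standardized dosages and clipped to positive
semidefinite.

**Variance components.** The ratio `delta = sigma_e^2/sigma_u^2` is
estimated once per element by REML under the null (no variant) and held
fixed across cis variants — the standard fast-LMM approximation; exact
per-variant REML would cost O(n^3) per variant for no measurable gain at
these sample sizes. The REML surface is evaluated on a 100-point log10
grid over [1e-5, 1e5] and refined by bounded scalar minimization to 1e-6.
With K eigendecomposed once per tissue, every per-variant test is a
weighted least-squares Wald t-test in the rotated basis; with K = I the
scan reduces exactly to OLS (verified to 1e-8). Genotype columns
collinear with the covariates are dropped with a warning rather than
failing the element.

**Multiple testing.** Per element, the minimum nominal p is scaled by an
effective number of tests: candidate variants are processed in
consecutive chunks of 200; each chunk contributes the smallest number of
eigenvalues of its dosage correlation matrix reaching 99% cumulative
variance. Genome-wide control is Benjamini–Hochberg over the per-element
lead variants (lead = minimum corrected p, ties broken by largest
absolute effect). Significance is q < 0.05.

**Conditional signals.** Up to three conditional rounds per significant
element, each adding all previously found lead genotypes to the fixed
covariates (including in the null variance fit) and re-applying both
corrections. A conditional round is accepted when its element-corrected
p is below 0.05; the genome-wide BH pass applies across elements. The
filtering step then removes conditionals whose leads are absent from the
LD reference panel, in high LD with the primary lead (r^2 >= 0.8 or
D' >= 0.8 — either alone suffices), or monomorphic in the panel;
survivors are renumbered sequentially and every removal carries a reason
code. Elements with surviving conditionals have their primary summary
statistics re-estimated with those leads as covariates ("regressed")
before colocalization.

**Windows.** Cis windows are the element body ±1 Mb for genes and
±100 kb for peaks, anchored on the gene body by default (TSS anchoring is
available by flag; the choice is a package default, both are supported).
An exclusion-interval list (default: the hg38 MHC region) drops elements
whose window touches it; synthetic scenarios pass an empty list.

## Normalization

TMM follows the canonical trimmed-mean-of-M-values algorithm: reference
sample by 75th-percentile proximity to the mean, pairwise zero
exclusion, 30%/5% two-sided trims on M and A, inverse asymptotic
variance weights, geometric-mean-1 rescaling. The implementation is
checked against both a step-by-step re-derivation and Bioconductor
edgeR's `calcNormFactors`. Expression elements are kept when autosomal
with TPM >= 0.1 and raw count >= 6, each in >= 20% of samples (inclusive
thresholds); peaks are dropped on sex chromosomes or when TMM < 1
(strict) in >= 20% of samples. For synthetic elements TPM is
counts-per-million over a unit-length model since no transcript
structure exists. The inverse normal transform is
`Phi^-1((rank - 0.5)/n)` with average ranks on ties, so each retained
row is exactly a permutation of fixed normal quantiles.

Hidden confounders are the top principal components of the
element-centered normalized matrix restricted to the 2,000 most variable
elements. This is a deliberate, deterministic surrogate for factor
models such as PEER: the factors serve only as nuisance covariates, and
in practice they track sequencing depth and sample heterogeneity, which
PCs capture equally well. The factor interface is pluggable, and the
factor count can be chosen by pilot mapping (smallest k attaining the
maximum pilot discovery; ties to the smallest k).

## LD, complex modules, temporal classes

r^2 is squared Pearson correlation of dosages over shared non-missing
samples (>= 10 required). D' uses two-locus haplotype frequencies from
an EM over unphased genotype pairs (double heterozygotes are the only
ambiguous class; tolerance 1e-10, max 1,000 iterations; non-convergence
is an error with diagnostics).

Same-tissue primary QTLs whose leads are within 100 kb and in r^2
strictly greater than 0.8 share a signal; the per-tissue graphs are
partitioned by Louvain modularity maximization with sorted node
insertion and a fixed seed so runs reproduce. Modules of two or more
elements are complex QTLs; the rest are singletons; categories come from
the members' phenotype composition. Louvain output is checked against
exhaustive modularity maximization on toy graphs of up to 8 nodes.

Temporal classification consumes an LFSR (local false sign rate) matrix
directly — empirical-Bayes fitting of that matrix is out of scope, and
the synthetic generator emits LFSRs from planted classes (active
tissues ~ U(0, 0.02), inactive ~ U(0.2, 1)), which makes the
classification and propagation logic fully testable. LFSR exactly 0.05
counts as not significant. A cohort eQTL inherits EDev-specific/Shared
only when significant in its own discovery tissue; otherwise it is
No Association. Module propagation applies, in order: any
No Association member poisons the module; an EDev/Shared mix becomes
Shared; unanimity is kept. The map is a fixed point (applying twice
equals once).

## Colocalization

Per-variant evidence is the Wakefield approximate Bayes factor
`log ABF = 0.5 log(1-r) + z^2 r / 2`, `r = W^2/(W^2+V)`, with prior
effect SD W = 0.15 for quantitative traits. Hypothesis sums use
log-sum-exp throughout so arbitrarily large z cannot overflow. Priors
p1 = p2 = 1e-4 and p12 = 1e-5 are the colocalization method's documented
defaults, exposed as configuration. The posteriors equal brute-force
enumeration over all causal configurations to 1e-12 on every region of
up to 6 variants.

A colocalization is accepted when all five criteria hold (inclusive
bounds): >= 50 overlapping variants, PP.H4 >= 0.80, lead candidate GWAS
p <= 5e-8, lead candidate QTL p <= 5e-5, lead candidate per-variant
posterior >= 0.01. 99% credible sets take variants in descending
posterior order until cumulative mass crosses 0.99 (the crossing variant
included); sets of <= 25 variants are high-confidence. GWAS loci are the
survivors of sliding-window LD pruning (500-variant window, step 5, r^2
0.1) among genome-wide-significant variants; when a linked pair must be
broken the smaller-MAF member is removed, ties to the later position —
the pruning dialect is not fully specified by the upstream tool's
description, and block-structured toys are insensitive to it.
Colocalizations attach to the locus whose index variant is within 350 kb
at r^2 >= 0.7 (best r^2 when several qualify); lead candidates absent
from the reference panel fall back to the nearest same-trait locus.
Complex modules are represented in colocalization by one member chosen
uniformly among those whose leads are in the reference panel (all
members if none are), with a seeded generator.

## MOPCV prioritization

High-confidence credible-set variants intersect TF motif occurrences
with BED conventions: a 1-based variant at p hits a 0-based half-open
interval [s, e) iff s <= p-1 < e. Priority is the first matching rule:
High — the variant is in a caQTL signal's credible set and inside that
signal's own caPeak (any module caPeak for complex modules); Moderate —
inside the caPeak of a different caQTL signal; Low — otherwise,
including variants overlapping only accessibility peaks without a caQTL
and variants in no caQTL credible set (the default keeps the ranks a
partition). "Present in a caQTL signal" is interpreted as membership in
that signal's 99% credible set. Whether the Moderate rule should also
require the other signal to colocalize with the same locus is left
unrequired. Ranks are stable under addition of motifs; motif hits decide
membership only.

## The synthetic generator

Genotypes use a founder-mosaic model rather than a coalescent: sample
haplotypes copy founder haplotypes block-wise, switching founders
between adjacent blocks with a configurable probability. This produces
strong within-block LD (|r| = 1 in the two-founder limit), LD decaying
with block distance (independence at switch probability 0.5), and, via
block-level transmissions from in-family parents, realized kinship
matching pedigree expectations (parent-offspring GRM entries near 0.5).
It does not reproduce realistic human LD maps, recombination hotspots,
population stratification beyond the PC mechanism, sex chromosomes, or
imputation dosages — so passing tests demonstrate the statistics behave
correctly under the assumed model, not performance on real cohorts.

Phenotypes are generated by the same structure the mapping model
assumes: planted standardized-genotype effects (in latent SD units),
hidden factors, a kinship-correlated polygenic term and independent
noise, observed through a Poisson–log-normal layer with log-normal
library sizes. Any overdispersed count model would do, because the
pipeline consumes only TMM + inverse-normal values. Default study
conditions: 200 samples in four families of 4–6 plus unrelated
founders, planted effects of 1 latent SD at MAF ≈ 0.3, noise SD 1,
hidden factor SD 0.5, polygenic SD 0.3, GWAS N = 50,000 with reference
panels of 200 — chosen once as representative of a mid-sized molecular
QTL cohort and held fixed.

GWAS summary statistics draw z ~ MVN(sqrt(N) R b, R) from the reference
panel's dosage correlation matrix, with se = 1/sqrt(2 N p (1-p));
ill-conditioned R is ridge-regularized with a declared epsilon and
logged. Annotation fixtures construct, per requested label, the exact
peak/motif/credible-set geometry that defines that MOPCV rank, so
ranking accuracy has constructed ground truth.

## Problem sizes

The default verification scenarios use 300 all-null elements at n = 150
with ~100 cis variants each for FDR calibration; 50 planted-effect
elements at n = 200 for power and bias; 15–40 replicates for
conditional-signal and colocalization calibration; 300–500 replicates
for credible-set coverage; 1,000 pairs for temporal recovery. These
sizes give binomial standard errors small enough for the stated bounds
while keeping a full run in minutes on one core.

## Known limitations

- Single-causal-variant assumption in colocalization (no multi-signal
  fine-mapping); conditional GWAS signals are not modeled.
- The effective-tests correction is slightly conservative for highly
  fragmented LD, which lowers the realized false discovery rate below
  the nominal level on null data.
- Conditional-round significance uses the element-corrected p rather
  than a genome-wide pass per round; at cohort scale the difference is
  absorbed by the subsequent BH over conditional leads.
- The founder-mosaic LD model has no recombination within blocks;
  D'-based filtering is exercised mainly through constructed fixtures.
- Trans effects, interaction QTLs, dosage genotypes and X-chromosome
  models are out of scope.
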