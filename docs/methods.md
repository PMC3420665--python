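# Methods

## Problem and model

A gene or region yields $p$ variant sites, most of them rare, for $n$
sequenced individuals with a continuous trait $y$. With additive coding
$g_{ij} \in \{0,1,2\}$ (minor-allele count of variant $j$ in individual
$i$), the working model is the linear predictor

$$ y_i = \mu + \sum_{j=1}^{p} \beta_j g_{ij} + \varepsilon_i . $$

Rare-variant association asks two questions: is any $\beta_j$ nonzero
(gene-level association), and if so which ones (variant-level
localization). Because $p$ can approach $n$ and most columns are
near-constant, the model is fit with regularization. Five estimators are
implemented:

* **PCR** — the fitted response with $k$ components is
  $\hat y = \bar y + \sum_{m \le k} u_m u_m^\top y_c$, where $u_m$ are
  left singular vectors of the column-centered design ordered by
  decreasing singular value and $y_c$ is the centered response.
* **PLS** — scores are built by the standard predictor-deflation
  recursion with first weight vector $\propto X^\top y_c$;
  $\hat y = \bar y + \sum_{m \le k} z_m z_m^\top y_c / (z_m^\top z_m)$.
* **Ridge (RR)** — via the SVD,
  $\hat y = \bar y + \sum_m u_m \frac{d_m^2}{d_m^2+\lambda} u_m^\top y_c$.
  $\lambda = 0$ is ordinary least squares (pseudoinverse on
  rank-deficient designs); presets $\lambda \in \{0, 10\}$ are exposed.
* **LASSO** — a descending 100-point log-spaced penalty path from
  $\lambda_{\max} = \max_j |X_j^\top y_c|/n$ down to
  $\varepsilon\lambda_{\max}$ ($\varepsilon = 10^{-3}$ if $n > p$, else
  $10^{-2}$), with the path computed by coordinate descent
  (scikit-learn) and the penalty chosen by an information criterion.
* **Sparse PLS (SPLS)** — per component the direction vector
  $X_d^\top y_c$ is hard-thresholded at $\eta \cdot \max_j |w_j|$;
  variables surviving any of the first $K$ components form the active
  set, refit by plain PLS; $(K, \eta)$ chosen on a grid by the same
  information criteria. $\eta = 0$ recovers PLS exactly.

### Fit statistics

Association strength is a single scalar per fit, oriented so larger
means stronger: for RR/PCR/PLS the Pearson correlation
$\mathrm{cor}(y, \hat y)$ (defined as 0 when $\hat y$ has zero
variance), and for LASSO/SPLS $-\log_{10}$ of the F-test p-value of the
ordinary-least-squares refit on the selected columns (an empty selection
scores 0; a saturated or perfect refit is flagged degenerate and scored
at the floating-point minimum p). Note the correlation statistic is
scale-invariant, so under extreme ridge shrinkage it tends to its
heavy-shrinkage limit $\mathrm{cor}(y, XX^\top y_c)$ rather than to
zero, even though $\hat y \to \bar y$.

### Model-size selection

* PCR/PLS: either one component ("Comp1") or the smallest $k$ whose
  training $R^2$ reaches a fraction $\theta$ (default 0.80,
  configurable) of the full-rank $R^2$ ("Compk").
* LASSO/SPLS: minimize
  $\mathrm{IC} = n\log(\mathrm{RSS}/n) + c \cdot \mathrm{df}$, with df
  the number of nonzero coefficients (LASSO) or the active-set size
  (SPLS), and $c = 2$ (AIC), $\log n$ (BIC), or
  $(\log\log n)(\log p)$ (GIC — a standard high-dimensional choice; the
  multiplier is configurable). Ties go to the sparser model.

Design columns are mean-centered but **not** variance-scaled: scaling
would inflate near-monomorphic rare-variant columns by factors of 10 or
more, and the fixed ridge presets are calibrated on raw allele counts.

## Pooled-threshold augmentation

Motivated by variable-threshold burden testing, the predictor space can
be augmented with pooled counts $C_t(i) = \sum_{j: q_j \le t} g_{ij}$
for a lattice of rarity thresholds $T$ = {0.05} ∪ {observed MAFs
< 0.05}. The ≤ comparison is used so each observed-MAF threshold
actually changes the membership set. Pooled columns that exactly
duplicate one another collapse to the largest threshold's column, and a
pooled column identical to a single original column is dropped; both
rules remove exactly collinear predictors. Method labels carry a
".p" suffix when pooled columns are present.

## Comparators

* **WE** (weighted sum): per-individual score
  $S_i = \sum_j g_{ij} / \sqrt{n q_j (1-q_j)}$; the continuous-trait
  statistic is $|\mathrm{cor}(y, S)|$. (The classical form is a
  case-control rank sum; the correlation adaptation is this package's
  choice and is exercised only through its permutation null.)
* **VT** (variable threshold):
  $z(t) = |\sum_i (y_i - \bar y) C_t(i)| / \sqrt{\sum_i C_t(i)^2}$
  maximized over the same ≤-threshold lattice as the pooled
  augmentation.
* **SKAT**: $Q = r^\top G W^2 G^\top r$ with intercept-only residuals
  $r$ and Beta(1, 25)-density weights on the sample MAFs. No asymptotic
  p-value is computed: all methods, SKAT included, are calibrated by the
  same permutation scheme, so the statistic alone suffices.

## Permutation inference

The phenotype vector is permuted against the genotype rows; every
model-fitting step, including IC minimization over the penalty/grid and
component-count selection, is repeated inside each permutation (this is
essential: the selection step makes the observed statistic the maximum
of many fits, and a null that skipped re-selection would be badly
anti-conservative). Pooled columns are not rebuilt — genotypes do not
change under a phenotype permutation. The empirical p-value is the
add-one estimate $p = (1 + r)/(B + 1)$ with $r$ the number of
permutation statistics $\ge$ the observed one (ties count as extreme);
its floor is $1/(B+1)$. An optional sequential mode stops after a fixed
number of exceedances (default 50) and reports $r/B_{\text{used}}$; it
is off by default. Randomness uses NumPy's PCG64 generator; identical
seeds give bit-identical results, and per-dataset/per-method streams are
spawned from the master seed so results do not depend on the order in
which methods are listed.

A permutation whose statistic evaluation raises is scored $-\infty$
(never extreme, hence conservative) with a warning.

## Genotype handling

MAF is computed from non-missing entries as (allele count)/(2 ×
non-missing individuals), with columns above 0.5 recoded $g \to 2-g$;
the frequency is recomputed after recoding so a second pass is a bit-level
no-op. Missing genotypes are imputed once per dataset, before analysis,
from Hardy–Weinberg probabilities $\{(1-q)^2, 2q(1-q), q^2\}$ at the
computed MAF, and MAFs are then recomputed on the completed matrix.
Monomorphic variants are removed. MAF uses all individuals (the trait is
continuous; there is no case/control split). Pooled counts are kept as
raw counts (not capped or standardized).

## Synthetic data

Real sequenced genotypes for the three study genes are private, so the
generator reproduces their marginal structure. Panels are described by a
profile (n individuals, p variants, number of rare sites); the shipped
presets mirror the three genes: 98/28/122 polymorphic sites of which
85/26/99 are rare (MAF < 1%), at n = 1998. Rare target MAFs are drawn
from a density ∝ 1/x on [1/(2n), 0.01) — the neutral-spectrum-like
shape under which most rare variants are very rare — and common MAFs
uniformly on [0.01, 0.5]. Genotypes are Binomial(2, q) per individual;
each column is redrawn until it is polymorphic and its realized MAF
falls in its intended rarity class, so realized rare counts match the
profile exactly. An optional AR(1) Gaussian-copula mode (two latent
haplotype fields per individual) induces linkage disequilibrium between
adjacent variants; the default is independence, so these simulations
cannot show any benefit the dimension-reduction methods might draw from
long-range LD in real genes — a deliberate limitation to keep the
generating model transparent.

Phenotype scenarios (presets I.1–I.6, II.1–II.6, plus a null):

| id | causal MAF | direction | causal | mean effect (SD) |
|----|-----------|-----------|--------|------------------|
| *.1 | < 0.01 | deleterious | 10% of rare | 1.64 |
| *.2 | < 0.01 | deleterious | 4 rare + 4 common | 1.64 / 0.07 |
| *.3 | < 0.01 | deleterious | 10% of rare | 1.0 |
| *.4 | < 0.01 | deleterious | 20% of rare | 1.0 |
| *.5 | < 0.01 | 7.5% del. / 7.5% prot. | 15% of rare | ±1.64 |
| *.6 | < 0.001 | deleterious | 20% of rare | 1.64 |

Set I uses a constant effect; set II makes the effect inversely
MAF-dependent, $\delta_j = c\, w(q_j)$ with default $w(q) = 1/\sqrt q$
(pluggable) and $c$ solved so the mean over the rare causal set equals
the target exactly (to 1e-12 by construction). The causal set is redrawn
for every simulated dataset. Percent-to-count rounding is half-to-even
with a floor of one causal variant (a fraction of exactly 0 yields the
null scenario: no causal variants). Bidirectional scenarios size the
deleterious half as round(7.5% × eligible) and give the remainder
negative effects. Phenotypes: non-carriers draw from N(0, 1); a carrier
draws from N(δ*, 1) where δ* belongs to the rarest causal variant
carried. Baseline mean 0 and SD 1 are without loss of generality since
effects are in SD units.

## Power harness

Power is the fraction of S simulated datasets with empirical p ≤ α
(default α = 0.05); its Monte-Carlo SE is
$\sqrt{\hat\pi(1-\hat\pi)/S}$, at most 1.6% when S = 1000. For LASSO
and SPLS the harness also averages, over datasets, the number of design
columns selected, the number of truly causal variants among them, and
the number of pooled columns — the variable-selection view of
performance.

## Problem sizes used in the shipped checks

The acceptance tests and `scripts/acceptance.py` run scaled versions of
the full study, chosen as the package's own evaluation sizes:

* null calibration on a gene-B-like panel at n = 500 (28 variants, 26
  rare), S = 400 datasets (S = 150 for the sparse methods), B = 99
  permutations, with the rejection-rate band the 99% binomial interval
  for the S actually used;
* comparative power at n = 500, p = 50 (42 rare), S = 150, B = 99,
  scenarios I.1 and I.5, each method in its standard configuration
  (PCR/PLS "Compk", RR λ = 10, LASSO/SPLS under AIC);
* the SPLS evaluation grid is K ≤ 4, η ∈ {0.1, 0.3, 0.5, 0.7, 0.9}
  (the full default grid is K ≤ min(10, rank), η ∈ {0.1, …, 0.9}).

At these sizes the strong-effect scenarios sit near the power ceiling,
which compresses differences between SKAT and the regressions relative
to a full n ≈ 2000 study; orderings among near-tied methods should be
read with the binomial SE in mind.

## Numerical choices and degenerate inputs

Rank is determined from the SVD with a relative tolerance of
1e-10 × max(n, p) × d₁. Zero-covariance responses (Xᵀy_c = 0) yield a
null fit with statistic 0 rather than an error, so permutation loops
never abort. RSS = 0 makes an information criterion −∞ — such a model
wins immediately and is flagged degenerate. IC ties resolve to the
larger penalty (sparser model). The Compk rule breaks ties toward
smaller k. Empty pooled-member sets produce no column; a gene with no
variant at or below the 5% threshold simply has zero pooled columns.

## Known limitations

Covariates are not supported (the fit statistic is a global
goodness-of-fit measure; adjusting it to isolate genetic effects would
require restructuring). Binary traits, phasing, annotation weights and
multi-gene modelling are out of scope. The WE continuous-trait
adaptation and the GIC multiplier are reasonable but non-unique choices;
both are configurable. Independence between variants in the default
generator means the simulations say nothing about performance under
strong LD.
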