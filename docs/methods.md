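# Methods notes

This note records the models implemented in `mnqtl`, the conventions
adopted where the underlying methodology is open to interpretation, and
what the synthetic-data studies do and do not establish.

## Interaction descriptors and observed strengths

The descriptors `Z_mu, Z_an, Z_ag, Z_al` are closed-form functions of a
single abundance snapshot of a pair, with the orientation (`u` = more
abundant) re-derived from the data, so results are invariant to input
order. Key algebraic facts used throughout (and enforced by tests):
`Z_al = 1 − 1/Z_ag`; scaling both abundances by `c` scales `Z_mu` by `c`
and leaves `Z_ag`, `Z_al` unchanged; for observed strengths
`A_g·A_l = 1` and `M_u = (x_u/w_u)(x_v/w_v)·A_n` wherever both sides are
defined.

Conventions:

- **Antagonism rendering.** The printed antagonism formula is ambiguous.
  Default: `Z_an = 1/(x_u x_v (x_u − x_v))` (`reciprocal_product`);
  alternative `(x_u − x_v)/(x_u x_v)` (`inverse_mutualism`, the exact
  reciprocal of `Z_mu`). Both are positive for `x_u > x_v > 0`. Any
  analysis using `Z_an` should state which form it used.
- **Ties and zeros.** `x_u = x_v` leaves `Z_mu/Z_an` undefined; pairs
  are flagged missing (NaN) with a warning rather than raised, because
  ties are routine in sparse count data; `strict=True` raises. Zero
  abundances void the whole pair; an optional pseudocount (default off)
  can rescue them.
- **Winsorization.** `Z_mu` and `Z_an` diverge as `x_u → x_v`;
  `InteractionTensor.winsorize(q)` caps both per host at quantile `q`
  (suggested 0.99) before network construction. The permutation null
  used for edge significance applies the same per-host capping so
  observed and null means are compared on one footing.
- **Relative vs absolute abundances.** A `normalize` switch converts to
  per-host relative abundances; `Z_ag`/`Z_al` are unaffected,
  `Z_mu`/`Z_an` are not scale-free and do change.
- **Applicability.** `M_u` is meaningful only when both co/mono ratios
  exceed 1, `A_n` only when both are below 1; descriptor-vs-strength
  validation correlations restrict those channels to their applicable
  pairs.

## Growth curves and phases

Three sigmoids are fitted by least squares: logistic
`K/(1+e^{−r(t−t_m)})`, Gompertz `K e^{−e^{−r(t−t_m)}}`, and the
four-parameter Richards `K(1+ν e^{−r(t−t_m)})^{−1/ν}` (ν = 1 recovers
the logistic; ν → 0 the Gompertz). Initial guesses: `K` = max
abundance, `r` from the log-slope of the middle third, `t_m` at the
half-max crossing; on failure, five jittered restarts with a fixed seed.
Model selection uses AICc by default (BIC available, plus a nested RSS
F-comparison); on effectively exact fits the RSS is floored at a √ε
relative scale so the parsimony penalty resolves ties.

Phase segmentation is a convention, not a published rule: the lag phase
ends at maximum growth acceleration, the log phase at maximum
deceleration. In the substitution `u = e^{−r(t−t_m)}` both extrema of
`f''` solve `u² − (3+ν)u + 1 = 0` for every model in the family, giving
closed-form boundaries; the logistic case is `t_m ± ln(2+√3)/r`.
Boundaries outside the observed window are clamped with a warning.

## Network reconstruction

Cohort-average networks: a pair's test statistic is its cross-host mean
descriptor; the null reshuffles taxon labels independently within each
host (B permutations, fixed seed) and recomputes; per-pair permutation
p-values get Benjamini–Hochberg FDR control at α. This permutation
scheme is a documented convention — the original edge-significance
procedure is unspecified. Note the granularity constraint: the smallest
achievable p-value is `1/(B+1)`, so B must comfortably exceed
`m(m−1)/(2α)` for any edge to survive BH in large communities.
Mutualism/antagonism networks are undirected; aggression/altruism edges
are oriented from the more to the less abundant taxon by majority vote
across hosts, which also guarantees no 2-cycles. Per-host networks skip
the cross-host test: edges are finite descriptors at or above a
per-host quantile (default 0.9; 0 keeps all).

### Property indices

Closeness, betweenness (fractional counting over multiple shortest
paths), eccentricity, eigenvector centrality and PageRank are
implemented directly from their defining equations on BFS
distance/path-count machinery and dense linear algebra, so an external
graph library can act as an independent cross-check in the tests rather
than the implementation. Conventions:

- Disconnected graphs: closeness/eccentricity are computed within each
  node's reachable set and the reachable fraction is reported; isolated
  nodes get NaN.
- Eigenvector centrality solves `AG = λG` (right eigenvector — the
  importance a microbe derives from those it points to) by power
  iteration on `A + I`, which cannot oscillate on bipartite graphs.
- PageRank as printed uses a non-normalized teleport `(1−d)`; the
  standard `(1−d)/m` variant is an option. The two differ by the factor
  `m` only, so rankings coincide. `K` is the out-degree of the linking
  node; dangling mass is spread uniformly. Both variants are solved as
  linear systems.
- Connectivity is the mean number of incident links per node (in+out
  for directed networks). Per-network scalars for the five node-level
  indices are means over microbes.
- Hubs: degree above median + 1 MAD (configurable; no published
  cutoff), with a Welch t-test of hub vs non-hub abundance. Role
  labels: leader/follower (mutualism), antagonist/agonist (antagonism),
  hawk/dove/hawk-dove (aggression: out-only/in-only/both), and
  altruist/beneficiary/altruist-beneficiary (altruism).
- Scale-freeness: discrete power-law (Hurwitz-zeta) maximum likelihood
  with `kmin` fixed at the smallest positive degree, and a parametric
  bootstrap Kolmogorov–Smirnov goodness-of-fit p-value; fewer than 10
  positive-degree nodes is reported undefined.

## QTL mapping

Phenotypes are residualized on fixed-effect covariates (intercept
included); a user-supplied relatedness/covariance matrix triggers GLS
whitening instead — no kinship structure is assumed by default because
none is generally available. Genotypes are coded AA/Aa/aa → 1/0/−1
(VCF alt-dosage 2/1/0 maps accordingly); missing genotypes drop hosts
per-SNP; classes below 2 members are excluded with a warning.

The alternative model gives each genotype class its own normal mean with
a pooled ML variance; the null has one mean. The LRT reduces to
`n ln(σ̂₀²/σ̂₁²)`, is invariant to affine transforms of `y`, and is
asymptotically χ² with (classes−1) df under the null. Genome-wide
thresholds come from the permutation distribution of the max-LRT over
SNPs under phenotype shuffling (defaults: 1000 permutations, α = 0.05),
computed per phenotype with no cross-phenotype correction. The scan is
vectorized over SNPs and permutation copies (three indicator-matrix
products per genotype class), which makes permutation thresholds cheap.

## Path analysis

Reported genotype–phenotype correlations use a class-conditional
Gaussian mutual-information estimator,
`Î = ½[ln σ̂²_tot − Σ_c π̂_c ln σ̂²_c]` mapped to the correlation scale by
`|r| = √(1−e^{−2Î})` with the sign of the dose covariance; the estimator
subtracts its independence-bias `(C−1)/n` (under independence `2nÎ` is
asymptotically χ² with `2(C−1)` df). Dose-coded Pearson correlation is
available as an alternative, and supplies the p-values for mediator
screening (two-sided, retain at p ≤ 0.10).

The decomposition itself uses standardized multiple-regression weights
of `z` on `(g, y_1..y_k)` obtained from the normal equations in
correlation form. This makes the identity
`r_gz = P_{z←g} + Σ_j P_{z←y_j} r_{gy_j}` and
`R² = β′R_xx β ∈ [0,1]` exact, and generalizes the printed
single-mediator system to several mediators in the standard
path-analysis way. The alternative single-path variant — constraining
`P_{z←y} = r_yz` and letting the direct path absorb the remainder — is
available via `decompose(..., single_path=True)`; it follows the
published single-mediator identity literally but is not a least-squares
solution. Collinear mediator sets are rejected with the condition
number reported. Seasonal perturbation mediators (winter − summer
property differences) use only hosts measured in both seasons.

## Synthetic cohorts and the power study

The generator emulates a season-paired gut-microbiome GWAS cohort: 127
hosts, 8 interacting microbes, biallelic SNPs in Hardy–Weinberg
proportions with allele frequency ~ U(0.2, 0.5), log-normal abundance
noise with unit log-scale variance and a fixed log-abundance spacing of
2 between adjacent microbes (so dominance orientations are stable).
Effect-size schemes fix the causal SNP's share of phenotypic variance on
each affected microbe's log-abundance: small 1–5%, moderate 5–10%, big
10–20%.

The mapping from "a QTL that affects abundance" to "a QTL that affects
interactions" is the largest open modeling choice. Conventions here:

- **Mutualism scenario:** the causal genotype adds the same effect to
  the log-abundance of a cooperating subset (default 4 of 8 microbes).
- **Aggression scenario:** the genotype raises the two most abundant
  (dominant) microbes and suppresses the two least abundant
  (subordinate) ones, shifting every dominance ratio between the sets
  in the same direction. (Suppressing mid-ranked taxa instead would
  partially cancel in rank-weighted aggregates.)
- **New-model phenotype:** the per-host mean log descriptor weight of
  the scenario's interaction network — a connectivity-weighted mean
  interaction strength on the scale where abundance effects are
  additive. The traditional-model phenotype is one affected microbe's
  log-abundance.

The per-scan SNP count defaults to 10. This was inferred from the
noncentral-χ² power relation: at n = 127 with the schemes above, the
genome-wide max-LRT threshold implied by a 10-SNP scan reproduces the
published power profile of single-taxon abundance scans across all
three effect-size classes, whereas a large (say 100-SNP) scan pushes the
threshold to ≈15.2 and makes small-QTL abundance power collapse to
≈0.05. The network scan's power advantage then emerges mechanistically:
the network property pools the genetic signal shared by the coupled
microbes, raising the effective variance fraction several-fold.

Defaults: 1000 replicates (200 for reduced runs), 200 permutations per
scan inside replicates, α = 0.05. Power is the fraction of replicates
whose causal SNP exceeds its own genome-wide threshold, with binomial
SE; the false-positive rate pools declarations over non-causal SNPs.
All randomness descends from one master seed through spawned
`SeedSequence` children, so every table is bit-reproducible.

### What the synthetic studies do not show

The generator draws independent log-normal abundances around fixed
baselines; it does not emulate 16S compositionality, sequencing depth
variation, zero inflation, taxon correlation structure beyond the causal
coupling, linkage disequilibrium between SNPs, or relatedness between
hosts. Passing power and calibration checks therefore demonstrates the
statistical machinery under the stated generative conventions, not
performance on real cohort data — in particular, real-data edge
significance inherits the permutation-null convention above, and
`Z_an`-based results inherit the antagonism-form choice.

## Numerical details

- Permutation p-values use the add-one estimator `(1+#{null ≥ obs})/(1+B)`.
- Within-class variances are floored at 1e−12 and flagged degenerate
  when hit; constant phenotypes give LRT = 0 by convention.
- Power iteration tolerance 1e−14; PageRank solved exactly by LU.
- Growth fits use `curve_fit` with bounds `K, r, ν > 0` and tight
  (1e−14) termination tolerances.
- Bootstrap zeta sampling truncates the tail at cumulative mass
  1 − 1e−9.
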