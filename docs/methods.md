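# Methods

## Model

For one gene with K exons observed across G conditions and a set of time
points (with optional replicates), the read count on exon k of sample i is

    Y_ik ~ NegBin(nu, p_ik),    P(Y = y) = Γ(nu+y) / (y! Γ(nu)) p^nu (1-p)^y,

so the mean is nu (1-p)/p and the variance nu (1-p)/p².  The linear
predictor acts on the logit of the success probability,

    logit p_ik = log(beta_i) + eta(t_i, g_i) + z_k b_k,

with `beta_i` a per-sample scale offset, `z_k` the exon length in kilobases
and `b_k ~ N(0, sigma²)` a per-exon random effect capturing exon-to-exon
expression differences within the gene.  Under this parameterization the
mean count is `nu exp(-zeta)`: the linear predictor is a *link* scale and a
larger eta corresponds to a smaller mean.  Nothing downstream depends on the
sign convention; it is stated here so that fitted surfaces are read
correctly.

Replicates are independent samples sharing eta and b.  With K = 1 the
length-scaled random effect is confounded with the baseline; the ridge
penalty keeps the fit unique.

### Functional-ANOVA mean surface

Time is affinely mapped to [0, 1] per gene (recorded in the fitted model for
invertibility; the mapping leaves the test statistics unchanged and makes
smoothing-parameter scales comparable across genes).  The surface decomposes
as

    eta(t, g) = eta_0 + eta_1(t) + eta_2(g) + eta_12(t, g)

with side conditions ∫eta_1 = 0, Σ_g eta_2 = 0, ∫eta_12(·,g) = 0 for all g
and Σ_g eta_12(t,·) = 0 for all t.  The smoothness penalty

    J(eta) = theta_1⁻¹ ∫ (eta_1'')² + theta_12⁻¹ ∫ Σ_g (eta_12'')²

penalizes curvature only.  The reproducing kernel of the cubic-spline
construction on [0,1] uses scaled Bernoulli polynomials,
R(s,t) = k2(s)k2(t) − k4(|s−t|) with k1(x) = x−1/2, k2 = (k1²−1/12)/2,
k4 = (k1⁴−k1²/2+7/240)/24; the treatment kernel is I[g1=g2] − 1/G and the
interaction kernel their tensor product.  The unpenalized null space holds
the constant, the linear-in-t function k1(t), G−1 zero-sum treatment
contrasts, and (when the interaction is modelled) k1(t) × contrast columns.
Side conditions hold by construction of this basis.  Representers are
anchored at the distinct (t, g) design points — replicates share an anchor —
which contains the exact minimizer of the penalized problem and is cheap at
these design sizes (≤ ~16 anchors).

## Estimation

The penalized Henderson likelihood

    Σ_ik [(nu+Y) log(1+e^zeta) − nu zeta] + Σ_k b_k²/sigma² + N λ J(eta)

(N = number of observations = samples × exons) is minimized by an inner
Fisher-scoring/IRLS loop: at the expansion point the working response is
Ỹ = ζ̃ − μ̃/ω̃ with score μ̃ = (nu+Y)p̃ − nu and expected information
ω̃ = nu(1−p̃); all coefficients (fixed, kernel, random) are solved jointly in
one penalized weighted least squares per iteration, with step-halving on the
exact objective, so the objective trace is non-increasing.  p̃ is clipped
away from 1 so weights never vanish; wild trial steps are rejected by the
halving rather than producing NaNs.  Defaults: relative objective tolerance
1e-7, ≤ 50 iterations, ≤ 20 halvings.

### Smoothing-parameter selection

theta_1 is fixed at 1 (its scale is absorbed by λ).  (λ, theta_12/theta_1,
sigma²) are chosen by a GML (REML-type) score of the Gaussianized terminal
working system: the working response is treated as Gaussian with covariance
s0²W⁻¹, penalized coefficients as Gaussian effects with precision
proportional to the penalty blocks, s0² profiled out.  The search is a
deterministic coordinate sweep over the grids log10 λ ∈ {−5,…,1} (7 points),
ratio ∈ {1/4, 1, 4} and sigma² ∈ {1/4, 1, 4}, optionally followed by a
Nelder-Mead polish (`FitOptions(polish=True)`).

The GML choice is load-bearing.  Prediction-style scores (observation-level
GCV, and an exact leave-one-design-point-out score, both retained as
`selection_score` options) favour interpolating any between-cell variation
that exceeds the counting noise — including the *scrambled* profiles that
the permutation test generates — because at nu ≈ 1000 the NB noise is tiny
relative to profile variation.  A marginal-likelihood score may instead
explain a rough profile as inflated noise around a smooth curve.  In the
permutation null this interacts with the dispersion estimate (below) to
flatten shuffled data, which is what gives the test its power.

### Dispersion

nu is estimated by profile likelihood.  The textbook alternation — fit the
mean model, then minimize the nu objective
(1/N) Σ [log Γ(nu) − log Γ(nu+Y) − nu log p] at frozen p — is exact
coordinate descent, but the two blocks are coupled through the baseline
almost perfectly (refitting at a new nu re-matches the means, moving p
back), so it crawls: measured steps of ~0.5 per round starting at nu ≈ 5
with a target of 1000.  The implementation reaches the same stationary point
with a mean-preserving profile update: holding the fitted means
mu = nu(1−p)/p fixed, substitute p(nu) = nu/(nu+mu) into the NB likelihood
(both the `nu log p` and the `Y log(1−p)` terms then depend on nu) and
minimize over log nu by bounded scalar search; the refit is warm-started
with the baseline shifted by log(nu_new/nu_old).  Two to three outer rounds
suffice.  `estimate_nu` retains the frozen-p objective for direct use.
Bounds [1e-2, 1e6]; a boundary estimate raises a warning.  Initialization is
method-of-moments per exon, clipped to [1, 1e4].

## Testing

### Per-gene two-stage classification

NPDE test: full model F = {eta_0, eta_1, eta_2, eta_12} versus reduced
R = {eta_0, eta_1, eta_2}.  PDE test (only for genes not significant in
stage 1): F = {eta_0, eta_1, eta_2} versus R = {eta_0, eta_1}.  C is the
constant model {eta_0}.  nu and the smoothing hyperparameters are selected
on F and shared by R and C, so the three fits differ only in the mean terms
available to them.  The statistic is

    KLR = KL(eta_F, eta_R) / KL(eta_F, eta_C),

where KL is the exact average NegBin Kullback-Leibler divergence between
the fitted observation-level distributions at shared nu,

    KL = (1/N) Σ [ nu/p · log((1−p)/(1−p̂)) + nu (zeta − zeta_hat) ].

It is invariant to exon relabelling and to a common rescaling of the library
sizes (the offset shift is absorbed by the unpenalized baseline).

P-values are permutation-based with strict-greater counting, #{T* > T}/B, on
the grid {0, 1/B, …, 1}; a reported 0 means p < 1/B.  The entire pipeline —
smoothing selection and dispersion estimation — is re-run on every shuffled
dataset.  Two deliberate conventions:

1. **The normaliser is a per-gene constant.**  Permuted statistics are
   KL(F*, R*)/KL(F, C)_observed; equivalently the test compares the
   tested-term distances KL(F, R) directly.  The denominator exists to make
   KLR comparable across genes (it feeds the gene-set score); inside a
   per-gene permutation test it is a constant.  Re-normalizing each permuted
   draw by its own collapsed denominator would make the statistic scale-free
   — a ratio of two near-zero quantities under the null — whose broad null
   distribution destroys the separation the method demonstrably achieves.
   Measured on the cyclic study: observed interaction distances ≈ 28 against
   null draws ≤ 0.01 (on the observed-normaliser scale).

2. **The shuffle matches the tested term.**  The NPDE null shuffles time
   labels within condition (all exons of a sample move together; the
   multiset of (condition, time) pairs is preserved).  Shuffling destroys
   smooth time structure: the re-estimated dispersion collapses (measured
   nu* ≈ 2 vs nu ≈ 3700 on a cyclic gene) and the re-selected smoothing
   flattens the fit, so permuted interaction distances are tiny.  The PDE
   null instead shuffles *condition* labels within each time point: time
   shuffling would leave a treatment main effect fully intact and is not an
   exchangeability argument for eta_2 = 0 (using it makes stage 2
   anticonservative for genes with time-varying shared profiles — observed
   directly before the change).  A global time shuffle across conditions is
   available behind a flag.

Stage 1 applies Benjamini-Hochberg across all genes; genes with adjusted
p < alpha are NPDE.  Stage 2 applies BH within the remaining subset;
significant genes are PDE, the rest NDE.  Per-gene fit failures mark the
gene NDE with a flag.  Defaults B = 100, alpha = 0.05.

### Gene sets

A set's score is the mean KLR of its members present in the data.  Each
permutation round shuffles every gene's time labels independently and
recomputes every gene-level statistic once (shared across all sets
containing the gene, with the gene's observed normaliser); the set p-value
counts permuted scores strictly above the observed score.  Size filtering
(defaults 15–30 genes, ≥ 5 present) is applied before testing; B = 100 by
default.

## Library-size normalization

`tmm_effective_library_sizes` implements the TMM construction (trim 30% on
M-values, 5% on A-values, delta-method precision weights, upper-quartile
reference) and matches Bioconductor edgeR to 6 decimals on a fixture.
`attach_library_sizes` defaults to attaching the TMM *factors* alone
(geometric mean one), treating samples as sequenced to a common depth with
composition correction only; `mode="effective"` attaches totals × factors.

The distinction matters whenever expression changes are coordinated across
many genes: per-sample totals then carry biology, not depth.  In the
simulation studies (all genes generated at unit depth, most co-varying in
time) attaching totals × factors injects a spurious smooth condition-time
offset into every gene and ruins the error control (measured FDR 0.5 in the
scenario-1 study); with 2/3 of genes sharing one profile even the factors
acquire a condition-specific time ramp (log beta from +0.18 to −0.24) and
every null gene set becomes significant.  The validation studies therefore
analyze the simulated data at the generated unit depth.  For real data,
where totals are dominated by sequencing depth, the default factors mode (or
effective mode) is appropriate — but the composition caveat applies to any
total-count normalization in time-course designs.

## Simulator

`simulate` draws counts from the generative model itself: per gene,
b_k ~ N(0, sigma_b²) once, zeta = eta(t, g) + z_k b_k (beta = 1 at
generation), Y ~ NegBin(nu, logistic(zeta)); replicates are independent
draws.  Default study conditions: t = i/10 for i = 1..8, two conditions,
z = (0.1, 0.25, 0.4) kb, nu = 1000, sigma_b = 1.  DE mean patterns:

- linear: eta = C((0.9 − 2t) I[g=2] + t), C = 2 — crossing straight lines;
- exponential: eta = exp(10⁴ F1¹¹ F2⁶ + 10² F1³ F2⁹ + C_g), C_g = 1 — a
  condition-reversed bump (this expression is used directly on the link
  scale, as stated; with C_g = 1 it spans ≈ 2.7–3.2);
- cyclic: eta = sin(2.5π((0.9 − 2t) I[g=2] + t)) + 2 — phase-reversed sine.

NDE genes re-use the g = 1 branch for every condition (scenario 1: 25 DE +
25 NDE) or a flat profile at the time-average of that branch (scenario 2:
25 DE + 225 NDE; the flat level is not prescribed anywhere, the time-average
keeps the count scale comparable).  The gene-set study simulates 30 disjoint
sets of 10 genes, the first 10 enriched with linear-setting NPDE genes.
A count-level emulation of a read-simulator experiment is included
(`polyester_mean`: expected counts r·t vs r·(5−t) on t = 1+3(i−1)/7 with
r = 20·length/100, or the cyclic analogue, fed through the NegBin sampler);
read-level FASTA simulation and alignment are out of scope.  All randomness
flows from one seed through per-gene substreams, so results are independent
of worker count.

What the simulator does *not* emulate: alignment/counting artifacts, exon
lengths on the real bp scale (z is sub-unit by design), gene-gene
correlation, varying sequencing depth, and outlier samples.  Passing the
simulation studies therefore validates the statistical machinery under the
stated generative model, not robustness to those real-data phenomena.

## Validation studies and problem sizes

The test suite runs the full pipelines at the standard study conditions with
B = 50 permutations per gene (the studies' separations are far larger than
the resolution this costs), and the gene-set study at a scaled geometry of
10 sets × 10 genes (4 enriched).  `scripts/acceptance.py` re-runs all three
studies at those sizes.  Null calibration is checked on 200 flat genes with
pinned hyperparameters (a fixed statistic makes the permutation exactly
exchangeable; the Kolmogorov-Smirnov check then tests the machinery, not the
selection).  Measured outcomes at these sizes: linear study FDR 0.00 and
FNR 0.00; cyclic study FDR 0.00 with all DE genes detected; all enriched
sets detected with no null set significant.

## Known limitations

- The cyclic-study detection rate exceeds the ~88% reported in comparable
  analyses; the observed-normaliser permutation comparison separates the
  cyclic interaction essentially completely at these study conditions.
- The PDE stage's condition-label shuffle requires at least two samples per
  time point overall; with G = 2 and one replicate it reduces to a binary
  swap per time point, which is the minimal valid null.
- Dispersion is a single nu per gene (no per-exon or quasi-likelihood
  extension); zero-inflation is not modelled.
- The GML score is computed on the Gaussianized working system, not the
  exact NB marginal likelihood; this is the standard companion approximation
  to the IRLS fit.
- Genes need at least (null-space dimension + 1) distinct design points;
  with the full model and G = 2 that means ≥ 3 distinct time points per
  condition.
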