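# Methods

`velogrn` infers signed, time-resolved gene regulatory networks (GRNs)
from time-stamped single-cell RNA-seq snapshots. Because sequencing is
destructive, no cell is observed twice; the method therefore first
reconstructs *cell trajectories in distribution* with optimal transport,
converts them into per-cell **gene velocities**, and only then asks which
genes' velocities anticipate which others'.

## Model and pipeline

**Input.** Count matrices `x^t ∈ R^{m×n(t)}` (m genes, n(t) cells) at N
observation times t_1 < … < t_N, preprocessed with the conventional
log(x+1) transform. All costs and velocities are computed on the log
scale.

**Coupling.** For each consecutive pair (t, t~) a transition matrix
T ∈ Π(p, q) (row sums p, column sums q, total mass 1; both marginals
uniform by default) is found by minimising the entropic fused
Gromov–Wasserstein (FGW) objective

    (1−α) ⟨T, D⟩_F + α Σ L(S_cd, S~_{c~d~}) T_{cc~} T_{dd~} − ε H(T),

with D the max-normalised Euclidean (optionally cosine) distance between
cells across the two times, S, S~ max-normalised geodesic distances on a
symmetrised kNN graph within each cohort (k = max(1, ⌊min(50, 0.2 n(t),
0.2 n(t~))⌋)), and L the square loss (an absolute-loss variant is
available for small cohorts). The Wasserstein term matches cells by
expression similarity; the Gromov term preserves each cohort's internal
geometry, which matters for branching populations. Entry T_{cc~} is read
as the probability that cell c~ descends from cell c.

Defaults α = 0.5 and ε = 0.01 are stable across datasets and are the
package defaults throughout.

**Velocities.** The barycentric projection
𝒯(x^{t,c}) = Σ_{c~} (T_{cc~}/Σ_{d~} T_{cd~}) x^{t~,c~} predicts a cell's
descendant state; the column-normalised analogue predicts ancestors.
Velocities are finite differences of these predictions: forward at t_1,
backward at t_N, and at interior points the gap-weighted centered scheme
with weights (t_k−t_{k−1})/(t_{k+1}−t_{k−1}) on the forward difference
and (t_{k+1}−t_k)/(t_{k+1}−t_{k−1}) on the backward one (their mean for
uniform spacing). Velocities are per gene, per cell, in log-expression
units per time unit. Each gene's velocities are scaled to unit pooled
standard deviation over all cells at all times; means are deliberately
**not** subtracted — the sign of a velocity distinguishes activation
from repression.

**Correlation mode.** The OT-weighted time-lagged correlation

    C_{g1,g2} = 1/(N−lag) Σ_k Σ_{c,c~} v_{g1}(x^{t_k,c}) v_{g2}(x^{t_{k+lag},c~}) T^{t_k,t_{k+lag}}_{cc~}

scores the edge g1 → g2 (positive: activation; negative: inhibition).
For lag > 1 the plan is the composition T_ab diag(1/q) T_bc of
consecutive plans. With one cell per time and T ≡ 1 this reduces to the
classical lagged product of a single trajectory. The per-interval
summands are retained so a network can be reported for any time window.

**Granger mode.** Per interval, the velocity of each target gene over
the cells at t_{k+1} is regressed on all genes' velocities projected
forward from t_k (projection supplies the cell pairing that destructive
sampling denies us):

    min_a 1/(2n) ‖v_{g2} − V̂ᵀ a‖² + λ (r‖a‖₁ + (1−r)/2 ‖a‖₂²).

The fitted coefficients form A^{t_k,t_{k+1}}; the global network is
their sum. Defaults λ = 1, r = 0.5; λ = 0 falls back to ordinary least
squares, r = 0 to closed-form ridge. Only first-order lags are used —
composing plans over long horizons degrades, and extra lags
overparameterise the regression.

**Stimulus.** Experiments driven by a known stimulus get an artificial
gene with velocity 1 for every cell at the stimulus time point and 0
elsewhere. It is exempt from the standard-deviation normalisation,
enters only as a predictor/source (its column in any weight matrix is
zero), and is never evaluated unless the ground truth includes it.

**Networks.** Weight matrices become ranked signed edge lists by
thresholding |weight| (absolute threshold, top fraction with
⌈f·E⌉ edges, or top-k); ties are broken lexicographically by gene names
so rankings are platform-independent. Windowed networks sum (Granger)
or average (correlation) the per-interval matrices whose source time
falls in the half-open window. Branch-split analyses combine
branch-specific matrices either by elementwise sum (this package's
default) or by largest absolute value with its sign (the convention used
when aggregating other tools' outputs).

**Evaluation.** Off-diagonal |weights| are ranked against a signed
ground-truth adjacency. AUPRC sweeps every distinct score threshold
with tied scores grouped and traverses each tie group *fractionally*
(true and false positives accrue proportionally, as under a randomised
threshold), integrating precision over recall exactly. Under this
convention a constant matrix scores exactly the edge density, a perfect
ranking 1 — and, unlike step or trapezoidal tie handling, demoting a
true edge into a tie group can never raise the area. AUROC follows the
standard tie-corrected definition. Signed variants zero any entry whose
sign contradicts a known interaction before ranking, so signed ≤
unsigned. The AUPRC ratio divides by the
edge density (the expected AUPRC of a random ranker). Early precision
is the precision of the top-k edges with k the number of true edges.

The in/out-degree ratio deg(g) = Σ|C_{·,g}| / Σ|C_{g,·}| (self-loops
excluded, absolute values; a signed variant exists behind a flag)
nominates regulators (deg < 1) versus targets (deg > 1). Genes with no
outgoing weight get deg = +∞ and a flag.

## Numerics

The FGW solver is projected gradient descent: each outer iteration
linearises the Gromov term at the current plan (for the square loss via
the low-rank identity ∇ = 2(constC − 2 S T S~ᵀ)) and projects onto
Π(p, q) with an entropic Sinkhorn solve at the target ε. Initialisation
is the independent coupling p qᵀ — feasible and deterministic; the outer
loop stops when the relative Frobenius change of the plan falls below
1e−9 (default) or after 1000 iterations, returning the best iterate
with a `converged` flag.

The Sinkhorn projection is log-stabilised (scalings absorbed into the
dual potentials before they overflow; the kernel exponent is clipped
against stale warm starts) with successive overrelaxation ω = 1.5 on the
scaling updates and ε-scaling on cold starts — both standard
accelerations that matter because ε = 0.01 sits two orders of magnitude
below the normalised cost scale. Dual potentials are warm-started across
outer iterations. Marginal residuals of returned plans are below 1e−6
(typically ~1e−10).

Cells with exactly identical log-expression (frequent after count
quantisation, extreme under dropout) are interchangeable in every term
of the objective; each interval problem is therefore solved over
distinct cell states with multiplicity-weighted marginals and the plan
expanded by splitting each group's mass equally. This is exact — the
entropic solution is unique and symmetric under permutation of identical
cells — and was additionally verified against a brute-force
high-iteration reference on the hardest benchmark instance.

Degenerate cases: a single-cell cohort gets the trivial plan [[1]]; a
disconnected kNN graph fills unreachable pairs with the largest finite
geodesic; an all-zero cost matrix skips max-normalisation; zero-variance
genes stay at zero velocity; composing through a mass-zero inner cell is
rejected.

## Synthetic data

The generator emulates the stimulus-response benchmark regime used for
time-series GRN inference: a known signed network, a stimulus switched
on at the first time point, **10 time points** with **200 cells drawn
fresh at each** (destructive sampling — no cell appears twice), and
optional independent dropout at a fixed rate (0.5/0.7 typical).

Each cell carries an independent latent log-scale trajectory

    ds = (Aᵀ act(s − b) − γ(s − b) + u(t)) dt + σ dW,

with act the identity (`linear_sde`) or a saturating tanh
(`hill_activation`), integrated by Euler–Maruyama (20 substeps per unit
time). Observed counts are round(exp(s) − 1), so log1p preprocessing
recovers the latent scale up to quantisation. Defaults: baseline b = 1.5
(counts ≈ 3–4 at rest), decay γ = 1 per time unit (response time ≈ one
observation interval, so a cascade of depth 3 unfolds well inside 10
intervals), interaction scale 1.2, stimulus amplitude 1.5 (a clear but
not saturating excursion), noise σ = 0.15 (cell-to-cell spread visibly
larger than quantisation noise). The default truth is a 5-gene cascade
with 4 signed edges (3 activations, 1 inhibition) driven through gene 0.
One seed fans out to per-stage substreams, so adding a stage never
perturbs earlier draws; identical seeds give bit-identical datasets.

What the generator does **not** emulate: mechanistic bursty
transcription, branching lineages (branch handling is tested by
labelling a simulated population), cell-type proliferation imbalances,
library-size variation, or expression-dependent dropout (dropout is
independent zeroing). Passing recovery tests on this generator shows the
pipeline's stages compose correctly and that its statistical assumptions
hold under the stated noise — not that performance transfers to any
particular real dataset.

## Benchmark problem sizes

The recovery benchmark (also run by `scripts/acceptance.py`) uses the
generator defaults — 5 genes, 10 × 200 cells — over five replicate
seeds, with and without 50% dropout, solving 9 FGW problems per run.
The oracle checks use small instances by design: exact
linear-programming transport at n ≤ 10 (where the LP is cheap and the
entropic gap at ε = 1e−3 is far below 1%), and brute-force PR/ROC sweeps
at ≤ 20 candidate edges.

## Known limitations

- Entropic FGW is non-convex; the solver returns a deterministic
  stationary point of the projected-gradient scheme, not a certified
  global optimum (the α = 0 special case is checked against the exact LP).
- The correlation network is dense by construction; sparsity comes only
  from thresholding. The Granger network inherits elastic-net sign
  cancellation: interval coefficients of opposite sign can cancel in the
  global sum (documented, not prevented).
- Uniform marginals ignore proliferation and death; unbalanced transport
  is out of scope.
- Pseudotime is consumed, never inferred; quantile binning assigns ties
  at a bin edge to the lower bin.
- Granger regression cost grows with gene count (one elastic net per
  target per interval); the correlation mode is the practical choice for
  thousands of genes.
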