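# Methods

This note records the models, numerical choices and limitations behind
`shootcount`. It is the package's own account of its science; every
number quoted here is recomputed by the test suite or by
`scripts/acceptance.py`.

## Problem setting

The countable object is a pine *new shoot* — a current-season growth tip —
seen from above in RGB imagery of individual tree crowns. Annotation is a
single dot per shoot. The counting model is a density regressor: it maps
an image to a non-negative grid whose integral is the count. Crown
detection itself (the boxes that crop single trees out of a stand image)
is treated as an upstream input: the package reads detector output in
Pascal-VOC XML and evaluates it, but does not train a detector.

## Ground-truth density maps

Each dot becomes a discretized Gaussian of unit mass. Bandwidths follow
the geometry-adaptive rule `σ_j = β · mean distance to the k nearest
annotated neighbours` with defaults `k = 3`, `β = 0.3`: smoothing adapts
to local crowding, so dense tufts get tight kernels and isolated shoots
wide ones. Degenerate inputs are handled by two floors: points with fewer
than `k` neighbours use `fallback_sigma = 4 px`, and bandwidths below
`min_sigma = 1 px` (coincident duplicates) are raised to it.

Kernels are truncated at 4σ (≲1e−4 of mass) and **renormalized after
boundary clipping**, so each kernel's in-image mass is exactly 1 and the
map's sum equals the count up to accumulation error (≤1e−4 over dozens of
points). Renormalization rather than reflective padding was chosen
because it makes the sum-equals-count invariant exact and therefore
testable. Sum-pooling (`downsample_density`) preserves mass exactly and is
used to compare ground truth against the strided network output.

## The unbalanced entropic transport loss

The composite training loss is

```
L = smoothL1(Σ D, m) + λ₁·L_UOT + λ₂·MSE(D, D′)
```

with `D` the predicted map, `D′` the ground-truth map, `m` the dot count,
and λ₁ = 0.1, λ₂ = 0.01 by default (configurable; these magnitudes follow
the convention of density-map counting losses of this family). The
transport term compares the flattened prediction `a` (masses at pixel
centres `x_i`) with the dot map `b` (unit masses at `y_j`):

```
L_UOT = min_{P ≥ 0}  ⟨C, P⟩ − ε Σ P log P
        + τ ‖P1_m − a‖₂²  + τ ‖Pᵀ1_n − b‖₁ ,     ε = 0.05, τ = 0.5.
```

Notes on the exact form implemented:

- The entropy term is implemented exactly as written, `−ε Σ P log P` with
  `0·log 0 = 0`. With this sign the per-entry objective is **bistable**:
  every entry has a basin at exactly zero and possibly a second basin at
  an interior stationary value, separated by a small barrier. This shapes
  the solver design below.
- The pixel marginal uses a squared L2 penalty, the point marginal an L1
  penalty. The L1 term is non-smooth: optimal column sums frequently sit
  exactly on the kink (column sum = b_j).
- Cost kinds: `euclid` (`L_ij`), `squared`, `exp`, and `perspective`
  (`exp(L_ij/η_ij)` with `η_ij` the mean of the two normalized heights).
  Distances are normalized by the image height before exponentiation and
  exponents clamped at 50, since `exp` of raw pixel distances overflows.
  Normalized height is `(row + 1)/H ∈ (0, 1]` — strictly positive so η
  can never divide by zero; continuous dot coordinates are clipped into
  the same interval. The cost at zero distance is `exp(0) = 1`, as the
  functional form dictates.

### Solver

Classic Sinkhorn scaling does not apply: the marginal penalties are not
KL-shaped. The solver is an alternating scheme, run from up to three
starting plans (rescaled outer product, uniform, and a balanced
log-domain Sinkhorn warm start at the common marginal total):

1. a multiplicative **mirror step** on the full subgradient
   (positivity-preserving; the exponent is clipped at ±3 so a single step
   cannot vault across the entropy barrier between basins);
2. a **proximal-gradient step** in which the column-L1 term enters
   through its exact prox — per column a uniform shift `max(y − μ, 0)`
   with `μ ∈ [−λ, λ]` found by vectorized bisection — which is the move
   that resolves the kink the subgradient merely oscillates around;
3. **marginal rescales** that scale rows onto the quadratic penalty's
   minimum and columns onto the L1 kink.

Every move is backtracked on the true objective, so the objective is
monotonically non-increasing; termination requires the relative decrease
to stay below `tol` for three consecutive iterations. On small problems
(n·m ≤ 64) a quasi-Newton polish (bound-constrained L-BFGS-B on the true
objective, accepted only on improvement) and a **basin-flip refinement**
— greedily switching single entries between the zero and interior basins
and re-descending — follow. On 100 random instances with n·m ≤ 9
(ε = 0.05, τ = 0.5) this matches an independent global-search oracle
(differential evolution, escalated with Powell restarts on disagreement)
to ≤1e−4 relative; in the balanced limit (τ = 10³, ε = 10⁻³, equal
totals) the transport term lands within 2% of the exact balanced-OT
linear program. Large (training-scale) problems skip polish and
refinement and run a single warm-started descent: a good local minimum is
all a loss gradient needs.

The loss gradient with respect to the predicted masses uses the envelope
rule at the converged plan — only the quadratic pixel-marginal penalty
depends on `a` directly, giving `∂L/∂a = −2τ(P1_m − a)` — and matches
central finite differences to ≤1e−3 relative on small instances. When an
image has no annotated shoots the transport degenerates; stray predicted
mass is then charged linearly at rate τ, which keeps the gradient defined.

## Synthetic scenes

The generator emulates the statistical structure the method assumes:
non-overlapping elliptical crowns (rejection-sampled, bounding-circle
test, 1000-attempt budget) on a low-frequency green-noise background,
shoots rendered as small bright Gaussian blobs. Within each crown, shoots
are a parent–child clustered process whose **expected density rises
linearly with normalized image height**, `ρ(h) ∝ 1 + g·h` — the
perspective effect of nadir UAV imagery, where canopy farther from the
camera appears denser. The gain `g` defaults to 2.

Cluster centres are drawn by stratified inverse-CDF sampling of the
in-ellipse density `width(y)·(1 + g·y/H)`, and shoots are allocated
evenly across centres with Gaussian scatter (`cluster_spread`) rejected
back into the ellipse. Carrying the height law at the centre level with
stratification expresses the stated density law with near-deterministic
height profiles; an earlier variant that thinned individual children
around uniformly chosen centres put the entire law at cluster-size
granularity and was too noisy to exhibit its own law reliably. The
per-crown shoot count is drawn exactly from the configured range, so the
configured mean is the true mean.

What the generator does **not** emulate: occlusion between canopy layers,
illumination and blur variation, shoot-scale appearance diversity, and
real crown texture. Passing tests on these scenes show that the loss and
trainer recover counts when density structure matches the model's
assumptions — not that the counter generalizes to field imagery.

## Counter and training

The counter is deliberately small: a 3-block convolutional encoder
(channels 8-16-16; the first block stride 1, later blocks stride 2, so
the output stride is 4) and a multiscale regression head of parallel 3×3
convolutions at dilations 1, 2, 3 summed and projected to one channel,
with a final rectifier enforcing non-negativity. Convolutions, backprop
(im2col) and Adam are implemented in NumPy; initialization is He-normal
and fully seeded. The transport term is computed on the strided grid
(16×16 = 256 pixels for 64×64 inputs) with dots mapped into grid
coordinates, keeping the plan small.

`TrainConfig` defaults mirror a full-scale training recipe (batch 16,
learning rate 1e−5). The **desk-scale experiment** — the package's
canonical benchmark, used by the tests and the acceptance script — is 60
synthetic 64×64 single-crown scenes with 5–30 shoots (48 train / 12
validation), 30 epochs, batch 8, Adam at 1e−3. The rate differs from the
default because a freshly initialized three-block network cannot move
measurably in 30 epochs at 1e−5 on sixty images; 1e−3 is sized to this
network and data scale. The baseline to beat is the constant predictor
that always answers the training-set mean count. The trained model beats
that baseline on at least 4 of 5 seeds; occasionally a seed collapses to
a near-constant output (a dead-rectifier failure mode of very small
networks), which affects all cost kinds equally. The cost-function
ablation compares mean validation MAE under the `perspective` and `exp`
costs over the same 5 seeds and asserts only the ordering
(perspective ≤ exp), not absolute values.

## Evaluation protocol

- **Matching**: greedy in descending confidence with one-to-one GT
  assignment; duplicate detections of an already-claimed crown count as
  false positives.
- **AP**: area under the all-point interpolated P-R curve (precision
  envelope). Eleven-point interpolation is a common alternative; the
  all-point form is the documented choice here.
- **Counting**: standard MAE and MSE over per-image counts (`mae ≤ √mse`
  is asserted as a type invariant). Published formula listings for these
  two metrics sometimes swap the square between them; the standard
  definitions are implemented.
- **Split**: 7 : 1.5 : 1.5 with a deterministic shuffle; train takes the
  floor of its share of N, validation the floor of its share of the
  remainder, test the rest. This rounding reproduces the published sizes
  at both N = 1860 (1302/279/279) and N = 313 (219/47/47).
- The shipped 26-image crown-detection tally (four detectors, per-image
  correct/false/missed counts against 303 boxes) is a published benchmark
  table carried as plain CSV; a few of its printed rows are internally
  inconsistent (correct + missed ≠ total), so the tally loader does not
  enforce the per-image identity that `tally_detections` applies to
  matcher output.

## Known limitations

- The solver's global-optimality evidence is empirical (oracle agreement
  on small instances); the objective is non-convex by construction and no
  guarantee extends to large instances.
- The interface supports batch-free training only; images in a batch must
  share a size (true for the synthetic datasets).
- Density maps are single-class; no shoot/branch disambiguation.
- The desk-scale experiment's runtime is dominated by the per-image
  transport solve; problem sizes were chosen so the full benchmark (10
  training runs) completes in minutes on one CPU.
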