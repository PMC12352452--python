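# Methods

## Notation and conventions

A dense tensor `X ∈ R^{D_1 × … × D_N}` is a numpy array of finite reals,
order `N ≥ 2`.  The mode-`n` unfolding `X_(n) ∈ R^{D_n × D̃_n}`
(`D̃_n = Π_{m≠n} D_m`) places element `i` of mode `n` in row `i`; columns
enumerate the remaining modes with the lowest-numbered remaining mode varying
fastest (the Kolda–Bader convention).  Any self-consistent column order
yields identical decompositions; fixing one makes the enumeration-oracle
tests and external comparisons well defined.  The Python API is 0-based;
serialized index sets always carry an explicit `index_base` field, and the
CLI feature reports are written 1-based for human consumption.

All singular vectors are sign-fixed (largest-magnitude entry positive) so
repeated runs are bit-reproducible; every metric used is invariant to these
signs.  Where an unfolding is much wider than tall (width ≥ 8× height), left
singular vectors come from the eigendecomposition of the small `D_n × D_n`
Gram instead of a direct SVD; the two agree to well below 1e-8 on
non-degenerate inputs.  Pseudo-inverses use the standard numerical-rank
cutoff `max(dim) · ε · σ_max` everywhere.

## The coreset model

For one mode, each row `x_i` of the unfolding is embedded as the rank-one
matrix `x_i^T x_i`; the mode's *full embedding* is the Gram
`X_(n)^T X_(n) = Σ_i x_i^T x_i`, whose eigenstructure is exactly what the
HOSVD core preserves.  A coreset `(I, w)` approximates the full embedding by
`Σ_{i∈I} w_i x_i^T x_i`; the squared Frobenius gap between the two is the
**discrepancy**.  Expanding the square shows the discrepancy is a quadratic
in `w` involving only embedding kernels `k(i,j) = (x_i · x_j)²`, so
everything is computed from `D_n × D_n` inner-product matrices:
`P = X[I] X^T`, its subset block `P_II`, `K = P_II∘²`, `c = (P∘²) 1`, and
`‖X^T X‖_F² = ‖X X^T‖_F²` (computed from the small Gram — no `D̃_n × D̃_n`
object is ever formed).  Computed discrepancies are clamped at zero against
round-off.

**Weights.**  `min_{w ≥ 0} wᵀKw − 2wᵀc` is solved on the kernel normal
equations.  The unconstrained solution `K⁻¹c` is tried first and returned
(clipped) when it is already nonnegative — the common case; otherwise an
active-set NNLS runs on a square-root factorization `AᵀA = K`, `Aᵀb = c`
obtained from the eigendecomposition of `K`.  A ridge `1e-12 · tr(K)/R̂` is
added only when `K` is numerically singular, and flagged.  Solutions satisfy
the KKT conditions of the nonnegative quadratic program to 1e-8.

**Random selection** draws distinct row indices sequentially with
probability proportional to squared row norms, renormalizing after each draw
(distinct indices keep the subset Gram invertible; zero-norm rows are never
drawn).

**Deterministic selection** is weighted kernel herding.  Maintaining a
coreset `S` with NNLS weights `w`, each step adds the index maximizing the
residual alignment `(c_i − Σ_{j∈S} w_j K(i,j)) / √K(i,i)` — the correlation
of candidate `i`'s embedding with the current residual — then re-solves the
weights over `S ∪ {i}`.  This rule uses only the mode Gram (cost
`O(D̃ D² + R̂³ D)`), reduces to classical kernel herding when weights are
frozen, and is exposed as a documented policy.  Ties break to the smallest
index everywhere, making the deterministic path bit-reproducible; the
discrepancy trace is non-increasing in the step index because each re-solved
weight vector can only improve on the previous one extended by zero.

## The sequential decomposition

Modes are processed in a configurable truncation order (default ascending).
For each mode: select indices, solve weights, form the mapping
`M = Pᵀ P_II⁻¹ W⁻¹`, and replace the unfolding by the weighted coreset
`W X[I]` before folding back and moving on.  The final working tensor is the
core — the subtensor `X[I_1, …, I_N]` scaled by each mode's `W` — and the
mappings are the factor matrices.

**Weight power.**  The discrepancy weights multiply *embeddings*, so the
rows themselves carry `√w`: the default is `W = diag(w^{1/2})`, the only
scaling under which the truncated mode's Gram matches the full-mode Gram the
weights were optimized for (the per-mode quadratic-form deviation then
equals the mode's discrepancy exactly).  `weight_power=1.0` (rows scaled by
`w` itself) is available as a configuration option.  Because the mapping
uses the same `W`, the per-mode product `M (W X[I])` equals the unweighted
row projection either way — weights influence only the modes processed
later.

**Zero weights.**  The NNLS optimum can lie on the boundary.  A zero weight
is floored at `1e-12 · max(w)` where `W⁻¹` is required, and the event is
recorded in the model provenance.  Reconstruction is unaffected (the floored
mapping column multiplies a correspondingly tiny core slice), but the
zero-weighted slice is effectively absent from the truncated working tensor
seen by later modes — see Limitations.

**Symmetry.**  Modes declared symmetric (equal size and rank) share one
selection: the group's lowest mode is processed normally, and its indices,
weights and mapping truncate every other member immediately afterwards
(consecutive processing keeps index sets valid under the shrinking working
tensor).  A tensor symmetric in those modes yields a model symmetric in
them.

**Randomness.**  One seed expands into independent per-mode substreams
(`SeedSequence.spawn`), so a mode's draw does not depend on how many modes
precede it.

## Baselines and metrics

HOSVD and ST-HOSVD follow their standard definitions; ST-HOSVD projects the
working tensor after each mode's SVD.  Chidori CUR samples index sets from
the full tensor and computes each mode's mapping from that mode's beam only
(the subtensor free in the mode, restricted elsewhere); RST-CUR uses
uniformly sampled fibers as factors with a pseudo-inverted core.  Any
Tucker-form model converts to HOSVD form by QR-factorizing the factors,
absorbing the triangular parts into the core, and running a full HOSVD on
the small core; rank-deficient factors fall back to pivoted QR with a
warning.

The ISI index is evaluated on entrywise absolute values — required for the
stated invariance to sign and permutation of factors — and is zero iff the
matrix is a scaled signed permutation.  HOSVD distance sums per-mode ISI of
`A_nᵀ B_n`; cross-distance averages all `M²` ordered pairs of runs
*including the zero diagonal* (note: not the `M(M−1)` normalization some
cross-ISI variants use).  Models are always converted to HOSVD form before
distance computation.

## Synthetic data

The signal-plus-noise generator draws Gaussian factors and a Gaussian core
(fully dense, or superdiagonal for the CPD variant), then adds Gaussian
noise rescaled so that `‖signal‖_F / ‖noise‖_F` equals the requested SNR
`η` — larger `η` means cleaner data, the convention under which error curves
decrease in `η`.  The opposite (noise multiplied by `η`) is available as
`snr_convention="literal"`.  Reference configuration for method comparisons:
`N = 3`, `R = R̂ = 4`, `η = 10`, common mode size `D`; the test suite and
trend checks use `D = 60` with 10–24 seeds, sizes at which every observed
qualitative trend is already stable.

The connectivity-like generator emulates a subject-stacked FNC tensor:
per-subject slices are `clip(B + E, −1, 1)` with unit diagonal imposed last,
where `B` is a symmetric block mean (two dense diagonal blocks of ~17% of
the nodes each at strength 0.6, mimicking motor/visual network groups) and
`E` is symmetric Gaussian noise (sd 0.15).  Slices are symmetric,
`[−1, 1]`-bounded and unit-diagonal, but **not** constrained positive
semidefinite — no implemented method uses PSD-ness — so they are
correlation-like rather than guaranteed correlation matrices.  The generator
does not emulate subject-group effects, temporal structure, or the
heavy-tailed dependence of real fMRI correlations: passing tests demonstrate
algorithmic correctness and qualitative behavior, not clinical validity.

## Limitations and observed behavior

* Relative error of the coreset decompositions exceeds ST-HOSVD's at equal
  ranks (they use a row subset instead of principal components); the gap
  narrows as `R̂` grows, and closes exactly at full subset sizes.
* The NNLS weights provably minimize the per-mode discrepancy — per subset
  they are never worse than unit weights or classical norm-rescaled
  weights, and the package asserts this.  This does **not** always transfer
  to lower end-to-end reconstruction error for the random selector: a
  uniform weight scale cancels out of every downstream mapping estimate, so
  only the weight *variation* matters, and when the NNLS optimum lies on the
  boundary (zero weights, frequent at `R̂ = R` where the sampled rows carry
  no redundancy) the zeroed slices degrade downstream estimates.  In paired
  runs where all weights stay interior, the weighted pipeline's mean error
  is at or below the unit-weight pipeline's; across all runs at `R̂ = R` it
  can be above it.  The deterministic selector is not affected (herding
  picks diverse rows; interior weights in all observed runs).
* Dense in-memory tensors only; no sparse, lazy, or complex support.
* The experiment harness follows a repeated-runs protocol: one tensor per
  sweep value, replicate seeds driving only method randomness, so the
  deterministic method's cross-distance aggregate is exactly zero.  Recorded
  runtimes are host-dependent and excluded from any assertion.
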