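# Methods

This note documents the model conventions, numerical choices and known
limitations behind `nestmax`.  It is written for users who need to know
exactly what the numbers mean, not just how to obtain them.

## Geometry and temperature

**Coordinates.** The ranked `N×M` matrix is mapped onto the unit square in
Cartesian orientation: the cell at (row rank `i`, column rank `α`) has its
center at `x = (α − 0.5)/M`, `y = (N − i + 0.5)/N`, so the most generalist
row (rank 1) sits at the top (`y` near 1) and the most generalist column at
the left (`x` near 0).  The expected-filled region is the area *above* the
isocline; this is the orientation under which the shape function's endpoint
values (`f = 0.5/N` at the first column center, `(N−0.5)/N` at the last) are
consistent with a full first column and a single-link last column.

**Shape function.** On the band of cell centers
`x ∈ [0.5/M, (M−0.5)/M]`,

    f(x; p) = 0.5/N + ((N−1)/N) · [1 − (1 − (Mx−0.5)/(M−1))^p]^(1/p),

extended flat to the square's edges (this avoids fractional powers of
negative bases outside the band).  At column centers the band coordinate is
evaluated as `u = (α−1)/(M−1)` so the endpoint values are exact in floating
point.  `f` is monotone non-decreasing in `x` for every `p > 0`.

**Calibration.** `p` solves `∫₀¹ [1 − f(x; p)] dx = Φ`; the band integral is
computed by adaptive quadrature (tolerance 1e−12) and the root found with
Brent's method on `p ∈ [1e−4, 1e4]`, expanded geometrically to
`[1e−8, 1e8]` when needed, to an area residual below 1e−8.  The area above
the curve is strictly *decreasing* in `p` (the curve flattens onto
`y = 0.5/N` as `p → 0` and rises to `y = (N−0.5)/N` as `p → ∞`), so sparse
matrices calibrate to large `p`.  The attainable area range is a proper
subinterval of (0, 1) that narrows for small matrices — e.g. (0.25, 0.625)
at 2×2.  A strict solve raises an error (reporting the attainable range)
for fills outside it; the temperature path instead *clamps* `p` at the
bracket edge and records the residual, because small matrices routinely
carry fills no finite `p` can match (the perfectly nested 2×2 has fill 3/4)
and must still be classifiable.  Classification at a clamped edge is stable:
near the edges the expected mask no longer depends on `p`.

**Classification and distances.** A cell is expected-filled iff its center
lies on or above the curve; centers within 1e−9 of the curve count as on it
(they contribute `d = 0` either way).  For each unexpected cell a probe line
of slope −1 through its center is drawn; `D = √2·(x+y)` is the distance
between the probe line's axis intercepts, taken literally even when the
intercepts fall outside the unit square (a documented policy choice; the
alternative of clipping at the matrix boundary is not implemented).  `d` is
the distance from the center to the probe line's intersection with the
flat-extended isocline.  Along the probe line the gap
`(x+y−t) − f(t)` is strictly decreasing, so that intersection is unique and
Brent root-finding (tolerance 1e−12) replaces a bisection scan.  `U` sums
`(d/D)²` over the unexpected set divided by `NM`, and `T = 100·U/0.04145`,
unclamped above 100.  The constant `U_max = 0.04145` is fixed; it is
configurable in source for research use only.

Since `d`, `D` and the expected mask depend only on cell *positions* (never
on matrix content), the per-geometry grids are computed once per
`(N, M, L)` and memoized; evaluating a new ordering costs one masked sum.
This is what makes exhaustive search and the GA affordable.

## Fitness–complexity ranking

From the uniform initial condition `F_i = Q_α = 1` the map

    F̃_i(n) = Σ_α B_iα Q_α(n−1),    Q̃_α(n) = 1 / Σ_i (B_iα / F_i(n−1))

is iterated, each step followed by normalization of both vectors by their
mean.  The fixed point can drive scores of weakly connected nodes to zero
(slowly, density-dependent), so iteration stops on the *ranking*: the
smallest `n*` at which Spearman ρ between the scores at `n*` and at
`n* + Δn` exceeds `1 − 10⁻³` on both sides (`Δn = 10` by default; 20, 30
and a fixed 100-iteration run are available and compared by the pipeline).
The reported scores are those at `n* + Δn`, the more converged window end.
Two all-tied score vectors are treated as perfectly rank-correlated in this
stop rule (the standalone `spearman` returns NaN for zero-variance input).
Scores are floored at 1e−280 before entering the reciprocal sum; the stop
rule normally triggers long before the floor matters, and hitting it logs a
warning.  Rows are ranked by decreasing fitness, columns by *increasing*
complexity (the least complex column is the most generalist and belongs on
the packed side); ties break by decreasing degree, then input order.
Empty rows or columns are rejected — strip them with `drop_empty` first and
re-append them at the worst ranks if a full ranking is needed.

## Genetic algorithm

Chromosomes are (row, column) rank-permutation pairs; the objective is the
temperature of the reordered matrix.  Defaults: population 30, up to 500
generations, stop after 100 generations without improvement, mutation
probability 0.1 per side, copy probability 1/2.

- **Seeding:** degree ranking + FCA ranking + random permutations.  The
  comparison pipeline overrides this to degree + random only: an FCA-seeded
  elitist GA can never end hotter than the FCA, which would make the
  FCA-vs-GA comparison vacuous.
- **Selection:** the well-performing parent by linear rank weighting (best
  member weight = population size), the partner uniformly at random.
- **Crossover (per side, independently):** with probability 1/2 the
  offspring copies the well-performing parent; otherwise a cut point `k` is
  drawn uniformly, positions ≤ k copy the first parent, positions > k adopt
  the partner's value unless it already appeared in the prefix, and open
  positions are repaired with the unused rank values in increasing position
  order, values taken in increasing order (a deterministic repair rule).
- **Mutation:** with probability 0.1 a random contiguous slice is rotated
  by one position (the rotation amount of the cyclic permutation is a
  convention; one position is used).
- **Replacement:** steady-state and elitist — the offspring replaces the
  current worst member only if strictly better, and duplicates of existing
  members are kept out so the population remains a set of distinct
  candidates.  One *generation* comprises `population_size` births.  The
  best-so-far temperature history is non-increasing by construction.

With these conventions the GA attains the exhaustive brute-force minimum
(over all `N!·M!` orderings) on every tested 4×4/4×3 instance across 50
seeds per matrix.  A weaker effort calibration (one birth per generation)
cannot do this; a stronger one would be slower without changing results on
small matrices.

## RCA binarization

`R_iα = w_iα·W/(w_i·w_α)` after dropping zero-margin rows/columns; links
are the pairs with `R_iα ≥ 1` (inclusive), and rows/columns left linkless
are stripped.  For raw exporter→importer→product records, volumes are
aggregated over importers by summation before RCA.  No product-classification
harmonization, deflation or re-export correction is attempted; which
classification level and sectors to include is a data-preparation decision
left to the user.

## Synthetic generators

**Perfectly nested matrices.** The generator fills exactly the cells whose
centers lie in the expected-filled region of an isocline, with the isocline
calibrated *at the matrix's own realized fill*: starting from the target
fill it rebuilds the mask at each realized fill until the mask reproduces
itself (direct iteration, with a bisection on the link count for the
slow-drift regime).  This self-consistency is what makes the degree-ordered
matrix score `T = 0` exactly — the cornerstone fixture of the test suite.
The price is fill drift: discrete cell counts systematically exceed the
continuous calibration area, so the self-consistent fill settles above the
target (30×20 at target 0.25 realizes 0.305; the effect grows for large
sparse targets).  The realized fill is always available on the result.

**Noisy variants** move `⌈η·L⌉` randomly chosen links to randomly chosen
empty cells.  Swaps conserve `L` — and hence the isocline — by design, so
noise levels differ only in ordering difficulty, not in fill.  Swaps can
empty a row or column; the pipeline strips such lines before ranking.

**Random matrices** place exactly `round(Φ·N·M)` links uniformly, redrawing
(bounded retries) until no line is empty.

**Trade tables** put volume `c_i · p_α · exp(ε)` on the cells of a nested
capability mask (log-normal sizes `c`, `p` with σ = 1; log-normal noise ε
with σ = `dispersion`, default 0.5) and exactly zero elsewhere.  Off-mask
cells can therefore never gain an RCA link (no false positives); on-mask
cells near the generalist×generalist corner can fall below the RCA
threshold — for multiplicative margins the corner cell always has
`R ≤ 1` — so recovery of the mask is structurally imperfect (recall ≈ 0.7
at the default dispersion, binarized fill within ±0.05 of the target).  For
tables above 5000 cells the capability mask is the one-shot nested mask
rather than the exact fixed point: RCA thresholding destroys exact isocline
compatibility anyway, and the fixed-point search scales poorly.

**What passing on synthetic data does not show.** Swap noise on a perfect
matrix produces *locally repairable* disorder: a temperature optimizer can
chase individual unexpected cells.  Empirical mutualistic networks carry
structural disorder that no reordering repairs.  Consequently the GA
outperforms the FCA on this ensemble more often than on real interaction
webs — on small dense synthetic batches the FCA ends no hotter than the GA
in roughly 40% of instances, and that fraction is tie-dominated (the two
temperatures typically differ by ~2%), so it also moves by several
percentage points across FCA stop rules.  Results on downloaded interaction
matrices should be expected to favor the FCA more strongly.

## Defaults that matter

| parameter | default | meaning |
| --- | --- | --- |
| binarize threshold | 0 | any positive interaction count is a link |
| `U_max` | 0.04145 | temperature normalization constant |
| area tolerance | 1e−8 | isocline calibration residual |
| tie tolerance | 1e−9 | center-on-curve classification band |
| `Δn` | 10 | FCA look-ahead window |
| FCA ρ threshold | 1 − 10⁻³ | ranking-convergence criterion |
| GA population / generations / stagnation | 30 / 500 / 100 | search effort |
| mutation / copy probability | 0.1 / 0.5 | GA operator rates |
| GA repetitions (pipeline) | 3 | `T_GA` is the best of these |
| noise η | 0.1 | batch condition for the comparison protocol |
| trade dispersion | 0.5 | log-normal volume noise σ |

Problem sizes used by the test suite and the acceptance script — 30×20
batches of 50 matrices, 4×4/4×3 exhaustive checks, calibration grids up to
200×200 — were chosen so each property is measured at the smallest scale
where it is meaningful.

## Known limitations

- Only the temperature statistic is implemented; no NODF, spectral-radius
  or discrepancy measures, and no null-model significance testing.
- `D` uses literal axis intercepts; whether boundary clipping better
  matches historical implementations is untested here.
- The perfect-nested generator's fill drift means very sparse large
  ensembles cannot be generated at their nominal fill (the self-consistent
  fill is substantially higher).
- Mesoscopic (in-block) nestedness and weighted nestedness are out of
  scope, as are extinction-cascade validations of the rankings.
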