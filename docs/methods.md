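# Methods

This note records the models implemented in `neurosync`, the conventions and
numerical choices behind them, and what the synthetic test data does and does
not establish about behaviour on real recordings.

## Synchronization networks

A synchronization network is a simple weighted graph on recording channels.
Edge values live in (0, 1] and measure strength of statistical dependence;
the value 0 is reserved for "no edge", and self-loops are excluded (the
diagonal of any input matrix is ignored and forced to zero). Networks are
built from a synchronization matrix by thresholding:

* **binary** mode keeps an edge iff `w_ij >= t` and sets its value to 1;
* **greyscale** mode keeps the original values at or above `t`.

The comparison is non-strict so that `t = 1.0` still retains
perfect-synchrony edges. An asymmetric matrix passed with `directed=False`
is symmetrized by the mean of `w_ij` and `w_ji`, with a logged warning.

Distance-based metrics need *lengths*, not strengths. Two transforms map
(0, 1] onto [1, +inf): `g(x) = 1/x` and `g(x) = 1 - log2(x)`. Both fix
`g(1) = 1` and decrease strictly; `1/x` diverges faster as `x -> 0+`, so it
penalizes weak edges harder. Absent edges get an explicit `+inf` sentinel
(never a large finite number), and shortest paths are computed exactly with
Dijkstra's algorithm on the transformed lengths.

## Connectivity estimators

**Magnitude squared coherence (MSC).**
`gamma_xy(f) = |<S_xy(f)>|^2 / (<S_xx(f)><S_yy(f)>)` with `<.>` Welch
window averaging. Defaults: Hann window, 256-sample segments, 50% overlap —
standard practice for EEG-length records; all exposed as `WelchParams`.
The numerator is evaluated as `re^2 + im^2` rather than `abs(.)**2`, and the
self-pair passes the identical array object to the spectral routines, so the
self-coherence is exactly 1.0 at every bin rather than 1 minus a rounding
ulp. Constant (zero-variance) channels are an error: their coherence is
undefined.

**Nonlinear interdependence (RIM).**
Signals are delay-embedded (`x(t) = [x(t), x(t+tau), ..., x(t+(m-1)tau)]`,
dimension `m`, delay `tau`). With `R_t(Y)` the mean squared distance of the
embedded point `y(t)` to all other points, and `R_t^(k)(Y|X)` the mean
squared distance to the points at the time indices of `x(t)`'s `k` nearest
Euclidean neighbours, the directed measure is
`N(Y|X) = mean_t (R_t(Y) - R_t^(k)(Y|X)) / R_t(Y)`, and the symmetric index
is `(N(X|Y) + N(Y|X)) / 2`. Temporally adjacent points
(`|index - t| <= m * tau`, the Theiler window) are excluded from the
neighbour search so autocorrelation does not masquerade as coupling. Raw
values can be slightly negative for independent signals; synchronization
matrices store the value clipped to [0, 1] while the raw values remain in
the result record. Defaults `m = 5`, `k = 10`, `tau` from the
autocorrelation criterion below; the literature offers heuristics rather
than canonical values, so all three are explicit parameters.

**Embedding delay.** `estimate_tau` returns the first lag at which the
autocorrelation estimate falls to zero. A finite-sample ACF never crosses
zero exactly where the population ACF does (truncation bias is O(1/N)), so
the crossing is declared at the first lag where the estimate drops below a
Bartlett-style noise floor `2 / sqrt(N)` — the standard error of the ACF
estimate of an uncorrelated series. For a period-T sinusoid this yields the
quarter-period `T/4`; for white noise it yields 1. If no crossing occurs
within `N/2` lags, the first lag below `1/e` is used (logged); failing
that, an error asks for a manual choice.

**Partial directed coherence (PDC).**
A VAR(p) model `x(t) = sum_r A(r) x(t-r) + eps(t)` is fitted by ordinary
least squares on the lagged design after centring; collinear channels make
the design rank-deficient and are a hard error. Order selection by AIC
(`log det Sigma + 2 p n^2 / T`) is available, capped at
`p_max = min(10, N/(5n))`. With
`Abar(w) = I - sum_r A(r) e^{-iwr}`, the influence of source channel j on
target i is `pi_{i<-j}(w) = |Abar_ij(w)| / sqrt(sum_l |Abar_lj(w)|^2)`
(the **standard** variant), which guarantees values in [0, 1] and
`sum_i pi_{i<-j}^2 = 1` per source column. An **as_printed** variant
without the square root is retained for comparison with sources that write
the denominator as a plain sum of squares; the standard variant is the
default because the [0, 1] range statement requires the root. PDC vanishes
at all frequencies iff all cross-coefficients `A_ij(r)` are zero.

**Band reduction.** Spectral indices are reduced to per-band scalars by the
arithmetic mean over grid frequencies in `[f_lo, f_hi]` (median available).
The conventional EEG bands delta (0.5–4 Hz), theta (4–8), alpha (8–13),
beta (13–30) and gamma (30–45) are predefined. `connectivity_matrix`
evaluates `n(n-1)/2` unordered pairs for MSC/RIM and fills ordered pairs
from a single VAR fit for PDC (entry `(i, j)` = influence of j on i), so
PDC matrices may be asymmetric.

## Graph metrics

All formulas operate on the weight matrix `W` with max-normalized weights
`w^ = w / max(w)` where noted.

* **Zhang–Horvath clustering**:
  `c_Z(v) = sum_{i!=j} w^_vi w^_ij w^_jv / sum_{i!=j} w^_vi w^_jv`
  (ordered pairs excluding v). Uses weights only; invariant to uniform
  rescaling of all weights. Vertices with a zero denominator score 0.
* **Onnela clustering**:
  `c_O(v) = (1/(deg(v)(deg(v)-1))) sum_{i!=j} (w^_vi w^_ij w^_jv)^{1/3}`
  with `deg` taken on the binary skeleton (the network's support by
  default; a separate re-threshold can be supplied). The denominator is the
  ordered-pair count `deg(v)(deg(v)-1)`, so a unit triangle scores exactly
  1. Degree < 2 scores 0.
* Network means average over *all* vertices, including the zero-scoring
  ones.
* **Assortativity** (symmetric form): the Pearson correlation of a vertex
  property over the 2m ordered edge-endpoint pairs, evaluated in the closed
  form `r = (4m S_uv - S_+^2) / (2m S_sq - S_+^2)`. The directed-weighted
  form is the omega-weighted Pearson correlation between source and target
  properties. The default property is degree (binary) or strength
  (greyscale). A vanishing denominator (e.g. regular graphs) is *undefined*
  and reported as NaN, never coerced to 0.
* **Efficiency**: `c_Ef(v) = (1/(n-1)) sum_u 1/d(v,u)` with unreachable
  pairs contributing 0, so it is well defined on disconnected graphs;
  global efficiency is its mean. **Closeness** `(n-1)/sum_u d(v,u)` is NaN
  whenever any vertex is unreachable.
* **Betweenness**: ordered-pair sum of `sigma_st(v)/sigma_st` normalized by
  `(n-1)(n-2)`. Path counts use a dynamic program over the distance matrix;
  two path lengths tie when they agree within relative tolerance 1e-12
  (exact binary ties are exact in floating point; greyscale ties are
  resolved by counting all co-minimal paths within that tolerance).
* **Eigenvector centrality**: principal eigenvector of `W^T`, scores
  `|s_i| / ||s||_p` with `p = 2` by default (any `1 <= p <= inf` keeps
  scores <= 1). A non-simple dominant eigenvalue triggers a warning.
* **Hubbell centrality**: exact solution of `(I - alpha W^T) c = e`;
  `e` defaults to all-ones and `alpha` to `0.5 / lambda_1`. The restriction
  `|alpha| < 1/lambda_1` (convergence of the underlying Neumann series) is
  validated, not assumed.
* **Subgraph centrality**: `diag(expm(A))`, i.e. closed walks of length k
  weighted by 1/k!; symmetric matrices use the eigendecomposition route.
  The greyscale generalization substitutes `W` for the 0/1 adjacency.
* **Network entropy**: transition matrix `p_ij = w_ij / sum_k w_ik`
  (row-normalization is the only construction consistent with substituting
  W for the adjacency matrix), stationary distribution `pi P = pi`, per-row
  entropies `H_i`, entropy rate `H = sum_i pi_i H_i` in bits by default
  (natural log available). Both `H_i` and the removal-impact products
  `pi_i H_i` are reported per vertex; neither is singled out as "the"
  centrality. A dangling vertex (zero out-strength) or a reducible support
  is a hard error with a remediation hint, because the walk or its
  stationary distribution is then undefined.

## Layouts

* **static**: montage coordinates (3-D montages project to x, y), centred
  and uniformly scaled to fit an oval with semi-axes 1.0 x 0.8 representing
  the scalp. One translation + one scale preserves relative geometry and
  makes the map idempotent.
* **mds**: classical (Torgerson) scaling of the shortest-path distance
  matrix — double-centre `-D^2/2`, take the top-2 eigenpairs. The reported
  residual is the normalized strain `||B - XX^T||_F / ||B||_F`, which is
  non-increasing in the embedding dimension by Eckart–Young; exact planar
  distance matrices embed with strain ~1e-16. Unreachable pairs receive a
  finite connection distance of twice the largest finite distance (logged).
  Output is deterministic via a fixed sign convention on the axes.
* **bstress**: minimizes
  `sum_{edges} (|p_i - p_j| - 1)^2 + alpha sum_{non-edges} (|p_i - p_j| - M)^2`
  by weighted-stress majorization (SMACOF update with the pseudo-inverse of
  the weight Laplacian). Defaults `alpha = 1/n^2` (so the O(n^2) spread
  terms do not drown the O(n) edge terms) and `M = sqrt(n)` (a disc of
  about unit area per vertex). Majorization guarantees a non-increasing
  cost; iteration stops at relative cost change < 1e-9 or 1000 iterations
  (non-convergence returns the last iterate with a warning). Identical
  seeds give identical layouts. Pairwise computation is exact; no
  Barnes–Hut approximation is used at these problem sizes.

Note that with >= 4 vertices the spread term cannot be driven to zero in
the plane (at most 3 points are mutually equidistant), so even the perfect
optimum leaves the non-edge distances with a coefficient of variation
around 0.3–0.4; the tests assert concentration relative to the random
start, not impossible equidistance.

## Synthetic data

The generators are pure functions of their parameters and seed
(bit-reproducible), and each echoes its parameters in the returned `meta`
record. A 500-sample burn-in precedes every recorded dynamical trajectory.

* `gen_var` simulates a stable VAR(p) with known coefficients and bundles
  the generating model, so the *analytic* PDC is available as ground truth
  for estimator validation.
* `gen_coupled_henon` produces the canonical driver–response testbed for
  nonlinear interdependence: two Henon maps (a = 1.4, b = 0.3) where the
  coupling C replaces a fraction of the response's self-drive
  (`y(t+1) = 1.4 - (C x(t) + (1-C) y(t)) y(t) + 0.3 y(t-1)`). C = 0 gives
  independent realizations; the interdependence index rises monotonically
  with C. Divergent trajectories re-seed deterministically with a warning.
* `gen_sinusoid_pair` shares a sinusoid between two noisy channels for
  coherence validation (`snr = 0` degenerates to independent noise).
* `gen_random_network` / `gen_montage` provide random weighted graphs for
  the metric oracles and ring/grid electrode montages on the scalp oval,
  including a 61-channel cap emulating a typical dense-EEG study;
  `gen_eeg_like` drives a sparse stable VAR(2) for many-channel
  pipeline tests.

What this synthetic data does **not** emulate: volume conduction and
common-reference effects (which inflate zero-lag coupling between nearby
electrodes), non-stationarity across trials, artifacts (ocular, muscular),
or realistic 1/f spectra. Passing tests therefore establish correctness of
the estimators and metrics on their defining models, not robustness of
scientific conclusions drawn from real EEG; threshold selection and
significance testing of synchronization values are likewise out of scope.

## Problem sizes and tolerances

Default test and validation sizes were chosen as the smallest at which each
property is sharply distinguishable: 2000-sample Henon series for the
interdependence tests (Theiler-corrected k-NN statistics stabilize well
below that), 5000-sample realizations for VAR coefficient recovery within
±0.05, 64-point frequency grids for PDC, 200 random graphs with n <= 8 for
the brute-force path-enumeration oracles. Linear-system residuals
(eigenvector, Hubbell) are checked to 1e-10, stationary-distribution
residuals to 1e-12, the matrix-exponential/series agreement to 1e-9, and
path-length ties to a relative 1e-12.

## Reproducing the reference numbers

`scripts/acceptance.py --seed S --out results/acceptance.json` recomputes,
from scratch at run time: the star-graph assortativity (`t2`) and the
minimum self-coherence over the Welch frequency grid for a seeded
white-noise channel (`t4`). Both derive from closed-form identities, so
they are exact regardless of seed.
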