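# Methods

## The measures

**Sample entropy.** For a series `x` of length `N`, templates of length
`m` are the runs `x[i..i+m-1]`. Two templates match when their Chebyshev
(maximum-coordinate) distance is at most `r · SD`. With `B` the number of
distinct matching pairs at length `m` and `A` at length `m + 1`,

    SampEn(m, r, N) = −ln(A / B).

Conventions, all of which matter for bit-level reproducibility and are
exercised against a brute-force oracle in the tests:

* both template sets start at the first `N − m` points, so `A` and `B`
  are counted over a common pair index set;
* self-matches are excluded; pairs are unordered (`i < j`);
* the comparison is inclusive (`distance ≤ r · SD`);
* `SD` is the population standard deviation (`ddof = 0`) of the scale-1
  series unless a reference SD is supplied.

When either count is zero the ratio is undefined: the estimate *fails*.
Failures are data, not exceptions — they are carried as NaN plus a
boolean mask and skipped (with recorded skip counts) by every
aggregation. A constant series yields SampEn 0 (all templates match at
both lengths), not a failure.

**Multiscale entropy.** Scale factor `l` replaces non-overlapping blocks
of `l` points by their mean (trailing remainder dropped, length
`floor(N/l)`), and SampEn is evaluated per scale with the tolerance
anchored to the *scale-1* SD. This scale-invariant tolerance is what
drives the white-noise profile down with scale: coarse-graining divides
i.i.d. variance by `l` while the match radius stays fixed. For i.i.d.
Gaussian noise the profile has the closed form

    SampEn(l) = −ln erf(r √l / 2),

independent of `m`, which the suite uses as an independent oracle
(observed agreement within ±0.1 at N = 4800 over 20 realizations).
SampEn is *not* monotone in `r` in general — the match sets are nested,
so `A` and `B` are individually non-decreasing, but their ratio can dip
when counts are small; the tests assert the nestedness, not the folklore
ratio monotonicity.

**Phase-coherence edges.** Each node's instantaneous phase θ(t) is the
angle of its analytic (Hilbert-transformed) signal; no band-pass filter
is applied at any stage. Edge connectivity at time `t` is
`cos(θ_i(t) − θ_j(t))`, giving `n(n−1)/2` edge series indexed in
row-major upper-triangular order with 1-based node ids (90 nodes → 4005
edges). All time points are retained by default; a symmetric trim is
available for analytic-signal edge-effect sensitivity checks. Phases are
computed on the concatenated multi-run series; a per-run mode is
available by preprocessing runs separately.

**Complexity levels.** nMSE is the multiscale entropy of each node
signal (neuronal complexity); eMSE is the multiscale entropy of each
edge series (functional complexity); edge-based nMSE is a node's
unweighted mean eMSE over its `n − 1` incident edges. Network values are
unweighted means over member nodes of the 14-network, 90-node functional
parcellation shipped with the package; whole-brain values are unweighted
means over all nodes (or all edges for eMSE). Every mean skips failed
cells and records the skip count; a unit whose members all failed is
itself failed. The divergence map is the per-edge group-mean SampEn at a
coarse scale (default 10) minus a reference scale (default 2, where
whole-brain entropy peaks); edges failed at either scale for any subject
are excluded and listed. Level contrasts use two-tailed paired t-tests
with uncorrected p-values; no multiple-testing correction is applied
anywhere in the mapping.

## Parameter selection

The (m, r) grid is screened against CSF-like reference signals, which
carry minimal physiological information and serve as a noise floor. Per
subject and per (m, r, l) cell, SampEn is computed for each of the
subject's CSF series (scale-invariant tolerance per series) and the
relative error is derived from the mean μ and standard deviation σ of
those values. The default grid is m ∈ {1, 2, 3} × r ∈ {0.05, …, 0.80 in
steps of 0.05} — 48 combinations — over scales 1–10, with acceptance
threshold 0.1 (≈10% coefficient of variation).

The printed form of the relative-error formula is typographically
ambiguous, so all three readings are implemented and the variant is
recorded in every output:

| variant   | formula            | default |
|-----------|--------------------|---------|
| `literal` | 1.96 σ / μ²        | yes     |
| `ratio`   | 1.96 σ / μ         |         |
| `squared` | (1.96 σ / μ)²      |         |

The surface value per cell is the **median across subjects** of the
per-subject relative errors; a cell where *any* subject has a failed
SampEn is failed (strictest reading of the exclusion rule). A combination
is acceptable when no cell failed and the mean relative error across
scales is ≤ threshold; per pattern length, the failure-free combination
with the lowest mean RE is also reported. On synthetic white-noise CSF
the surface reproduces the expected structure: errors grow with scale and
with m, failures appear only at m = 3 with small tolerances, and the
per-m minimizers sit at small-to-moderate r.

## Behavioral prediction

Features are one measure's values over a set of scales, assembled
subject × (unit, scale) with deterministic unit-major, scale-minor column
order. Features failed for any subject are dropped cohort-wide and
logged; a missing cell (as opposed to a failed one) is an error.

Leave-one-subject-out SVR: for each held-out subject, the remaining
subjects' features are ranked by ascending Pearson-correlation p-value
against their scores (ties: |r| descending, then column position;
zero-variance columns last; no multiple-comparison correction), the first
`n` are selected, standardized with training-fold statistics, and a
linear-kernel SVR (library defaults: C = 1, ε = 0.1) is trained to
predict the held-out score. Ranking and standardization live strictly
inside the fold — the tests assert structurally that changing only the
held-out subject's score changes neither that fold's selection nor its
prediction. The headline statistic is the Pearson correlation between
the LOSO predictions and the actual scores; the cross-fold intersection
of selected features is reported as the "common features".

Significance uses a permutation test that keeps selection and training
identical while permuting the scores (default B = 1000; the verification
suite uses B = 99), with the add-one estimator
`p = (1 + #{r_perm ≥ r_obs}) / (1 + B)`, which can never be exactly
zero. The null distribution of the LOSO correlation under label
permutation is wide (empirically ±0.2 even at 100+ subjects) because
correlation-based selection lets folds co-adapt to noise — this is
precisely why the permutation test, not an analytic null, is used. Under
pure-noise scores the permutation p is uniform (KS-checked in the suite)
and the correlation is centered at zero over replicates.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes,
not the physics of imaging:

* per run, node signal = `(1 − λ_s) · (oscillator + pink) + λ_s · white`,
  where the oscillator is a band-limited (0.01–0.1 Hz by default, at
  0.72 s sampling) stochastic oscillation shared by all nodes of a
  resting-state network with a random spectrum per subject/network/run,
  the pink component is `1/f`-shaped background private to each node
  (spectral shaping of white noise, exponent 1, variance-normalized),
  and runs are independent given the subject's parameters;
* λ_s for *planted* nodes is uniform on `noise_fraction_range` (default
  0.2–0.8); all other nodes sit at the range midpoint, so only planted
  nodes carry between-subject entropy variation;
* CSF references are i.i.d. Gaussian white noise (default 10 per
  subject — the appropriate count is genuinely unknown, so it is a
  parameter, not a constant);
* the behavioral score is `Σ_k w_k λ_s(k) + ε`, `ε ~ N(0, 0.1)` with
  unit weights by default. Coupling the score to the mixing weight
  rather than to any computed entropy keeps the generator independent of
  the estimators it tests; the λ → entropy link is physical (more white
  noise ⇒ higher SampEn).

Defaults mirror the geometry of four ~15-minute runs at 0.72 s with 90
nodes (4 × 1200 → 4800 points); tests and the bundled analysis run
reduced sizes. What the generator does **not** emulate: hemodynamics,
spatial structure, motion or physiological artifacts, non-Gaussian CSF
content, family structure, or any confound (age, sex, motion). Passing
tests therefore demonstrate the estimators and the pipeline logic, not
performance on real BOLD data.

## Verification problem sizes

Chosen as the package's own trade-off between statistical resolution and
a test suite a laptop runs comfortably:

* SampEn counting: exact equality with a numpy brute force on 200 random
  series of length ≤ 60 for m ∈ {1,2,3}, r ∈ {0.1, 0.2, 0.5};
* Gaussian closed form: N = 4800, 20 seeds, m ∈ {1, 2}, r = 0.2, scales
  1–10, tolerance ±0.1 plus strict decrease;
* planted recovery: 60 subjects × 20 nodes × 4 × 300 points, operating
  point m = 3, r = 0.2, scales 1–10, 50 features per fold; median LOSO r
  over generator seeds 1–5 must exceed 0.4, and the B = 99 permutation
  test on the median-r seed's cohort must give p < 0.05;
* null calibration: 20 subjects × 40 noise features, 10 selected,
  B = 99, 20 replicates of fresh Gaussian scores on a fixed feature set
  (exact null, since features never depend on scores); KS test against
  uniform at α = 0.01;
* determinism: two same-seed runs of the full CLI chain must be
  byte-identical.

## Numerical and design notes

* The pair-counting kernel is compiled (numba) with early abort on the
  first exceeded coordinate; the test oracle is an independent
  broadcasting implementation with no shared code.
* Detrending is per-run least-squares linear fit removal, then per-run
  z-scoring with sample SD (ddof = 1), then concatenation — in that
  order. A node that detrends to numerical dust (constant or pure ramp)
  is an error naming subject, run, and node.
* Matrix files are tab-delimited text with 17-significant-digit floats:
  read(write(x)) is bit-exact. Node ids are 1-based everywhere a human
  reads them.
* Tie handling at distance exactly `r · SD` is inclusive; this is
  unobservable for continuous data but pinned down for reproducibility.
* Known limitations: no refined/composite MSE variants, no
  scale-dependent tolerance, no sliding-window dFC or state clustering,
  no confound regression, no imaging-format ingestion. These are out of
  scope by design.
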