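# Methods

## The Markovian Entropy measure

A single-cell calcium fluorescence trace `x_1 … x_T` is modelled as a
k-th order Markov process over `n` discrete activity states:

1. **Quantile discretization.** The empirical quantiles of the trace at
   levels `j/n` (j = 1 … n−1, linear interpolation between order
   statistics) define state boundaries; each value is replaced by the
   number of boundaries strictly below it. Values tied with a boundary go
   to the lower state. Quantile binning needs no user-set thresholds,
   gives each state near-equal occupancy, and makes the measure exactly
   invariant under strictly increasing transforms of the signal
   (in floating point: whenever the transform keeps values distinct).
2. **Transition tally.** Every (k-gram → next symbol) transition is
   counted into an `n^k × n` matrix (rows lexicographic, oldest symbol
   most significant); observed rows are normalised to probabilities.
   Total counts equal `T − k`.
3. **Entropy.** The Shannon entropies `−Σ p log2 p` of the rows are
   summed and divided by `n^k log2 n`, the maximum possible sum. The
   value lies in [0, 1]: 0 for fully predictable transitions, 1 for fully
   unpredictable ones. Unobserved rows contribute zero bits but remain in
   the denominator, so in the sparse regime (`n^k · n` approaching
   `T − k`) the value is depressed mechanically; a warning and the
   `unobserved_rows` count expose this regime. Constant ("dead-cell")
   traces return 0 with a `degenerate` flag instead of raising, so
   population pipelines keep running.

Row entropies are summed **unweighted** — deliberately not weighted by
stationary occupancy (which would give an entropy rate). The unweighted
sum is the quantity this measure is defined as; do not "improve" it.

Defaults `n = 2, k = 1` suit traces of length ~800–900. The matrix size
grows as `n^(k+1)`; keep it well below the trace length.

### Estimator bias under quantile binning of discrete-level signals

A subtlety worth knowing when validating against chains with known
entropy: quantile binning forces an exactly equal symbol split, while the
true state occupancy of a persistent chain fluctuates (for a symmetric
stay-0.9 two-state chain at length 900 the occupancy SD is ≈ 45 points).
Whenever occupancy deviates from 50/50, the median boundary falls inside
one noise cluster and the excess points are mislabelled — about 4% of
points on average, **independent of how small the observation noise is**.
The mislabelled points are scattered randomly in time, so they inflate
the estimated transition entropy: the full pipeline reports ≈ 0.62 for a
chain whose symbolic entropy is 0.469. (With exactly zero noise a
different pathology appears: the boundary ties the upper level and the
tie rule collapses a state.) The transition-entropy estimator itself is
nearly unbiased — applied to the exactly observed state path, its mean
over 200 length-900 traces is within 0.003 of the analytic value — so
the acceptance analysis evaluates estimator consistency on the
generator's true symbol path and reports the full-pipeline value
alongside it as a measured property of the discretization. On real-valued
calcium signals, whose within-state dynamics spread values continuously,
this two-level pathology is a worst case rather than the typical regime.

## Comparator measures

**Spike counting.** Onset at index t when `x[t] ≥ 1.5 · x[t−1]` (ratio
configurable) and `x[t−1] > 0`; the spike persists while the trace stays
at or above the value **at the onset point**, ends at the first point
below it, and counts only if it spans ≥ 2 points. Scanning resumes after
the spike end, so spikes never overlap. Two documented choices: (a) "the
value attained at the onset" is read as the elevated value at the onset
sample, not the pre-onset baseline — this is what makes the two-point
duration rule discriminating; (b) onset tests with a non-positive
predecessor (possible after baseline subtraction) are skipped and
tallied, since a ratio threshold is undefined there. The detector is
scale-invariant but **not** shift-invariant — adding an offset changes
every onset ratio — which is exactly the fragility the threshold-sweep
analysis quantifies.

**Average power.** `(1/T) Σ x_t²` — the discrete-signal Parseval form.
Trend- and offset-sensitive by construction.

**Hurst exponent.** One 512-point window is placed uniformly at random
(seeded) in the trace; for each dyadic size s = 512, 256, …, 8 the window
is tiled from its left edge and the rescaled ranges of the tiles
averaged. For a segment X: `Y = X − mean(X)`, `Z = cumsum(Y)`,
`R_i = max(Z_1..Z_i) − min(Z_1..Z_i)`, and a standard-deviation series
`S_i`; the segment's rescaled range is the mean of `R_i / S_i` over
indices with `S_i > 0` (constant prefixes are skipped). The estimate is
the OLS slope of `log2(mean R/S)` against `log2 s` — the slope must be
taken in log–log for H = 0.5 to emerge on memoryless noise. Estimates
with H > 1 carry an `excluded` flag and are dropped from population
statistics.

Two variants of `S_i` are provided. The default (`sd_mode="paper"`)
centres each term on the running mean of its own prefix,
`S_i = sqrt((1/i) Σ_{k≤i} (X_k − u_k)²)` with `u_k = mean(X_1..X_k)`;
the conventional form (`sd_mode="classic"`) centres every term on `u_i`.
Measured calibration on 500 white-noise traces (length 900): mean H
≈ 0.49 for the classic series, ≈ 0.43 for the running-mean series —
the running-mean variant carries a small negative bias. Calibration
claims about the H = 0.5 white-noise law therefore refer to the classic
series; the default remains the running-mean form for continuity with
the measure as defined. Random-walk traces give mean H ≈ 0.87, with
~12% of estimates flagged H > 1.

## Preprocessing: AsLS baseline correction

Slow trends (bleaching, drift) are removed by asymmetric least squares:
minimise `Σ w_i (y_i − z_i)² + λ Σ (Δ²z_i)²` with `w_i = p` above the
baseline and `1 − p` below, re-deriving weights from the current solution
until no point switches sides (or `max_iter`). Each iteration solves the
sparse pentadiagonal system exactly. Defaults λ = 1e5, p = 0.01,
max_iter = 20, tol = 1e-6 — inside the canonical recommended ranges for
signals of this length with positive-going transients; all exposed as
parameters and CLI flags. Useful identities: a constant trace is a fixed
point; a straight line passes through unchanged (second differences
vanish); the objective is translation-invariant, so detrending is
unaffected by additive offsets; larger λ strictly reduces baseline
roughness. Detrending is idempotent to ~1e-2 on spiky traces (the weight
configuration can shift slightly on the second pass).

Because the entropy measure depends on values only through ranks,
detrending moves it only where the trend is large enough to reorder
points: on trend-free stay-0.9 chain traces the mean |shift| from
detrending is ≈ 0.02, and a linear drift of 0.2 (one fifth of the signal
range over the whole recording) shifts entropy by ≈ 0.03 on average
while moving average power by > 10%.

## Population statistics

Two-sample Kolmogorov–Smirnov test with the asymptotic two-sided
p-value (sample sizes in scope are tens to hundreds; reported extreme
p-values are necessarily asymptotic), Bonferroni-scaled by the number of
comparisons m in the invocation (`p_adj = min(1, m·p)`, m explicit, never
inferred). Effect size is Cohen's d with pooled (n−1)-variance SD, sign
convention mean(A) − mean(B) with A listed first. |d| maps to
lower-inclusive star bands at 0.20 / 0.50 / 0.80 / 1.00 / 2.00
(* to *****); the ≥-edge convention is used at exact band edges.

**Subsample separation.** For each sample size s, `reps` pairs of size-s
with-replacement samples are drawn (one per population) and the KS p
recorded, plus an A-vs-A control. Mean p declines monotonically with s
for genuinely different populations and stays ≳ 0.5 for the control.
Desk-scale runs use reps = 200 (the analysis is a mean over i.i.d.
replicates; its shape is stable well below the 5,000 replicates used at
full scale).

**Parameter sweep.** Cohen's d of the entropy comparison over a grid of
(n, k), optionally on truncated traces. When `n^k · n` outgrows the
usable trace length, the measured d can flip sign — a data-sparseness
artifact, not biology: the less entropic population concentrates its
counts on few k-grams whose rows remain well-estimated (entropy > 0),
while the more entropic population scatters single counts across many
rows that all look deterministic. The sweep reports the cells whose sign
differs from the (2, 1) reference. On 900-point chain populations the
first flip appears at matrix sizes ~2000; truncation to 100 points pulls
it down to ~250, confirming the artifact scales with data, not with the
dynamics.

## Synthetic data

- **Chain traces**: n-state chain started from its stationary
  distribution, emitting `levels[state] + N(0, noise_sd)`; defaults
  length 900, levels (0, 1), noise SD 0.05 (visually comparable to
  indicator noise relative to a unit dynamic range), with the analytic
  normalized entropy of the generating matrix available for validation.
- **Spike traces**: baseline 1.0 plus Bernoulli events (rate 0.01/frame)
  with amplitude 3.0 and exponential decay τ = 5 frames, noise SD 0.02.
  Each transient rises over one frame (half amplitude at the event frame,
  peak the next) before decaying — real indicator transients have a
  finite rise, and an instantaneous-rise kernel would make its own peak
  the onset sample, leaving nothing for a ratio-onset detector with a
  two-point duration rule to count.
- **Irregular traces**: stationary AR(1) around a mean level (default
  coefficient 0.8) — the progenitor-like regime with no clean features.
- **Trends**: additive `magnitude · t/T` or `magnitude · exp(−3t/T)`.
- **Populations**: per-cell seeds derive from
  `SeedSequence([master, index])` (truncated below 2^31), so populations
  are bit-reproducible and growing a population preserves its first
  cells.

What the generators do **not** emulate: indicator saturation and
nonlinearity, photon shot noise, bleaching photophysics beyond the trend
fixture, cell-to-cell parameter heterogeneity, and mechanistic calcium
kinetics. Passing tests on these fixtures demonstrate the estimators'
statistical behaviour under known ground truth, not performance on any
particular microscope's noise regime.

## Numerical and interface choices

- `0 · log2 0 ≡ 0` throughout; entropies computed on exact integer
  counts, so monotone-transform invariance of the entropy is exact.
- Quantiles: numpy's linear-interpolation definition; tie-heavy data can
  shift boundaries, documented above.
- R/S terms with `S_i = 0` are skipped; fully constant segments raise a
  distinct `ConstantSegmentError`.
- Hurst affine invariance is exact for power-of-two rescalings (IEEE-754
  exactness) and holds to ~1e-9 for general affine maps.
- CLI outputs carry a `#`-prefixed provenance header (tool version, full
  parameter set, seed — no timestamps), so identical command + seed gives
  byte-identical files; `#` lines are skipped on read. Exit codes follow
  the click convention: 0 success, 2 usage error, 1 data/runtime error.
- Test and validation problem sizes (200-trace chain populations,
  500-trace Hurst calibrations, 2000-rep KS null, reps = 200
  subsampling, 100-cell sweep populations) were chosen as the smallest
  scales at which the targeted quantities are stable to well within the
  asserted tolerances across seeds.

## Known limitations

- The entropy value at large (n, k) is dominated by the unobserved-row
  mechanics; compare values across conditions only at matched (n, k) and
  trace length.
- The quantile-binning bias on discrete-level signals described above.
- The Hurst estimator inherits classical small-window R/S bias; its
  absolute level is estimator-specific, so compare H across populations
  estimated with identical settings only.
- KS p-values are asymptotic; at subsample sizes below ~10 with heavy
  ties they are conservative.
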