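# calentropy

Quantifying how *predictable* single-cell calcium activity is.

Many calcium signals — developing neural progenitors are the canonical
case — do not decompose into clean spikes, waves or oscillations, so
feature-based analyses (spike counts, peak shapes) either miss the
dynamics or hinge on arbitrary thresholds. `calentropy` takes a
feature-free view: it models each fluorescence trace as a **k-th order,
n-state Markov process** and scores the Shannon entropy of its state
transitions.

For a trace `x_1 … x_T`:

1. split the observed values into `n` empirical quantiles and map each
   value to its quantile index, giving a symbol sequence over
   `{0, …, n−1}`;
2. tally every (k-gram → next symbol) transition into an `n^k × n`
   matrix and row-normalise it;
3. report the **Markovian Entropy**

   E = Σ_rows ( −Σ_i p_i log₂ p_i ) / ( n^k log₂ n )  ∈ [0, 1],

   0 when every observed transition is deterministic, 1 when every
   k-gram's successor is uniformly random.

Because the discretization is quantile-based, the measure is invariant
under any monotone rescaling of the signal and largely insensitive to
slow trends. Alongside it the package implements the three standard
comparator measures — **spike counting** (150%-of-previous-point onset
rule), **average power** `(1/T) Σ x²`, and the **rescaled-range Hurst
exponent** — plus asymmetric-least-squares (AsLS) detrending,
population-comparison statistics (two-sample KS test, Cohen's d with
star bands at |d| ≥ 0.20/0.50/0.80/1.00/2.00, Bonferroni correction),
robustness meta-analyses (subsample separation curves, (n, k) parameter
sweeps), and a fully seeded synthetic-trace generator with analytic
ground truth.

Intended users: anyone analysing wide-format CSVs of single-cell calcium
time series (rows = time points, columns = cells) who wants a
threshold-free activity measure and honest statistics around it.

## Worked example

Generate two populations of noisy two-state Markov traces — one
persistent (stay probability 0.9, strongly autocorrelated, like early
progenitors) and one labile (stay probability 0.6) — then score and
compare them:

```bash
calentropy simulate chain --cells 50 --stay-prob 0.9 --seed 1 -o stage14.csv
calentropy simulate chain --cells 50 --stay-prob 0.6 --seed 2 -o stage22.csv
calentropy analyze stage14.csv --measure entropy --n 2 --k 1 -o ent14.csv
calentropy compare stage14.csv stage22.csv --measure entropy --bonferroni 3 -o cmp.csv
```

`ent14.csv` holds one row per cell:

```
# calentropy 0.1.0 | analyze | ... k=1 measure=entropy n=2 ...
cell_id,excluded,entropy,degenerate,unobserved_rows
cell_0001,False,0.50362930653851645,False,0
cell_0002,False,0.73765425633720316,False,0
```

Cell 1 scored 0.504: its binary state transitions carry about half the
maximum entropy, i.e. fairly predictable dynamics (the generating
stay-0.9 chain has analytic normalized entropy 0.469; quantile binning
of noisy two-level emissions reads slightly high — see
`docs/methods.md`). The compare command prints

```
entropy: d=-4.714 (*****), KS=1.000, p_adj=0
```

Cohen's d = −4.71: the persistent population is far *less* entropic than
the labile one (sign convention mean(A) − mean(B)), a five-star effect
(|d| ≥ 2), with the Bonferroni-adjusted KS p-value numerically zero.

The same library surface is available in Python
(`calentropy.markovian_entropy`, `compare_populations`,
`parameter_sweep`, `subsample_separation`, …), and the remaining
subcommands cover detrending (`detrend`), the other measures
(`analyze --measure spikes|power|hurst`), and the robustness analyses
(`sweep`, `subsample`). To run the pipeline on real recordings, point
`detrend`/`analyze` at your CSV export (use `--orientation time_columns`
if cells are rows).

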