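# Methods

## Model

Each of `n` brain regions (default 90, an AAL-style parcellation) carries the
normal form of a supercritical Hopf bifurcation (Stuart–Landau oscillator) in
the complex variable `z_j = x_j + i y_j`:

    dx_j/dt = (a_j − x_j² − y_j²) x_j − ω y_j + G Σ_i C_ij (x_i − x_j) + β η_j(t)
    dy_j/dt = (a_j − x_j² − y_j²) y_j + ω x_j + G Σ_i C_ij (y_i − y_j) + β η_j(t)

with a homogeneous angular frequency `ω = 2π f_f`, diffusive coupling through
the structural matrix `C`, a global coupling scale `G`, and additive Gaussian
white noise of amplitude `β`, independent per node and per equation.  For
`a_j < 0` a node is a noisy damped oscillator; for `a_j > 0` it sits on a
limit cycle of radius `√a_j`.  All analyses here run at criticality
(`a_j = 0` for every node), where noise drives transient excursions toward
the oscillatory regime; regions receiving correlated structural input make
these excursions together, which is the mechanism that produces correlated
band-limited amplitude envelopes.  `x_j(t)` is treated as the simulated
source-space MEG signal.

The multi-frequency configuration runs one *independent* network per
fundamental frequency (default `f_f ∈ {4, 8, 12, 16, 20, 24, 28}` Hz), all
sharing the connectome and the same `G`, with no cross-frequency interaction;
each layer is analyzed only in its own carrier band.

### Parameters

| parameter | default | units | role |
|---|---|---|---|
| `a_j` | 0 | – | bifurcation parameter; 0 = critical point |
| `f_f` | – | Hz | fundamental (carrier-generating) frequency |
| `G` | scan 0–1 | – | global coupling; the principal control parameter |
| `β` | 0.02 | state units | additive noise standard deviation |
| `α` | 0.2 | – | connectome rescaling: `C ← α·C/max(C)` |
| `dt` | 1 | ms | integration step |
| `duration` / `burn_in` | 300 / 10 | s | simulated time; discarded transient |
| `output_rate` | 250 | Hz | output sampling (matches downsampled MEG) |

The α-rescaling only fixes the units of `G` and `β`; `G` is explored on
[0, 1] and the fundamental frequency on 1:2:29 Hz.

## Integration

The integrator is an exact-rotation splitting scheme (exponential
Euler–Maruyama): each step applies an Euler–Maruyama substep to the
amplitude dynamics, coupling, and noise (increment `β √dt N(0,1)` per node
and equation), then rotates `(x, y)` exactly by `ω dt`.  Plain
Euler–Maruyama is not usable for this model at audio-band frequencies: its
linearization of the rotation has per-step modulus `√(1 + (ω dt)²)`, which
acts as a spurious bifurcation-parameter shift of `ω² dt / 2` — at
`f_f = 12` Hz and `dt = 1` ms that is +2.8, pushing every "critical" node
deep into the oscillatory regime (the state settles near `|z| ≈ 1.69`, the
square root of the shift).  The splitting scheme removes the bias exactly at
identical cost and remains first-order convergent in `dt` for the remaining
dynamics; a half-step agreement test against a high-accuracy Runge–Kutta
reference verifies the order.

The coupling sum is evaluated in difference form `Σ_i C_ij (x_i − x_j)`, so
a spatially uniform state receives *exactly* zero coupling in floating
point; noise-free trajectories from uniform initial conditions are therefore
bit-identical for every `G`, which the tests assert.  Initial conditions
default to uniform draws in [−0.1, 0.1]² per node from the same seeded
generator as the noise; 10 s of burn-in are discarded.  A trajectory leaving
`|z| > 10³` raises an error naming the integration step.

## Envelope analysis

For each carrier band `[f_c − 2, f_c + 2]` Hz (`f_c = 4:2:28`):

1. zero-phase 4th-order Butterworth band-pass (`sosfiltfilt`);
2. decimation of the narrowband signal by plain striding to an intermediate
   rate of at least 2.5× the band's upper edge (the band-pass stopband is
   the anti-alias filter); this only removes redundant samples;
3. Hilbert transform → instantaneous amplitude `A(t)` and carrier phase;
4. zero-phase 4th-order Butterworth low-pass of `A(t)` at 0.2 Hz → the
   ultra-slow envelope component used in all statistics;
5. striding to the 5 Hz analysis rate (the 0.2 Hz low-pass is the
   anti-alias filter; the raw-envelope channel is strided with the same
   offsets so all arrays share one time base);
6. per-region demeaning and a second Hilbert transform → envelope phases.
   Demeaning is required because `A(t)` is one-sided; the analytic phase of
   a signal with a dominant DC component is degenerate.

One second of data is discarded per side after each filter/Hilbert stage
(edge transients).  Empirical source-space matrices and simulated signals go
through this identical code path.

## Observables

- **Envelope FC** — region × region Pearson correlation of the slow
  envelope components over the whole retained record.  Zero-variance regions
  are flagged `NaN`, never silently zeroed.  Group averaging is a plain mean
  over FC matrices.
- **Metastability** — the standard deviation over time (population,
  `ddof=0`) of the Kuramoto order parameter
  `R(t) = |Σ_k exp(i φ_k(t))| / n` of the envelope phases.
- **CCD** — coherence connectivity dynamics: the time × time matrix of
  cosine similarities between instantaneous coherence vectors `V(t)`, where
  `V(t)` holds `cos|φ_i(t) − φ_j(t)|` for all region pairs in row-major
  upper-triangle order.  The Gram matrix is evaluated through a phasor
  identity (`V(t)·V(t′)` reduces to `(|Z Z^H|² + |Z Zᵀ|² − 2n)/4` with
  `Z_tk = exp(i φ_k(t))`), which is O(T²n) instead of O(T²n²) and agrees
  with the explicit dot products to machine precision (tested).  Records
  longer than 300 s are split into consecutive ≤300 s sessions; CCD is
  computed per session and upper-triangle values are pooled, mirroring the
  handling of multi-session empirical recordings and bounding memory.
- **KS distance** — two-sample Kolmogorov–Smirnov statistic between pooled
  upper-triangle CCD value distributions; the model-fitting objective.
  Implemented directly (sorted-sample CDF evaluation) because it runs on
  ~10⁶-value samples inside scans; verified against brute-force CDF sweeps
  and `scipy.stats.ks_2samp` to 1e-12.

## Fitting

`scan_single_frequency` simulates every `(f_f, G)` cell, summarizes it
through the same pipeline, and records per carrier band the FC-triangle
correlation, the KS distance, and the metastability against a target
summary.  Per-cell seeds derive from a base seed and the cell index through
`numpy.random.SeedSequence`, so scans are reproducible and cells
independent.  The optimum is the cell minimizing band-averaged KS distance
(tie-break: smaller `G`, then smaller `f_f`); band subsets default to the
8–16 Hz carriers for single-frequency optimization, where resting-state
envelope correlations are most meaningful, and to all bands for
multi-frequency evaluation.  The `combined` criterion minimizes
`KS + (1 − FC)/2`, putting both observables on comparable [0, 1] scales.

## Synthetic data

No public deposition exists for the study-type inputs (a group-averaged DTI
connectome and source-space MEG), so the package generates both.

**Connectome generator.**  Modular log-normal weights: block support with
full intra-module density and 0.25 inter-module density, log-space sigma
0.65, inter-module median lighter by 2.5 log-units, symmetrized,
zero-diagonal, α-normalized (α-normalized row sums ≈ 0.8).  The defaults
were calibrated so that the critical Hopf network driven through the matrix
reproduces, across `G ∈ [0, 1]`, the qualitative operating regime reported
for empirical connectomes: the envelope-synchronization transition falls
inside the scanned coupling range, and at `G ≈ 0.5` the network shows
partial, module-shaped envelope synchrony (envelope-phase order parameter
≈ 0.3) with fast metastable switching rather than locked global coherence,
so the `G` scan is informative on both sides of the optimum.  Two failure
modes bracketed the calibration and are worth recording: with too little
total coupling mass (α-normalized row sums ≈ 0.25) the responsive regime
moves to `G ≈ 2–4` and the [0, 1] scan is flat; with too much (row sums
≳ 1), `G = 0.5` lands far *above* the transition, where the order parameter
wanders on ~100 s timescales and single-run CCD distributions become
irreproducible.

**Pseudo-empirical targets.**  `make_pseudo_empirical` simulates at hidden
`(f_f*, G*)` and summarizes the result exactly like empirical input,
sealing the hidden values in a provenance record.  For recovery experiments
the target pools several independent records (`combine_target_summaries`
concatenates CCD triangles and averages FC matrices), mirroring pooling of
empirical data over participants and sessions.

**What the generator does not emulate:** spatial embedding (no
distance-dependent weights or homotopic pairs), measurement noise and source
leakage of beamformed MEG, inter-subject variability, and 1/f background
spectra.  Passing tests therefore demonstrate the mechanism and the
correctness of the analysis chain on model-consistent data, not performance
on real recordings.

## Problem sizes, sampling noise, and experiment designs

The envelope order parameter decorrelates over ~15 s (a timescale set by
the 0.2 Hz envelope low-pass), so a 300 s record holds only ~20 independent
coherence states; single-record CCD value distributions therefore carry
heavy sampling noise (two matched-parameter 300 s runs can differ by KS
0.1–0.4).  Three consequences shape the package's experiment designs:

- *Parameter recovery* (coarse grid `f_f ∈ {8..16}` Hz × `G ∈ {0.3..0.7}`,
  300 s per cell) uses common random numbers across scan cells
  (`seed_policy="common"`): with independent per-cell seeds the argmin over
  `G` is dominated by sampling noise, and comparing single short records
  against a better-sampled pooled target is systematically biased toward
  *low* `G` (a stable weak-coupling run matches the bulk of a pooled
  mixture better than a volatile matched-coupling run).  Sharing one noise
  stream per repetition cancels most cell-to-cell realization noise; the
  default policy remains independent seeds.
- *Multi-frequency self-consistency* uses 1200 s per layer with both sides
  pooled over two independent records per layer (`runs_per_layer=2`), the
  same pooling applied to multi-session empirical data.
- The fundamental frequency is always recovered robustly (off-band
  envelopes carry an unmistakable signature); the coupling dimension is the
  marginal one at these record lengths.

Butterworth order (4), edge-trim (1 s), analysis rate (5 Hz), CCD session
length (300 s), and the carrier-rate margin (2.5×) are all exposed in
`EnvelopeConfig`.

Known limitations: no transmission delays (instantaneous coupling), no
cross-frequency interactions in the multi-frequency configuration, no
per-region bifurcation-parameter heterogeneity, and a scalar `G` shared by
all layers.  These mirror the modeled mechanism's scope rather than
implementation shortcuts.
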