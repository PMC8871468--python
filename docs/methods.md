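# Methods

## The membrane model

`neurorqa` simulates the two-variable Morris–Lecar (ML) membrane: a fast
voltage `v` (mV) and a slow recovery variable `w ∈ [0,1]`,

```
c dv/dt = i_stim − dΔv/dt − i_fast − i_slow − i_leak
  dw/dt = φ (m2(v) − w) / b(v)
```

with currents `i_fast = g_fast·m1(v)·(v+Δv−e_Na)`,
`i_slow = g_slow·w·(v+Δv−e_K)`, `i_leak = g_leak·(v+Δv−e_leak)`, sigmoid
steady states `m1(v) = ½(1+tanh((v−u1)/u2))`, `m2(v) = ½(1+tanh((v−u3)/u4))`
and the voltage-dependent time-constant factor
`b(v) = 1/cosh((v−u3)/(2·u4))`.  Dividing by `b` is the standard ML
convention (the recovery rate is `φ·cosh(·)`); the alternative reading
(multiplying by `b`) slows recovery roughly seven-fold and abolishes the
bursting regimes described below, so it is not offered.

An extremely-low-frequency (ELF, ≤ ~10 Hz equivalent) sinusoidal electric
field does not act as a current source.  It induces a membrane
depolarization

```
Δv(t) = (A/ω)·sin(ωt) + V_E ,    dΔv/dt = A·cos(ωt)
```

which is added to the voltage inside every ionic driving force, while its
time derivative enters the current balance.  The constant offset
`V_E = −17.63 mV` shifts all effective reversal potentials upward, making
the default parameter set (u1=−1.2, u2=18, u3=−13, u4=10 mV; conductances
20/20/2 mS/cm²; reversals 50/−100/−70 mV; φ=0.15; c=2 μF/cm²; i_stim=0)
tonically active with an intrinsic period of ≈ 43 ms; the `A/ω` scaling
makes slow fields modulate the membrane strongly (2 mV at ω=0.05 rad/ms)
and fast fields weakly.  By default the `−dΔv/dt` term sits inside the
bracket divided by `c` (the literal current-balance form);
`field_term_over_c=False` moves it outside.  At the amplitudes studied
(A ≤ 0.2) the two readings are numerically indistinguishable.

All rates are per millisecond, `ω` in rad/ms.

### Regime structure

With `A = 0.1` the neuron's response is set by `ω`: *n*-spike bursting for
ω ≲ 0.12 (4 spikes per stimulus period at ω=0.05, 2 at ω=0.10), a broad
1:1 entrained band ω ≈ 0.121–0.280, a chaotic (aperiodic) band beginning
near ω ≈ 0.281, and mode-locked single-spike firing above it (at ω=0.5 the
neuron fires exactly one action potential every third stimulus period,
phase-locked to the field; the locking ratio settles over the first
~1000 ms).

### The coupled pair

Two neurons are coupled by a gap junction, an ohmic current `−g·(v_i−v_j)`
divided by `c` like every other current.  The pair is mismatched —
`u2 = 18.0/18.1 mV`, `u3 = −12.8/−10.0 mV` — so each neuron bursts
chaotically at ω=0.286 with distinct mean frequencies.  A sign-flipped
variant of `u2` (−18.0/−18.1) is selectable via `presets.mismatched_pair`,
but it renders the fast activation inverted and the pair quiescent, so the
positive-sign pair is the default.  Initial conditions: v1(0)=−65.6,
v2(0)=−60 mV, w(0)=0 (the recovery variable's start is not critical after
transient removal).

## Integration

Classic fixed-step RK4; dt = 0.01 ms for single-neuron runs (2000 ms
default; 4000 ms for the aperiodic-band scan), dt = 0.05 ms with 50,000
steps and the first 10,000 samples discarded for coupled runs.  A
post-integration guard flags any |state| above 500 mV (far outside
physiology) with the offending step.  The integrator broadcasts over
trailing batch axes, so a 500-point coupling grid or an 81-point frequency
grid integrates as one vectorized run; results are bit-reproducible.
Empirical convergence order on the neuron itself is ≥ 3.9.

## Spikes, phases, frequency locking

Spikes are upward 0 mV crossings with a 2 ms refractory gap (ML action
potentials overshoot 0 mV robustly; the detector threshold only needs to
sit between rest and peak).  Regime classification uses stationary
interspike intervals (ISIs; everything after the leading 25% of a
single-neuron run): agreeing per-period spike counts with a repeating ISI
pattern → periodic n-spike bursting; more than 10 distinct ISIs (rounded
to 0.5 ms) with no repetition period ≤ 12 → aperiodic/chaotic; otherwise
mode-locked.  The distinct-ISI criterion is a deliberate heuristic —
Lyapunov exponents are out of scope — so band edges carry ±a few grid
steps of uncertainty.

Phases come from the analytic signal (Hilbert transform) of the
mean-subtracted voltage.  Instantaneous phase is unreliable for spiky
signals, so only the long-run mean frequency `Ω = Δφ/Δt` is used, with 10%
of samples trimmed at each edge where the analytic signal is distorted.
The finite 2000 ms record leaves a noise floor of ~1–2·10⁻³ rad/ms on
`ΔΩ = Ω1 − Ω2` even when the pair is perfectly locked.

**Locking tolerance.**  "ΔΩ vanishes" needs a quantitative cut.  The
package uses 2% of the *intrinsic* mismatch — |ΔΩ| at g=0 with no field —
as the default tolerance and reports the smallest grid g after which |ΔΩ|
stays below it.  Referencing each sweep's own g=0 baseline instead would
scale the cut with the forcing (for A=0.1 it lands at ~0.001, below the
Hilbert noise floor) and is therefore not usable.  With this definition
the pair locks at g ≈ 0.0655 without field and g ≈ 0.038 with A=0.1,
ω=0.286; the uncoupled pair locks by field alone at A ≈ 0.155 (at A=0.15
the residual |ΔΩ| is 7% of the intrinsic mismatch — visually zero on a
sweep plot but above the 2% cut).

## Recurrence analysis

Scalar voltage series are point-decimated to ≤ 5000 samples (0.45 ms
effective sampling for coupled runs, 0.4 ms for single-neuron runs; RR(τ)
peak positions in ms are insensitive to the factor), then delay-embedded.
Embedding presets follow the multi-delay convention (dimension m with m−1
lags): 4-spike (3; 17, 22), 2-spike (2; 16), chaos (2; 20), 1-spike
(2; 19); the embedding-selection algorithm that produced them is not
reimplemented.  Coupled runs default to the chaos preset.

The threshold ε is the `round(density·N²)`-th smallest element of the full
N² pairwise Euclidean distance multiset (diagonal zeros included), with
distances exactly equal to ε counting as recurrent, so the recurrence
matrix `R(i,j) = Θ(ε−‖x(i)−x(j)‖)` attains the requested point density to
within ±0.005 (up to ties).  Densities: 0.15 for single-neuron RPs, 0.1
for the synchronization pipeline.  RR(τ), the mean of the τ-th
superdiagonal, is computed diagonal-by-diagonal without materializing the
N×N matrix; the streaming and materialized paths agree exactly and both
are exposed.

## Synchronization measures

All measures compare the two neurons' RR(τ) series on a common lag grid
after removing lags below a 25 ms Theiler window (the τ≈0 peak belongs to
every RP's main diagonal and would fake similarity):

* `cpr_pearson` — Pearson correlation of the two series (the classical
  correlation of probability of recurrence); ≈1 under phase
  synchronization.  Onset is reported as the smallest g after which
  CPR > 0.95 is sustained, mirroring the ΔΩ onset rule.
* `cpr_spearman` — the same on average-tied ranks; less sensitive to the
  spiky marginal distribution of RR(τ) but biased by its many zeros.
* `hellinger` — RR(τ) estimates a probability of recurrence after lag τ,
  so the two truncated series are normalized to unit sum and compared as
  probability distributions: `H = √(½ Σ (√p−√q)²) ∈ [0,1]`, 0 for
  identical lag distributions, 1 for disjoint ones.  Unit-sum
  normalization is what guarantees the [0,1] range and the metric axioms.
  A secondary `normalization="rms"` reading —
  `√(½·mean((√RR1−√RR2)²))`, no normalization, per-lag averaging — is
  provided because the defining expression is ambiguous in parts of the
  literature; it compresses the scale (unsynchronized pairs ≈0.25 instead
  of ≈0.8) but orders regimes identically.

On the coupled pair, unsynchronized regimes give CPR ≈ 0.2 / H ≈ 0.7–0.8;
the synchronized regime (g=0.04, A=0.1) gives CPR ≈ 0.99 / H ≈ 0.15, with
the two RR(τ) series overlapping at Pearson r > 0.9.

## Surrogate significance test

The null hypothesis "the two signals are not synchronized" is sampled by
block shuffling: the decimated voltage of neuron 2 is cut into five
equal-width contiguous blocks, the block order is permuted (identity
excluded), and the full pipeline — embedding, fixed-density threshold,
RR(τ), Theiler window, H — is rerun against the unshuffled neuron 1;
1000 surrogates build p(H) and its 95% quantile is the confidence limit.
Blocks preserve short-term structure (burst shapes) while destroying
long-range phase relations; the value multiset is conserved exactly.
Under the package's H the null concentrates near the unsynchronized
observed values (q95 ≈ 0.79 at A=0, g=0.01 — as expected, since shuffled
surrogates *are* unsynchronized), so observed H ≈ 0.8 at small g is
correctly non-significant while H ≈ 0.1 in the locked regime lies far
below the entire ensemble.  The shuffle consumes the only randomness in
the package; a single integer seed reproduces the ensemble bit-for-bit.

## Problem sizes and numerical choices

Default experiment sizes: 500-point g grids on [0, 0.15]; amplitude grid
0–0.2 in steps of 0.005; ω grid 0.25–0.33 in steps of 0.001 with 4000 ms
runs for the band edge; 1000 surrogates.  Degenerate inputs are rejected
loudly rather than coerced: constant series (undefined phase, zero CPR
variance), all-zero truncated RR(τ), Theiler windows that empty the
series, embedding delays longer than the series, negative conductances.
Onset detectors return a sentinel (`None`) when locking is never
sustained on the grid.

## What the simulations do and do not show

All experiments run on the deterministic model itself — there is no
measurement noise, no channel stochasticity, no synaptic input, and no
network beyond two cells.  Passing tests therefore demonstrate the
internal consistency of the dynamics and of the recurrence toolkit, not
robustness of the measures to noisy biological recordings.  The toolkit
functions accept arbitrary scalar series, so the measures can be applied
to recorded data, but their noise sensitivity (particularly of the
fixed-density threshold and the Theiler window choice) has not been
characterized here.
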