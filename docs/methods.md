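# Methods

This note documents the model, the statistics, the numerical choices and the
known limitations of the `multistable` package.

## Model and integration

Two populations with activities r₁, r₂ ∈ (0, 1) compete through mutual
inhibition β, adapt with strength φₐ on the slow time scale τₐ, share a
common drive I₀ and receive independent colored noise:

    τᵣ ṙᵢ = −rᵢ + F(α rᵢ − β rⱼ − φₐ aᵢ + Iᵢ + nᵢ),   F(x) = 1/(1+e^(−x/k))
    τₐ ȧᵢ = −aᵢ + rᵢ
    ṅᵢ = −nᵢ/τₙ + √(2σₙ²/τₙ) ξᵢ

Fixed parameters: τᵣ = 10 ms, τₙ = 100 ms, k = 0.1, α = 0 (no
self-excitation; the self-sustaining regime is out of scope). Free
parameters and their grid ranges: I₀ ∈ [0, 2], β ∈ [0, 2], φₐ ∈ [0, 1]
(the regime-relevant triplet), σₙ ∈ [0.01, 0.35] and τₐ ∈ [1, 8] s (the
"hidden" pair, which shapes durations but not the regime).

Integration is fixed-step Euler with dt = 1 ms (= τᵣ/10) for (r, a). The
noise channel uses the exact discrete Ornstein–Uhlenbeck update
n ← n·e^(−dt/τₙ) + σₙ√(1−e^(−2dt/τₙ))·ξ with stationary initialisation, so
the noise statistics carry no discretisation bias. Unit Gaussian draws are
pre-generated vectorised (PCG64, single precision — far below the model's
dynamical noise scale) and consumed in fixed order, making every run
bit-reproducible given its seed; the trajectory-recording and
online-labelling integrators consume identical draws, so both paths label
the same reversals. Halving dt changes noiseless trajectories by < 10⁻³ in
sup-norm (tested).

Dominance is labelled hysteretically: percept x becomes dominant at the
first step where rₓ ≥ 1.25·r_y (and rₓ > r_y, which settles the degenerate
all-zero start) and remains dominant until the opposite crossing. The
segment before the first crossing is "mixed"; the final interval of a run is
flagged incomplete. For simulated sequences, statistics drop the leading
mixed segment and the incomplete tail, mirroring the trimming applied to
human report blocks (`trim_block`, default: first 60 s of each block and the
final incomplete period are discarded; periods straddling the cutoff are
dropped whole rather than truncated, which would bias C_v downward).

## Regime classification

The noiseless regime at (I₀, β, φₐ) is read from a 600-s run with σₙ = 0,
τₐ = 1 s, from the asymmetric initial condition r₁ = a₁ = 0, r₂ = a₂ = 1
(the bracket notation of the protocol is ambiguous; assigning 0 to
population 1 is the reading adopted — by index symmetry the label is
unaffected). Operational criteria, in order: *stationary* if
|r₁ − r₂| < 10⁻³ throughout the final 60 s; *oscillatory* if the rank order
of r₁, r₂ reverses at least twice in the final 300 s; *bistable* if the
maximal state derivative over the final 60 s is below 10⁻⁵/s with rank order
preserved. Points meeting none of the criteria raise an error carrying the
trajectory tail; grid scans label them `unclassifiable` and exclude them
from the "possible" volume (none occur on the default grids). Checking
stationarity before oscillation makes slowly decaying symmetric
oscillations stationary, as they should be.

Along φₐ at (β = 1.75, I₀ = 0.5) the classifier yields
bistable → oscillatory → stationary, but the oscillatory/stationary
boundary lies at very large adaptation (φₐ ≈ 20, far outside the standard
grid): with a steep gain (k = 0.1) the symmetric fixed point keeps a large
loop gain at any moderate φₐ. The ordering test therefore sweeps φₐ far
beyond the grid range.

## Observables

From the complete, uniform dominance periods of a sequence: T_dom (mean),
C_v (sample-sd/mean), balance (dominance time of percept A over total).
Duration distributions are fitted by maximum likelihood — Gamma and
exponential anchored at zero, Gaussian free — and assessed with a KS test
against the fitted distribution (parameters estimated from the same data,
the field's customary, mildly anti-conservative usage).

Cumulative history: per block, S_x(t) = 1 while x dominates, 0.5 during
mixed intervals, 0 otherwise, integrated exactly across the
piecewise-constant record via H(t+Δ) = S + (H(t)−S)e^(−Δ/τ_H), with
H(0) = 0 at each block start (blocks are independent presentations). At
each complete period onset tᵢ, the pairs (H_x(tᵢ), ln Tᵢ) are pooled across
blocks; the mean of |Pearson r| over the four history/percept combinations
(H_A×T_A, H_B×T_B, H_A×T_B, H_B×T_A, equally weighted regardless of pair
counts) is scanned over 60 logarithmically spaced τ_H ∈ [0.01, 60] s; c_H
is the maximum and τ_H its argmax (ties toward smaller τ_H; a combination
with fewer than 10 pairs raises an error; degenerate zero-variance
correlations count as 0). Significance of c_H is assessed against a
permutation null: durations resampled with replacement (`shuffle_sequence`,
200 shuffles by default), which preserves the duration distribution and
alternation structure while destroying sequential dependence.

## Synthetic generators

The generators emulate the structure of human reversal reports so the
statistics pipeline can be validated with known ground truth:
`renewal_sequence` draws i.i.d. Gamma(shape, rate = shape/mean) durations in
strict alternation (defaults: mean 2 s, shape 4 — the Gamma-like regime of
human data; 12 blocks × 240 s, matching typical session lengths);
`history_coupled_sequence` modulates each Gamma draw multiplicatively by
exp(−b·(H_own − ½)) with H maintained at the generator's own time constant
(defaults b = 0 off / 2 when used in tests, τ = 3 s), so the log-duration
carries the stated negative dependence on own-percept history while the
b → 0 limit reduces *exactly* to the renewal process; centring H at ½ keeps
the mean duration interpretable. `inject_patchiness` inserts exponential
mixed interludes at reversals with a given probability, shifting onsets and
truncating at the original block end so total block time is conserved.

What the generators do not emulate: report latency and keypress errors,
lapses, eye-movement covariates, non-stationarity across a session. Tests
passing on synthetic data therefore validate the estimators, not the
psychophysics of real reports.

## Grid scans and matching

`evaluate_point` follows the two-stage protocol: three runs of 500 s; if the
across-run coefficient of variation of any of the four statistics exceeds
0.5 (or some but not all runs produced too few reversals to score), the
point is re-evaluated with five runs of 3000 s; statistics are averaged
across runs and durations pooled for the distribution fits. Points where no
run yields two dominance periods are flagged non-reversing and excluded
from matching. Seeds are derived per grid point and run from the root seed
via `SeedSequence`, so results are independent of iteration order.

A hidden combination (σₙ, τₐ) matches an observer when all four statistics
lie within 25% (inclusive) of the observer's values; a triplet matches when
any hidden combination does, and the best combination (minimal summed
relative deviation) is recorded. The matching fraction is reported relative
to the possible volume (bistable + oscillatory triplets). Distribution-shape
criteria are deliberately *not* part of observer matching. Matching is
monotone in the tolerance (tested).

Because a full scan is expensive on one CPU, `scan_grid` applies two screens
by default (both disabled with `prefilter_factor=None`, and both only
discard combinations far outside the match band): a single 250-s probe run
drops combinations whose mean dominance time deviates from the target by
more than 3× the tolerance (or that produce < 2 periods when a matching
point would produce dozens), and escalation to the long protocol is skipped
when the short-protocol T_dom or C_v already deviates by more than 1.5× the
tolerance. At desk scale the long protocol is typically reduced to
3 × 1500 s (the tests state the sizes they use).

The human-like-distribution volume uses the published group criteria: a
combination counts as human-like if the fitted Gamma shape lies in
[3.1, 4.3], the Gamma KS p-value exceeds 0.7, and the Gamma fit beats both
the exponential and the Gaussian; a triplet counts if any hidden combination
passes. Note that the KS p-value at several hundred to a few thousand
periods is a demanding criterion — the model's duration distribution is
Gamma-*like*, not exactly Gamma, so the passing fraction of the cube
depends strongly on how many hidden combinations are tried per triplet:
each combination is one more draw of (shape, p), and the "any combination
passes" fraction grows steeply with the size of the hidden grid. The
acceptance script computes the fraction with the reduced 4 × 4 hidden set
(≈ 11% of the possible volume at its default seed); a full 18 × 11 hidden
grid yields a several-fold larger fraction but is beyond desk scale.

## Resonance and the sweet spot

Sensitivity is probed at σₙ = 0.15, τₐ = 1 s: one unmodulated 4000-s run
gives the reference duration distribution and ⟨T_dom⟩; a second run
modulates the inputs in anti-phase, I₁,₂ = I₀ ± ΔI·cos(2πt/T_s), with
ΔI = 0.2·I₀ at the best resonance period T_s = 2⟨T_dom⟩. P₁ is the ratio of
the probability mass of dominance durations in the window
[⅔·HP, 3/2·HP] around the half-period HP = T_s/2, modulated over
unmodulated — a symmetric multiplicative band that captures the fundamental
resonance peak while excluding the 3·HP harmonic. Histograms retained for
diagnostics use bin width HP/20; P₁ itself is computed from the raw
durations and is robust to binning by construction. Fewer than 50 periods
in either run flags the point unreliable. Under fast modulation the
duration distribution shows peaks at odd multiples of the half-period
(reversals lock to an odd number of input half-cycles; tested).

Stability: mean unperturbed dominance time ≥ 1 s. Sensitivity: P₁ ≥ 1.2.
Both thresholds inclusive (the two available statements of the stability
threshold disagree on strictness; ≥ is adopted). The sweet spot is their
intersection; `overlap_fraction` reports what fraction of a matching volume
falls inside it.

## Clustering

Matching-volume centers (mean matched triplet vectors) are compared in
range-normalised coordinates — (I₀, β, φₐ) divided by (2, 2, 1) — so the
three axes weigh equally in the Euclidean distance (the raw axes span
unequal ranges; absolute distance units are therefore arbitrary but
p-values are invariant to any common rescaling, tested). Virtual observers
recombine one observer's (T_dom, C_v) with an independently drawn observer's
(c_H, τ_H), with replacement. The one-sided p-value is the fraction of
virtual-set group-mean pairwise distances at or below the real group mean.
At desk scale, virtual-observer centers must come from reduced grids and
shortened runs; the full analysis (thousands of sets on dense grids) is
cluster-scale.

## Problem sizes and determinism

Defaults follow the protocols above; the test suite and the acceptance
script scale some of them down and say so where they do (e.g. 9×9×9 instead
of 11×11×11 triplets, 3×1500 s instead of 5×3000 s long protocol, reduced
shuffle counts). All randomness flows from explicit seeds; identical seeds
give byte-identical sequences, evaluations and scan volumes.

## Known limitations

- Euler at dt = 1 ms is first-order; reversal times are quantised to the
  step. Both are far below the time scales of interest (τₐ ≥ 1 s).
- KS p-values use estimated parameters (anti-conservative); this matches
  standard practice for these observables but means the human-like
  criterion is not a calibrated hypothesis test.
- τ_H estimates from single 500-s runs are highly variable (the argmax of a
  shallow correlation curve); the matching protocol absorbs this through
  across-run averaging and escalation, but τ_H remains the noisiest of the
  four statistics.
- The empirical targets ship only as group summaries per display;
  per-observer matching volumes and the published clustering numbers cannot
  be recomputed from them.
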