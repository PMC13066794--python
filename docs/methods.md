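# Methods

## Data model

All analyses consume a `RecordingSession`: a unit list (projection neurons
or glomerular ROIs), trial records carrying per-unit spike times (seconds,
session clock) or sampled fluorescence segments, and odor metadata. Every
analysis window is a half-open interval `[start, end)` relative to an odor
event (onset or offset); a spike at exactly the right edge belongs to the
next bin, so bins partition a window with no double counting. Sessions are
stored as `session.yaml` (metadata + trial table) plus a long-format
`activity.csv`, with an HDF5 mirror for large trace sessions; spike times
round-trip at microsecond precision, traces at nine significant digits.

## Preprocessing

Spikes are counted in non-overlapping bins (50 ms for geometry, 200 ms for
time-course decoding, locust defaults); trace frames are block-averaged
(4 frames per bin by default at ~16 Hz). Windows not divisible by the bin
width are truncated to the last full bin, never padded, so bin widths stay
constant within a matrix. Raw fluorescence is converted to
dF/F = (F − F0)/F0 with F0 the per-trial mean over the 2 s pre-odor window,
then median-filtered (length 5, odd) to remove single-frame artifacts.

Responses entering angle and correlation computations are
**baseline-subtracted per unit** (mean activity per bin in the 2 s pre-odor
window of the same trials). This is what lets odor-evoked *suppression*
appear as a negative vector component; without it spike-count vectors are
non-negative and can never separate by more than 90°, yet suppression of the
ON ensemble after odor offset is exactly the substrate of the inverted
afterimage. Locust analysis windows default to 4 s ON / 4 s OFF and a
20–21 s ITI (both ITI readings are in circulation; each analysis states
which it uses and both are configurable). Mouse defaults: 5 s ON, 50 s ITI.

## Geometry

Correlation matrices are Pearson coefficients across units between
population vectors — time bin by time bin, or between trial- and
time-averaged period vectors. Zero-variance vectors yield *missing* (NaN)
entries excluded from summaries rather than a fabricated 0.

Angular separation is `arccos` of the cosine similarity, clamped to
[0°, 180°] against float overshoot. **Angle distributions default to
per-vector centering** (subtract each vector's mean across units before the
angle), which makes `cos θ` identical to the Pearson correlation and the
equivalence "r < 0 ⟺ θ > 90°" exact. The uncentered reading
(`centering="none"`) is kept as a knob: for sparse non-negative activity
patterns the uncentered cosine of two *independent* vectors has a positive
expectation (the overlap of their means), so independent ensembles would sit
at ~85° instead of 90° and the orthogonality reference would be biased. The
two-vector primitive `angle_between` stays uncentered.

For one odor with 80 ON and 80 OFF bins the three comparison groups contain
C(80,2) = 3160 ON-ON, 3160 OFF-OFF and 80×80 = 6400 ON-OFF angles. The
control distribution uses pairs of independent standard-normal vectors
(10 000 pairs by default, seeded): median 90°, spread shrinking ~1/√n_dims.

PCA projects observations (time bins, or per-trial ITI vectors) onto the
top eigenvectors of their covariance matrix; component signs are fixed by
forcing the largest-magnitude loading positive so orientations reproduce
across runs. Clustering is agglomerative with complete linkage on angular
distance (the merge criterion minimizes the furthest within-cluster pair);
dendrograms export as Newick.

## Inference

- Wilcoxon signed-rank vs. 90°, one-sided, exact null below n = 25 and
  zero differences discarded: eleven per-odor medians all above 90° give
  p = 2⁻¹¹ ≈ 4.9×10⁻⁴.
- Mann–Whitney U (one-sided, OFF-vs-reference > ON-vs-reference), exact
  when samples are tie-free and ≤ 25.
- Paired t-tests on solitary-minus-sequential correlation differences;
  sidedness is a per-comparison flag (default one-sided in the
  contrast-enhancement direction).
- Permutation p-values use the add-one convention
  p = (1 + #{null ≥ observed})/(1 + N): conservative, never zero,
  super-uniform under exchangeability.
- BH-FDR is the standard step-up at q = 0.05 (statsmodels backend,
  cross-checked in the tests against an independent step-up
  implementation).

## Decoding

The classifier is k-NN with **leave-one-trial-out** validation: for each
query vector the k nearest neighbors are drawn only from other trials, and
the predicted odor is the majority label, ties broken in favor of the tied
label holding the single nearest neighbor (deterministic). Distances:
`correlation` (1 − Pearson; invariant to per-vector affine rescaling) or
`angular` (degrees; invariant to positive scaling). Queries with undefined
distances (zero variance under correlation) are unclassifiable and count as
errors.

Time-course decoding pools every (trial, bin) vector in the window across
odors and trials — a locust-style 7 odors × 10 trials × 105 bins (21 s at
200 ms) gives 7350 vectors — and reports per-bin accuracy per odor and
overall. ITI-averaged decoding uses one time-averaged vector per trial
(k = 10 on angular distance by default; the mouse variant is documented
with k = 20 but note that with 10 trials per odor only 9 same-class
neighbors exist, so k > 2·9 lets a tightly clustered neighboring class
outvote the true one — on clean synthetic data smaller k is appropriate).

Significance: odor labels are permuted at the **trial** level (all bins of
a trial move together), per-bin one-sided permutation p-values are BH-FDR
corrected across bins, and the null mean and 2.5–97.5 percentile band are
stored. Under trial-level permutation with leave-one-trial-out the
per-neighbor probability of matching the query's label is (m−1)/(nm−1) for
m trials per each of n odors — slightly *below* 1/n because the query's own
trial is excluded while occupying one of its label's slots — so the null
mean sits a few percent below nominal chance at m = 10. The same depletion
affects observed accuracy when labels carry no information, so the
permutation test remains calibrated; "null ≈ chance" checks are made
against the spread of the null distribution, not its standard error.

Across-session summaries average accuracy in groups of five consecutive
time points and test each group against chance (1/n_odors; 9.1% for eleven
odors) with one-sided one-sample t-tests, BH-FDR corrected.

## Sequential contrast

For a reference odor R and context odors c with both solitary blocks and
sequential (c → R) blocks: `corr_solitary` = Pearson between the
trial- and time-averaged, baseline-subtracted ON vectors of solitary R and
solitary c; `corr_sequential` = the same with R-after-c in place of
solitary R. The second odor's ON window starts at its own onset (0.5 s
after the first odor's offset in the locust paradigm, 1 s in the mouse
paradigm) with the solitary ON duration; the sequential trial's baseline is
the pre-trial window before the *first* odor. A paired t-test over context
odors tests solitary > sequential.

## Synthetic sessions

The generator is phenomenological: it reproduces the population statistics
the analyses assume, not antennal-lobe or olfactory-bulb biophysics. Per
odor: a sparse non-negative ON pattern `a` (each odor mixes an odor-specific
pattern with one session-wide shared pattern, weight `shared_rho` = 0.4, so
different odors' ON responses are moderately correlated, as in real
panels); an OFF pattern `c = (1−γ)·g + γ·complement(a)` with `g` independent
and `complement` loading the units least driven by `a`; and an independent
hysteresis pattern. Unit rates are

    rate_u(t) = max(0, b_u
        + on_amp  · [a_u − γ·c_u]                 during odor
        + off_amp · [c_u − γ·a_u] · e^(−Δt/τ_off) after offset
        + h · h_u · e^(−Δt/τ_h))                  hysteresis

with the hysteresis state updated at each odor *offset* (h ← λ·h + η; it is
post-odor persistent activity, so accruing it at offset keeps it from
spuriously correlating the ON and OFF windows). `γ` (inversion strength) is
the single anticorrelation knob: the cross-suppression terms scale with it,
so γ = 0 gives independent ON/OFF ensembles with no suppression (pipeline
ON-OFF median ≈ 90°) and γ = 1 full inversion (≫ 90°); with unconditional
suppression the OFF vector would approximate −(ON vector) at *every* γ and
the knob would be inert. In sequential trials the first odor's post-offset
terms superpose on the second odor's ON response (the mechanism of contrast
enhancement); `sequential_carryover=False` disables exactly that term for
control runs.

Rendering: spikes are inhomogeneous Poisson via thinning (per-unit rate
bounds, vectorized, seeded); traces are the rate convolved with a
peak-normalized difference-of-exponentials kernel (rise 0.08 s, decay
0.5 s, GCaMP6f-like), scaled onto a per-ROI F0 (~100) with per-frame
Gaussian noise. One global seed fans out through independent substreams
(patterns, schedule, rate jitter, rendering), so components reproduce
independently.

Key parameters and defaults (all configurable): 66 units, baseline rate
Gamma-distributed with mean 6 Hz, on_amplitude 50, off_amplitude 25,
γ = 0.5 (locust-like preset; 0.8 mouse-like), τ_off 8 s locust-like / 10 s
mouse-like, hysteresis λ = 0.85, η = 1.5 Hz, τ_h = 120 s, rate jitter
0.5 Hz, trace noise 16 fluorescence units/frame in the mouse preset
(per-frame dF/F noise ~0.16, plausible for 15–18 Hz mesoscale imaging).
Paradigm timing: 4 s (locust) / 5 s (mouse) pulses, blocks of ten trials,
60 s / 55 s ITIs, 0.5 s / 1 s sequential gaps, 1 s pulses with 19 s ITIs in
the random-order paradigm. Inter-block gaps default to the physical 900 s:
the schedule is event-driven so long gaps cost nothing, and hysteresis
state genuinely depends on them (a short symbolic gap would leak one
block's odor-specific residue into the next block's ITIs). The decay
constants are free choices — no quantitative value is documented — fixed
once at values that realize the documented behavior (OFF activity decaying
over tens of seconds; single-presentation ITI information fading on a
~10–15 s scale).

Amplitudes and noise were fixed once so the generator realizes the
documented population statistics (ON-OFF medians around 105–125°,
within-period medians below 90°, ITI time-course decoding around 40%
against 14% chance) and the γ sweep stays strictly monotone: the measurable
suppression depth is capped by the baseline rate (rates clip at zero), so
baseline and off-amplitude are balanced to keep the knob informative up to
γ = 1.

### What the generator does and does not emulate

It emulates anticorrelated ON/OFF ensembles, OFF decay, odor-specific
accumulating hysteresis, sequential suppression and the three presentation
paradigms. It does **not** emulate: within-period temporal trajectory
structure (ON vectors differ across bins only through noise, so
within-period angle medians run tighter than in real data); respiration or
sniff coupling; cross-trial OFF remnants spanning record boundaries; or
mechanistic circuit dynamics. Two consequences worth knowing: (1) per-trial
dF/F normalization cancels DC components, so in the trace modality the
constant part of accumulated hysteresis is absorbed into F0 and full-ITI
persistence is carried by the ITI-averaged decoder and the within-ITI decay
structure rather than by late-ITI single bins; (2) hysteresis accumulates
linearly (λ, η), which caps the contrast between repeated and single
presentations at roughly the accumulation factor (~2×), so in the
random-order paradigm decodability *declines* with time since offset but
does not fall all the way to chance within the 17 s analyzed ITI. Passing
tests therefore certify the analysis machinery and the stated qualitative
recoveries, not quantitative agreement with any particular recording.

## Numerical choices

Cosines are clamped to [−1, 1] before `arccos`; correlation entries to
[−1, 1]. Neighbor ordering uses a stable argsort, so equal distances
resolve by pool index, deterministically. Degenerate inputs fail loudly:
zero vectors in angles, all-tied Wilcoxon inputs, zero-variance paired
differences (unless the difference is constant non-zero, which reports the
minimal attainable p), p-values outside (0, 1], k larger than the eligible
neighbor pool. Test problem sizes are scaled to the structure being tested
(e.g. 4–11 odors, 10 trials, ITIs trimmed to the analyzed window) so the
full suite and the acceptance script each run in well under a minute.

## Deposited-data adapter

The archived locust/mouse recordings are referenced by the analyses but
their on-disk layout is not machine-documented; `read_figshare_deposit` is
an explicit adapter hook that raises with guidance until a concrete reader
is written. The acceptance test for reproducing the published per-odor
median angles from those recordings therefore reports the missing input
rather than a number.
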