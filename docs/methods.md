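# Methods

`sedanet` re-implements, as a tested pipeline, an EEG analysis for
propofol-sedation studies: spectral connectivity networks built from the
debiased weighted phase lag index (dwPLI), surrogate-normalized
graph-theoretic summaries of those networks, signed slow–alpha
phase-amplitude coupling (PAC), and a binomial classification of
behavioural responsiveness. Because the human dataset such an analysis
targets is not publicly deposited, the package ships a synthetic-data
generator that emulates the study's structure; every estimator is validated
against ground truth it controls.

## Preprocessing

A continuous multichannel recording (microvolts, 250 Hz by default) is
band-passed 0.5–45 Hz with a zero-phase 4th-order Butterworth filter
(forward–backward, so PAC phase estimates incur no group delay), cut into
non-overlapping 10 s epochs, and each epoch×channel trace is baseline
corrected by its own mean. Noisy items are flagged on z-scored
log-variance: each channel's mean log-variance across epochs and each
epoch's mean across channels are z-scored against their population and
items with |z| > 3 are removed in a single pass and logged. Note that the
largest attainable |z| of one outlier among *n* items is (n−1)/√n, so with
fewer than ~11 items nothing can exceed the default threshold — the rule is
meant for realistic epoch counts. Rejected channels can be rebuilt by
spherical-spline interpolation (Perrin g-function, order m = 4, 7 Legendre
terms, ridge 1e-5 — standard values; exact on a constant field), and data
are finally re-referenced to the channel average. The stage order
(filter → epoch → baseline → reject → interpolate → re-reference) is fixed
in `preprocess.preprocess`.

A caveat that matters for small montages: average referencing mixes −1/C of
every channel into every other channel, so with very few channels (≲8) a
strong source leaks everywhere and produces spurious connectivity. Unit
tests on few-channel fixtures therefore stop before re-referencing; the
pipeline's defaults (≥32 channels) make the leakage negligible.

## Spectral power and dwPLI connectivity

Power spectra use Welch averaging on a 0.25 Hz grid (4 s Hamming segments,
50% overlap), with per-channel band power converted to percentage
contributions over five canonical bands: delta 0–4, theta 4–8, alpha 8–15,
beta 12–25, gamma 25–40 Hz (alpha/beta deliberately overlap, as printed in
the source literature this package follows).

Connectivity comes from a short-time Fourier decomposition with a
`round(fs/0.49)`-sample Hann window (510 samples at 250 Hz) hopped every
`round(0.04·fs)` samples, per-segment demeaned. With `I_j` the imaginary
cross-spectrum of epoch *j* at a fixed channel pair and time–frequency bin,

    dwPLI = [ (Σ I_j)² − Σ I_j² ] / [ (Σ |I_j|)² − Σ I_j² ],   0 when the denominator vanishes,

i.e. the expectation runs over epochs, after which the per-bin values are
averaged over time. The estimator ignores zero-lag (volume-conducted)
coupling, is invariant to per-channel amplitude scaling, and its debiasing
removes the positive small-sample bias — independent noise averages to 0
(small negative values are legitimate). Imaginary parts at the floating
rounding level of |cross-spectrum| are zeroed before accumulation:
proportional signals would otherwise feed pure FMA rounding noise to a
scale-free statistic. A band matrix takes, per pair, the in-band frequency
bin with the largest time-averaged dwPLI (ties toward the lower frequency);
`median_connectivity` is the median over the strict upper triangle.

## Graph analysis

Band matrices are proportionally thresholded at connection densities 10% to
50% in 2.5% steps (17 levels; round-half-up edge counts, ties in weight
broken by lexicographic pair order; weights kept, not binarized; negative
retained values floored at 0). Per density:

- **Clustering** (Onnela): c_i = Σ_{jh} (ŵ_ij ŵ_ih ŵ_jh)^{1/3} / (k_i(k_i−1))
  with ŵ = w/max(w); degree-<2 nodes get 0.
- **Characteristic path length**: Dijkstra on 1/w edge lengths, mean over
  reachable ordered pairs; unreachable pairs are excluded and counted, and a
  fragmentation warning is recorded.
- **Modularity**: Louvain on weighted modularity, repeated 50 times (default)
  with distinct seeds; Q is the mean over repetitions, the partition comes
  from the best repetition.
- **Participation**: P_i = 1 − Σ_m (k_im/k_i)² on weighted strengths against
  the best partition; the spread (population SD across nodes) summarizes hub
  presence.

A warning is recorded when average degree falls below 2·ln(N) (natural
log), the usual estimability floor. Each metric is normalized by its mean
over 50 (default) surrogates obtained by adding an independent uniform
random phase per channel × epoch to the time–frequency coefficients — a
null that preserves every amplitude spectrum and destroys cross-channel
phase relations. Small-worldness is normalized clustering divided by
normalized path length. Whether group comparisons should use a single
density or the density average is not settled; both are computed, and the
packaged summaries average over densities.

## Signed direct PAC

Slow (0.5–1.5 Hz) phase and alpha (8–15 Hz) envelope come from the analytic
signal after a zero-phase FIR band-pass. The FIR length is
max(3 cycles of the band's low edge, 2 s), capped at a third of the signal.
The 2 s floor matters: a 3-cycle alpha-band filter (0.375 s at 250 Hz) has
so wide a transition band that it attenuates the ±1–1.5 Hz AM sidebands
which *are* the coupling, biasing |PAC| low by ~7%; with the floor the
closed-form check below is met within 0.5%. With phase φ(t) and amplitude
a(t) over N samples, M = Σ a·e^{iφ} and

    PAC = sign × |M| / (√N · √(Σ a²)),   sign = +1 if |arg M| ≤ π/2 else −1,

so peak-max coupling (alpha maximal at the slow peak, phase 0) is positive
and trough-max (phase π) negative; |arg M| = π/2 ties break positive, and
M = 0 returns 0. For a(t) = 1 ± cos φ with uniform phase coverage the value
is ±1/(2√1.5) ≈ ±0.408 — the package's analytic anchor. Epoched data are
filtered per epoch, trimmed 1 s at each edge, and concatenated before
estimation; ROI values are arithmetic means over member channels. A single
channel's null PAC at ~400 s of data has a standard error near 0.02 (the
slow phase is heavily autocorrelated), so null checks use means over
several channels.

## Behaviour

Hit counts (40 two-choice trials per sedation level) get exact
Clopper–Pearson 95% intervals (conservative at n = 40, coverage ≥ 95%). A
participant is **drowsy** when the moderate-sedation interval lies strictly
below the baseline interval, otherwise **responsive**; the rule is monotone
in moderate hits. Reaction times are summarized by per-level medians. A
median split on any baseline network metric (ties and the odd-n median
participant to the lower half) feeds a Mann–Whitney comparison of
moderate-sedation hit rates.

## Group statistics

Measures are compared with a two-way mixed ANOVA (between: group; within:
sedation level) via `pingouin`, with Greenhouse–Geisser correction: the
within term's epsilon (∈ [1/(k−1), 1]) rescales the degrees of freedom of
both the within and interaction F tests (pingouin reports a corrected p
only for the within term; the interaction's is computed here from the same
epsilon). Pairwise group contrasts at a level use Tukey's HSD
(studentized-range). Brain–behaviour and PAC–drug associations use Huber
IRLS regression (tuning constant 1.345, tol 1e-8, ≤50 iterations) with R²
on the weighted fit; the slope statistic is referred to a t distribution
with n−2 degrees of freedom — at n = 20 the asymptotic normal reference is
anticonservative (~7% type-I instead of ~5%).

## Synthetic generator: what it emulates, and what it does not

`simulate_recording` builds each channel as unit-RMS 1/f^β Gaussian noise
(β = 1 default, slope verified by Welch fit), scaled to a nominal 10 μV RMS.
Alpha phase-coupling is injected per edge of a coupling graph: a narrowband
Gaussian source is added to both channels with a fixed π/2 phase offset —
dwPLI is insensitive near 0 and π lags, so the simulator defaults to the
lag it detects best, and a separate zero-lag shared component serves as a
volume-conduction stand-in for testing that insensitivity. Edges are tiled
over 1.5 Hz-wide sub-bands of the alpha band (centres cycling with the
channel-index sum): multiple sources incident on one channel would
otherwise mask each other's phase consistency, making per-edge dwPLI fall
with node degree and inverting intended group orderings; the tiling matches
what per-pair peak-frequency selection is designed to read out. PAC is
injected by multiplying a channel's alpha component by
(1 + s·depth·cos φ_slow), s = +1 peak-max / −1 trough-max.

`simulate_cohort` (defaults: 13 responsive + 7 drowsy, 40 trials/level,
drug targets 0.6/1.2/0.1 μg/ml for mild/moderate/recovery with lognormal
scatter of CV 0.25 so group distributions overlap, per-participant
coupling scatter CV 0.2) uses a two-module topology: two ring-lattice
modules (neighbour degree 4, weight 0.6) for occipital-like and
frontal-like alpha networks, with every 4th occipital node a connector hub
bridged to 4 nodes spread across the frontal module. Spreading each hub's
bridges prevents community detection from absorbing hub and targets into
one module, which would zero the hubs' participation. Group × level effects
multiply intra-module weight, thin intra-module edges (each surviving with
probability `intra_survival` — segregation is kept but local triangles
break), and attenuate bridges; the drowsy defaults at moderate sedation
(intra ×0.6, survival 0.5, bridges ×0.03) jointly produce the five expected
network effects relative to the responsive group — lower clustering, longer
paths, lower small-worldness, higher modularity, lower participation
spread. PAC depth per participant scales with the drawn concentration
relative to target (mode flipping to peak-max in the drowsy group at
moderate sedation), so estimated PAC tracks drug level across subjects.
Hit probabilities default to near-ceiling everywhere except the drowsy
group's moderate level (0.20), mirroring the behavioural collapse the
classifier must detect. Cohort effect sizes are free parameters of the
generator, chosen to realize the qualitative phenomena; they are not
estimates of any real cohort, and baseline inter-individual variability is
a single lognormal knob.

The generator does not model head geometry or forward solutions, spatially
correlated noise (beyond the optional shared zero-lag source), ocular or
muscular artifact waveforms (rejection tests inject high-variance segments
instead), pharmacokinetic time courses, or non-stationarity within a
recording. Passing tests therefore demonstrate estimator correctness and
end-to-end recovery of effects the generator encodes — not robustness to
every failure mode of real scalp EEG.

## Problem sizes and numerical choices

Default test-bed scale is 32 channels × 20 epochs × 10 s at 250 Hz per
recording, cohorts of 8–10 per group, 8–10 surrogates and 5 Louvain
repetitions over densities {0.10, 0.20, 0.30, 0.40, 0.50}; the acceptance
script uses the same scale. These sizes keep a full run on one CPU in
minutes while leaving the group effects detectable; all estimators are
exercised at full 91-channel scale only through their complexity-neutral
code paths. Degenerate inputs are handled explicitly: zero total band power
yields missing relative power, a vanishing dwPLI denominator yields 0,
edgeless graphs and all-flagged rejections raise, zero surrogate means emit
missing values with a warning, and constant ANOVA data return missing
statistics. Time–frequency coefficients are stored complex64 (memory),
promoted to complex128 for accumulation.
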