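# Methods

This note documents the models, numerical conventions, defaults, and
known limitations of `fuzzybci`, in the order the pipeline runs.

## Windowed band power and ERS″

Windows are defined in milliseconds and realized on the sample grid by
nearest-sample rounding: a 300 ms window at 256 Hz is 76.8 samples and
becomes 77; a 150 ms step becomes 38 samples (148.4 ms). Rounding keeps
latency semantics intact to within half a sample. Band power is the mean
one-sided periodogram density (rectangular window, no detrending, no
Welch sub-averaging — the windows, 64–77 samples, are too short to
subdivide) over the FFT bins with lo ≤ f < hi. The default band table is
θ [4, 8), α [8, 13), β [13, 18), high-β [18, 25), γ [25, 45) Hz; the
recording chain is assumed band-limited to 4–50 Hz, so no δ band is
defined.

ERS′ and ERS″ are first and second finite differences of the per-window
power, aligned to the latest window of their stencil (an ERS″ series is
two windows shorter than its power series). ERS″ is computed on **raw**
power density, not percent-of-baseline: the band-dependent artifact
cutoffs (150 units slow / 10 units fast) are only meaningful on the raw
1/f-scaled axis. Second differences use consecutive hops of the
overlapping window grid (not disjoint window triplets); with 50 %
overlap, consecutive power values share half their data, which smooths
the series without changing the burst latency of one step.

The workload score is log₁₀(Σβ / Σ(θ+α)); the logarithm base is a
convention (configurable) chosen so score magnitudes are comparable
across montages. The valence index is αF4/βF4 − αF3/βF3, the
right-minus-left frontal α/β contrast; a commonly printed rendition of
this formula repeats the F4 term twice and is identically zero, so the
corrected contrast is implemented and the defect noted in the docstring.

### Locating a burst from ERS″

For a pulse-like burst of duration D below the window length W, the
windowed power traces out a smooth bump and |ERS″| peaks where the
*middle* stencil window covers the bump plateau — not at the onset
window. The plateau center sits `step − (W−D)/2` after the onset, so
`locate_burst_onset` takes the most negative ERS″ window and inverts
that offset. The estimator is unbiased for isolated bursts and resolves
to one window step. For a *sustained* power step, by contrast, the ERS″
peak equals the step height at the first window containing the step
(tested directly on power series).

## Trapezoidal calibration

Sets are built from baseline statistics exactly as stated in the README.
Numerical decisions:

- membership is core-closed and support-open (μ(b)=μ(c)=1; μ(a)=0 when
  a<b); vertical legs step at the breakpoint, closed on the core side —
  this makes the artifact cutoff at m+3c₃s unambiguous;
- a zero baseline standard deviation (flat synthetic baselines) is
  floored at 1e−6·max(|m|, 1) instead of raising, so degenerate fixtures
  still calibrate;
- baselines that are not exactly 100 windows warn but proceed;
- the `desync` set has no canonical formula; it is the mirror of
  low∪high below the mean, (m−3c₃s, m−3c₃s, m−c₃s, m−s) with a vertical
  left leg, for symmetric treatment of desynchronization;
- an optional one-sided `artifact` set covers (m+3c₃s, ∞) so that
  rule bases can classify the excluded region explicitly.

## Digital-twin cost and GA

The per-window cost E is the two-rule zero-order TSK system given in the
README; E is defined as 1 where both rule memberships vanish ("outside
the modelled region is maximal error" — the weighted average is
undefined there). E ∈ [0, 1] always. The fitness of a coefficient set is
the mean of E over the replayed trace; a trace must have ≥ 5 windows.

The GA operators are this package's design, chosen for small-population
robustness: truncation/rank selection of the top 20 of
40, uniform crossover, Gaussian mutation (σ = 0.6 gene units) clipped to
the gene bounds, repair by sorting the genes to enforce c₁ ≤ c₂ ≤ c₃,
elitism 1, and 10 generations by default. Everything is driven by one
seeded NumPy generator, so runs are bit-reproducible. When tuning is
restricted to a gene subset (e.g. `genes=("c3",)` for active-mode
refinement of a condition variable), the free genes are projected onto
the ordering cone without moving the fixed ones.

**Gene bounds.** Defaults are c₁ ∈ [1, 12], c₂ ∈ [1, 14], c₃ ∈ [1, 16].
The wide upper bounds are deliberate: the ref core is pinned at m ± s,
so on a trace whose spread matches the calibration standard deviation
(e.g. a standard-normal synthetic baseline) roughly a third of the
probability mass falls on the trapezoid legs, where the cost is
(|x|−s)/((c₁−1)s); the mean cost can only approach zero if c₁ can grow
well past the hand-tuned 1.2. On real recordings, where the reference
phase's std estimate typically exceeds the clean baseline spread, the
optimum lands near the hand-tuned values; the optimizer logs the result
against that experience range as a plausibility check, not an assertion.
Each variable gets an independent GA/digital-twin pair (a plain loop —
no state is shared between variables).

## RGRC training

The RGRC recipe fixes the ingredients (granules from data,
strength- and error-aware ranking, sparse-sample retention, single-winner
voting, ≤ 15 iterations) but not the step-by-step algorithm; the
concrete procedure here is this package's definition:

1. **Granulate**: one granule per class at the class feature means;
   per-feature left/right σ are RMS deviations of the below-/above-mean
   samples, floored at 1e−6 of the feature range. Membership is the
   product over features of two-sided Gaussians; a sample is governed by
   its argmax-membership granule (ties to the lower index).
2. **Consolidate**, up to 15 iterations: (i) split the rule with the
   largest misclassified-governed count at the error centroid (new
   granule fitted to the majority-true-label errors); (ii) for each
   misclassified sample, try re-assigning it to the best granule of its
   true class and refit both granules; (iii) re-rank by (support,
   error), dropping unsupported rules. Every move — split, transfer,
   drop — is kept only if the global single-winner training error does
   not increase, which makes the error trajectory non-increasing by
   construction (asserted at run time). A rule governing a single
   isolated sample survives whenever removing it would increase the
   error: isolated bursts are treated as signal, not outliers.
3. Stop at the first iteration with no accepted transfer
   ("consolidation stabilization").

Training is deterministic given the data order; the config seed is
reserved for callers that shuffle.

## Synthetic EEG

Each electrode is a sum of band-limited sinusoids plus white noise
(default σ = 2 µV). Tones sit on a 4 Hz grid — the FFT-bin spacing of
the canonical 250 ms window — with seeded random phases and amplitudes
normalized so each band's total power is amp²/2. On-bin tones make the
baseline band power *window-stationary* with an exact analytic
expectation; dense off-grid combs were rejected because a 250 ms window
resolves only one spectral mode in the θ band, making narrowband power
fluctuate with CV > 0.5 — indistinguishable from bursts at trial scale.
Default band amplitudes (θ 8, α 10, β 4, high-β 3.5, γ 3 µV) put
fast-band baseline density near 1 µV²/Hz so the 10-unit artifact cutoff
sits well above genuine burst responses.

Bursts multiply the target band's envelope by `gain` with 40 ms
raised-cosine ramps. Ramps at 20 ms were rejected: their modulation
sidebands exceed the (clean) baseline variability of non-adjacent bands.
Even so, any amplitude-modulated burst of duration D carries ≈ 1/D
(~5 Hz) of sideband width, so the *directly adjacent* band always sees
some leakage — an inherent property of band-limited burst models, and
the reason the cross-talk test exempts adjacent bands. Artifacts are
Gaussian-envelope broadband voltage spikes on one electrode.

The labelled three-condition dataset (default 300 trials of 1.25 s over
a six-electrode focused montage) assigns distinct burst signatures:
condition 1 — temporal θ+γ (gain 3.5); condition 2 — parietal
high-β/γ plus frontal θ, stronger (gain 4.0); condition 3 — parietal γ
only (gain 3.5); onset jittered in 400–700 ms, duration 150–250 ms, gain
jitter ±10 %. Trials are summarized for training by each variable's
positive ERS″ peak. These signatures are test fixtures emulating
well-separated attentional conditions; they are not claimed to
reproduce any physiology, and passing tests on them demonstrates the
algorithms, not real-data performance.

## What the synthetic tests do and do not show

Passing the pipeline on this generator shows: the feature algebra is
exact; calibration, inference, GA, and RGRC behave as specified under
controlled signal-to-noise; burst latency is recoverable when the burst
band offers enough time–bandwidth product. It does **not** show
robustness to 1/f backgrounds, volume conduction, blink morphology,
non-stationary baselines, or subject variability. In particular,
single-trial latency recovery in narrow slow bands (θ, α) is *unreliable
in principle* at 250–300 ms windows — their windowed power has one
spectral mode and hence CV near 1 for any stationary stochastic rhythm —
which is why the latency fixture uses γ bursts (time–bandwidth ≈ 5).

## Problem sizes and runtimes

Defaults were sized for a desk-scale run: GA convergence statistics use
20 seeds × (40 chromosomes × 10 generations × 60-window traces);
classifier statistics use 20 seeds × 300 trials; latency recovery uses
100 single-electrode 2 s simulations. The full test suite runs in about
half a minute; `scripts/acceptance.py` in about 25 s on one CPU.

## Known limitations

- The rule DSL covers conjunctive antecedents only (the conventional rule
  grammar); disjunction is expressed as multiple rules.
- First-order (linear-consequent) TSK rules are supported by the engine
  but unexercised by the calibration path, which is zero-order.
- Vote vectors treat classes absent from a rule's vote map as 0 support.
- `grand_average` aligns participants by window index; it does not
  time-warp across participants with different window configs.
- The consolidation transfer move only shifts samples *toward* granules
  of their own class; it cannot merge two same-class granules (merging
  falls out of the zero-support drop rule instead).
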