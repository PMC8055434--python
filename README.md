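# fuzzybci

A fuzzy Takagi–Sugeno (TSK) shell for EEG burst-feature brain–computer
interfaces. The package is for BCI researchers and engineers who want
*interpretable* decoding of oscillatory EEG: every feature is a named
linguistic variable, every decision traces back to a human-readable
IF–THEN rule, and every tunable constant has a physical meaning.

## The model

**Burst features.** Raw multichannel EEG (µV, nominally 256 Hz) is cut
into sliding windows (250 ms / 125 ms step for β, high-β and γ; 300 ms /
150 ms for θ and α) and converted per window to band power density
(µV²/Hz) by a rectangular-window periodogram. The burst feature ERS″
(ERD″ for the negative case) is the second finite difference of the
windowed power,

    ERS″[k] = p[k] − 2·p[k−1] + p[k−2],

the "rate of change of the change" of event-related
synchronization/desynchronization. A short power burst produces a large
|ERS″| with a latency of one window step. Variables are named
`{electrode}_{band}_{feature}_{window}`, e.g. `P8_T_ERS2_300` — a
θ-band burst over right-parietal P8 on 300 ms windows.

**Fuzzy sets from the baseline phase.** During a passive-view reference
phase each variable's mean *m* and standard deviation *s* (conventionally
over 100 windows) define trapezoidal fuzzy sets scaled by coefficients
1 ≤ c₁ ≤ c₂ ≤ c₃ (defaults 1.2, 1.4, 2):

    ref    = (m−c₁s, m−s, m+s, m+c₁s)
    low    = (m+s, m+c₁s, m+c₂s, m+c₃s)
    high   = (m+c₂s, m+c₃s, m+3c₃s, m+3c₃s)   ← vertical right leg
    desync = (m−3c₃s, m−3c₃s, m−c₃s, m−s)

The vertical leg of `high` excludes artifact-scale bursts from
evaluation; crisp artifact thresholds (|ERS″| > 150 units for slow
bands, > 10 for fast bands) flag windows online.

**Zero-order TSK inference.** A rule `IF x₁ is A₁ AND … THEN y` fires
with strength μ = T(μ_A1(x₁), …) (product or min t-norm) and the crisp
output is the strength-weighted average y(x) = Σμᵢyᵢ / Σμᵢ.
Classification uses label or vote-vector consequents with single-winner
aggregation; "no rule fired" is an explicit outcome, never a silent 0.

**Digital-twin GA calibration.** The coefficients c₁–c₃ are tuned by a
genetic algorithm (population 40, 20 mating parents, 3 genes, 10
generations) whose fitness replays recorded feature windows through a
two-rule TSK cost: in baseline mode
E(x) = (μ_ref(1−μ_ref) + μ_low²) / (μ_ref + μ_low), which is 0 when x
behaves like baseline and 1 when it is firmly "low".

**RGRC classifier.** Supervised training by rule granulation (one
two-sided-Gaussian granule per class) and rule consolidation
(split/transfer/re-rank moves accepted only if the global single-winner
error does not increase, with sparse single-sample rules retained when
dropping them would hurt) — stopping at "no accepted transfers".

No recordings ship with the package; a seeded synthetic EEG generator
(band-limited tones + white noise, condition-locked bursts, artifact
spikes) exercises the whole chain.

## Worked example

Simulate a recording with a mild α burst on O2 at 6 s, calibrate from
the first 40 baseline windows, and classify windows with two rules:

```python
import numpy as np
from fuzzybci import (
    SimConfig, BurstEvent, generate_raw, WindowConfig,
    band_power_series, burst_features, baseline_stats,
    CoefficientSet, build_variable, RuleBase, classify,
)
from fuzzybci.rules import parse_rule

sim = SimConfig(
    duration_ms=8000.0, electrodes=("O2", "P8"),
    bursts=[BurstEvent("O2", "A", onset_ms=6000.0, duration_ms=250.0, gain=1.25)],
    seed=42,
)
raw = generate_raw(sim)
feats = burst_features(band_power_series(raw, sim.bands, WindowConfig(250, 125)))

var = "O2_A_ERS2_250"
stats = baseline_stats(feats.values[var][:40])
lv = build_variable(var, stats, CoefficientSet(1.2, 1.4, 2.0), artifact_threshold=150.0)
rb = RuleBase(
    rules=[
        parse_rule(f"IF {var} is ref THEN label 1"),
        parse_rule(f"IF {var} is high THEN label 2"),
    ],
    variables={var: lv},
)
for k in range(44, 50):
    x = float(feats.values[var][k])
    res = classify(rb, {var: x})
    lab = res.label if res.fired else "no decision"
    print(f"window ending {feats.window_end_ms[var][k]:7.1f} ms: ERS2 = {x:7.2f} -> {lab}")
```

prints

```
window ending  6000.0 ms: ERS2 =   -0.26 -> 1
window ending  6125.0 ms: ERS2 =    2.76 -> 2
window ending  6250.0 ms: ERS2 =   -2.16 -> no decision
window ending  6375.0 ms: ERS2 =   -3.34 -> no decision
window ending  6500.0 ms: ERS2 =    2.25 -> 2
window ending  6625.0 ms: ERS2 =    0.08 -> 1
```

Reading it: the window at 6125 ms catches the
burst's rising edge one step after onset and lands in the `high` set
(label 2, "burst"); the following windows hold the burst's negative
second-difference lobe, which these two rules do not cover — reported
honestly as *no decision*, not guessed; by 6625 ms the variable is back
in `ref` (label 1, baseline). Calibration printed
`m=0.014, std=0.973` from the baseline windows, so the `high` core spans
ERS″ ≈ 2.0–5.9 µV²/Hz.

The same chain is scriptable from the shell:

```bash
fuzzybci simulate --duration-ms 8000 --electrodes O2,P8 \
    --burst O2:A:6000:250:1.25 --seed 42 --out raw.csv
fuzzybci features  --raw raw.csv --out features.csv
fuzzybci calibrate --features features.csv --baseline-windows 40 --out membership.json
fuzzybci optimize  --membership membership.json --features features.csv --seed 1
fuzzybci infer     --membership membership.json --features features.csv --out decisions.csv
```

`fuzzybci train --synthetic 300 --seed 0 --out model.json` trains the
RGRC classifier on the three-condition synthetic dataset and reports
training and held-out accuracy; `fuzzybci analyze` grand-averages
feature files or runs Bonferroni-corrected paired t tests.

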