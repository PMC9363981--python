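# misinoc

An agent-based model of misinformation spread and psychological inoculation
in online social networks.

Misinformation interventions based on inoculation theory ("prebunking")
demonstrably help individuals recognise manipulative content, but whether
individual-level protection scales to population-level *herd immunity* is a
systems question: beliefs spread through search and re-sharing, networks
prune themselves into echo chambers, and the protection itself decays and
diffuses. `misinoc` simulates this system — a population of Bayesian
belief-updating citizens exposed to honest and biased broadcasters — so the
interplay of training coverage, timing, decay and peer transmission can be
studied at scale. It is aimed at computational social scientists and
infodemiology researchers who want a reproducible, scriptable simulator of
these dynamics.

## The model

Each of N = 1000 citizens holds a belief about a scalar state of the world
(ground truth 0.5) represented non-parametrically: the last five
information items received, each replicated in an implicit multiset

    frequency_i = position_i² × round(SC_weight_i),        position ∈ 1..5

so recency weighs quadratically (newest = 25× oldest) and credibility
weighs via `SC_weight = rel_height × 100 × (CredInf × 2)` with CredInf =
0.3. The citizen's belief µ_own and spread σ_own are the mean and SD of
that multiset. Incoming information at value x has relative credibility

    cred(x) = exp(−(x − µ_own)² / 2σ_own²) + bonus

(bonus = 0.3 only when a broadcaster is the source) and is dismissed below
the 0.5 cut-off. Surviving messages face a misinformation-cue check: every
communication carries a cue in [0, 1] drawn from a truncated normal whose
mean is the sender's perceived deviation from audience belief, and a
message is rejected as misinformation when `1 − cue ≤ s`, with `s` drawn
around the citizen's current cue sensitivity. Accepted information enters
the rolling history; confidence P(H|E) updates by Bayes' rule with the
relative credibility acting as the amalgamated trust-and-expertise input.
Inoculation training adds 0.3 to cue sensitivity, holds for two rounds,
decays linearly, and spreads to peers with probability
`0.05 × MCS_own / 0.3` per round.

A 25-round simulation crosses three manipulations: training regime (none /
upfront 60% / staggered 3×20%), broadcaster condition (honest 0.5 / biased
0.75 / competing), and baseline cue sensitivity (0.05 / 0.2 / 0.35). Six
dependent variables are recorded per round: belief quantiles, mean local
network purity, accepted communications, correct vs false-positive cue
rejections, percent ever trained, mean sensitivity and mean confidence.

## Worked example

```python
from misinoc import ScenarioConfig, run_simulation

config = ScenarioConfig(
    n_citizens=300, rounds=25,
    training_regime="upfront",
    broadcaster_condition="biased",
    base_mcs_level="medium",
    seed=11,
)
result = run_simulation(config)
print(result.metrics_frame()[["round", "median", "q10", "mean_current_mcs",
                              "mean_confidence"]].tail(3).to_string(index=False))
```

```
 round  median   q10  mean_current_mcs  mean_confidence
    23    0.75 0.355             0.347            0.986
    24    0.75 0.355             0.342            0.986
    25    0.75 0.355             0.339            0.987
```

By round 25 the biased broadcaster has captured the majority (median belief
0.75) while a resister echo chamber — visible as the 10th-percentile band
holding well below 0.75 — stays organised around values near the 0.5 ground
truth. Mean cue sensitivity sits at 0.34, above the untrained 0.2 baseline,
because peer-to-peer sharing of the training offsets its decay; mean
confidence near 0.99 shows beliefs have consolidated whatever their
content. See `examples/` for scripts covering each capability, and the CLI
(`misinoc simulate`, `misinoc grid`) for shell use.

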