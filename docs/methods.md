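# Methods

## Model overview

The simulator couples three processes on a fully searchable social network
of citizens: (i) individual cognition — a frequency-weighted empirical
belief distribution with a source-credibility overlay and a Bayesian
confidence update; (ii) information flow — broadcasters that reach everyone
and citizen posts found through recency-ordered search, both gated by a
two-stage evaluation (credibility, then misinformation-cue detection); and
(iii) inoculation — an additive, decaying boost to cue-detection
sensitivity delivered by external campaigns and by peer transmission.
Links are undirected, created on acceptance of a found post and severed by
pruning, so network structure is emergent rather than assumed.

Each round executes, in order: inoculation (peer sharing by citizens
trained in earlier rounds → decay/aging → external campaign), broadcasting
(evaluation, belief and confidence update, share decision by accepters),
search by everyone who did not accept a broadcast (same evaluation and
update pipeline; a failed search triggers the no-information update), and
pruning by all citizens below the 0.999 confidence cut-off. The run stops
at 25 rounds or when every citizen is settled.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| prior mean / SD | 0.5 / 0.25 | truncated-normal parent of the 5 initial belief samples |
| initial credibility weight | 5 | constant weight of initial history items |
| temporal exponent | 2 | recency weighting position² |
| CredInf | 0.3 | converts relative credibility to weight (×100×2·CredInf) |
| credibility cut-off | 0.5 | minimum relative credibility to pass |
| broadcaster bonus | +0.3 | content-independent credibility of broadcasters |
| halo | 1 | multiplier on σ in the credibility overlay |
| cue SD | 0.2 | spread of generated cue values |
| detection SD | 0.25 | spread of the detection threshold draw |
| α_citizen | 0.2 | citizens' cue-deployment proclivity (broadcasters: 1) |
| inoculation effect | 0.3 | additive sensitivity boost |
| hold / decay | 2 rounds / 0.15 per round | boost duration, then linear decay |
| peer share probability | 0.05 × MCS/effect | per-round training transmission |
| false-positive band | ±0.05 | window around truth 0.5 for misclassified rejections |
| initial confidence | 0.05 | common prior P(H|E) |

Two figures for the decay rate circulate in the source literature for this
model class (0.075 and 0.15 per round); both are supported through
`InoculationParams.decay_rate`, with 0.15 as the default. Baseline
sensitivity levels are drawn per citizen from truncated normals with SD
0.05 around 0.05 / 0.2 / 0.35.

## Design choices where the design was open

- **Dynamic credibility weights.** At every belief update the weights of
  all retained history items are recomputed from the pre-update overlay
  (the incoming item uses the credibility calculated for this round,
  including any broadcaster bonus; recomputation of old items uses no
  bonus). This makes a coherent history resilient — a single deviant
  arrival contributes ~45% of the expanded mass rather than ~90% as it
  would against stale initialization weights — and is what lets resister
  echo chambers survive a persistent biased broadcaster.
- **Bonus scope.** The broadcaster bonus applies only when the broadcaster
  itself is the source. Re-shared broadcasts carry the bonus field verbatim
  in the post, but peer evaluation and pruning use no bonus.
- **Search probability.** P(search) = 1 − confidence, the simplest
  monotone map consistent with the 0.999 activity cut-off; settled citizens
  never search.
- **No-information update.** Only a search actually conducted and failed
  triggers it: the extreme pair (0.01, 0.999) enters the two newest history
  slots at the minimal weight, and the confidence update runs with
  credibility 0.01. Citizens who skip search make no update that round.
- **Post persistence.** A citizen's post stays publicly visible until
  replaced; declining to share leaves the old post standing. Search scans
  declarations newest-first by a global sequence counter.
- **Broadcast phasing.** A lone broadcaster is active on every round not
  divisible by three; under competition the honest broadcaster takes
  rounds ≡ 1 (mod 3), the biased one rounds ≡ 2, with every third round
  peer-only.
- **Numerical floors.** σ is floored at 1e-3 in credibility evaluation
  only (a collapsed belief still accepts its peak); expansion frequencies
  are `round(weight)` floored at 1; the credibility input to the Bayes
  update is clamped to [0, 1] since the bonus can push relative credibility
  above 1.
- **Iteration order** within each phase is a fresh seeded permutation, so
  citizen ids carry no processing advantage. Replicate seeds derive from
  the master seed through `SeedSequence(master, spawn_key=(index,))`, and
  all truncated-normal draws use the inverse-CDF transform, making runs
  bit-reproducible from (config, seed).
- **Peerless citizens** are excluded from mean purity rather than assigned
  perfect agreement, so early rounds (no links yet) do not fake an echo
  chamber.

## What the simulation does and does not emulate

The generator's defaults are the study conditions themselves: population
1000 (scaled to 300 in the replication tests), 25 rounds, the 3×3×3
manipulation grid, and all parameter values above. What it does not
emulate: real message semantics (cues are a single scalar), wilful
disinformation from citizens (only broadcasters can be biased), bounded or
spatial search (positions are stored but search is network-wide),
heterogeneous broadcaster credibility, or resistance to being trained.
Passing tests therefore speak to the internal logic of the
inoculation-in-networks mechanism, not to the behaviour of any empirical
platform population.

## Emergent behaviour worth knowing about

Acceptance is one-sided and self-reinforcing: citizens who find the biased
broadcaster credible converge on its value within a few accepted
broadcasts, while citizens who reject it on credibility grounds
consolidate with one another and become permanently immune as their σ
shrinks below the pass window. Outcomes are therefore governed largely by
the initial credibility-pass fraction (~60% under the default biased
scenario) plus the cue rejections accumulated in the first two rounds —
which is where training matters. Whether the *median* citizen resists is a
tipping phenomenon: it flips only in replicates where the resister
subpopulation crosses half the population, so median-based contrasts
between training regimes are noisy at small replicate counts.

A second consequence: under competing broadcasters the population
consolidates tightly around the truth, biased content then fails at the
credibility stage (so it stops generating *cue* rejections), while honest
broadcasts keep passing at the distribution peak and absorb the cue checks
— and because cue draws are truncated at zero, even zero-deviation
communications carry a mean cue near 0.16. Cue-based rejections in that
condition are therefore dominated by false positives on truthful content,
unlike the lone-biased-broadcaster condition where correct rejections
dominate by an order of magnitude.

## Problem sizes used in tests

Unit and property tests run on single states or populations of ≤ 200;
Monte-Carlo checks use 10⁴–10⁵ draws against scipy truncated-normal
moments; the replication tests use 300 citizens × 20 replicates × 6
conditions with counter-derived seeds from a fixed master seed.
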