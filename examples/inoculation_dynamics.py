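"""Population-level inoculation dynamics: boost, decay and peer spread.

Runs a small scenario with an upfront 60% campaign against a biased
broadcaster and prints the mean misinformation-cue sensitivity per round:
the initial boost, the decay dip, and the recovery as trained citizens
share the training with their peers.
"""

from misinoc import ScenarioConfig, run_simulation

config = ScenarioConfig(
    n_citizens=200,
    rounds=25,
    training_regime="upfront",
    broadcaster_condition="biased",
    base_mcs_level="medium",
    seed=7,
)
result = run_simulation(config)

print("round  %trained  mean sensitivity")
for m in result.metrics:
    bar = "#" * int(m.mean_current_mcs * 60)
    print(f"{m.round:5d}  {m.pct_ever_trained:7.1f}%  {m.mean_current_mcs:.3f} {bar}")

print("\nThe 60% campaign lifts mean sensitivity from the 0.2 baseline toward 0.38,")
print("decay pulls it back within a few rounds, and peer-to-peer sharing of the")
print("training gradually rebuilds it toward a trained equilibrium.")
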