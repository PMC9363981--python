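"""A scaled-down manipulation grid: training regime x broadcaster condition.

Runs 2 replicates per cell at n=150 and prints the replicate-averaged final
round of each condition, showing how training changes the end state against
a biased broadcaster but not against an honest one.
"""

from misinoc import ScenarioConfig, run_grid

base = ScenarioConfig(n_citizens=150, rounds=25, seed=5)
per_round, aggregate = run_grid(
    base,
    training_regimes=("none", "upfront"),
    broadcaster_conditions=("honest", "biased"),
    base_mcs_levels=("medium",),
    replicates=2,
    master_seed=5,
)

final = aggregate[aggregate["round"] == aggregate["round"].max()]
cols = ["training_regime", "broadcaster_condition", "median",
        "mean_current_mcs", "mean_confidence", "n_correct_rejections"]
print(final[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))

print("\nHonest cells converge on the 0.5 ground truth regardless of training;")
print("in biased cells the median is pulled toward 0.75, and training raises")
print("both the final cue sensitivity and the volume of correct rejections.")
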