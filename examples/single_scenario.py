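"""One full scenario run with all six dependent variables printed per round.

A biased broadcaster (communicating 0.75 against a ground truth of 0.5)
faces a population with medium baseline cue sensitivity and an upfront
inoculation campaign.
"""

from misinoc import ScenarioConfig, run_simulation

config = ScenarioConfig(
    n_citizens=300,
    rounds=25,
    training_regime="upfront",
    broadcaster_condition="biased",
    base_mcs_level="medium",
    seed=11,
)
result = run_simulation(config)
frame = result.metrics_frame()

cols = ["round", "median", "q10", "q90", "mean_purity", "n_communications",
        "n_correct_rejections", "n_false_positives", "mean_current_mcs",
        "mean_confidence"]
print(frame[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))

last = result.metrics[-1]
print(f"\nAfter {result.final_round} rounds the median belief is {last.median:.3f}.")
print("The 10th percentile shows the resister echo chamber holding near the 0.5")
print("ground truth while the captured majority consolidates on the broadcaster's")
print("0.75; correct rejections dwarf false positives, and mean purity near 1")
print("reflects links surviving only between like-minded citizens.")
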