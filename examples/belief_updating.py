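"""How a citizen's frequency-weighted belief reacts to incoming information.

Builds one citizen's initial belief state, pushes a deviant but credible
value, then simulates a failed search, printing the belief mean, spread and
confidence after each step.
"""

import numpy as np

from misinoc import (
    initialize_belief,
    item_frequency,
    push_information,
    push_no_information,
    relative_credibility,
    update_confidence,
)

rng = np.random.default_rng(42)
state = initialize_belief(rng)

print("initial history (value, expansion frequency):")
for item in state.history:
    print(f"  position {item.position}: value={item.value:.3f} freq={item_frequency(item)}")
print(f"belief mu={state.mu_own:.4f} sigma={state.sigma_own:.4f} confidence={state.confidence:.3f}")

# a message one standard deviation above the current belief
value = state.mu_own + state.sigma_own
rel = relative_credibility(value, state)
print(f"\nincoming value {value:.3f}: relative credibility {rel:.3f} (exp(-1/2))")

push_information(state, value, rel)
state.confidence = update_confidence(state.confidence, rel)
print(f"after accepting it: mu={state.mu_own:.4f} sigma={state.sigma_own:.4f} "
      f"confidence={state.confidence:.3f}")
print("the belief moved toward the message; credibility > 0.5 raised confidence")

# repeated coherent input concentrates the belief ...
for _ in range(5):
    rel = relative_credibility(state.mu_own, state)
    push_information(state, state.mu_own, rel)
    state.confidence = update_confidence(state.confidence, rel)
print(f"\nafter five confirmations: mu={state.mu_own:.4f} sigma={state.sigma_own:.4f} "
      f"confidence={state.confidence:.3f}")

# ... and a failed search widens it again
push_no_information(state)
state.confidence = update_confidence(state.confidence, 0.01)
print(f"after a failed search:    mu={state.mu_own:.4f} sigma={state.sigma_own:.4f} "
      f"confidence={state.confidence:.3f}")
print("the extreme placeholder pair widened the distribution and confidence dropped")
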