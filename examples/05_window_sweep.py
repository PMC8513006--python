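"""How window length affects recognition accuracy.

Re-runs extraction and the nested protocol per window length. Short windows
give more training examples but less context per decision; for face-touch
detection the useful lengths are short (a touch lasts a few seconds) and
short windows also mean faster on-device feedback.
"""

from facetouch import (BINARY, ModelSpec, SimulationConfig, align_and_trim,
                       simulate_dataset, window_sweep)

cfg = SimulationConfig(n_participants=7, activity_duration=60.0, seed=42)
recordings, logs = simulate_dataset(cfg)
segments = []
for rec, log in zip(recordings, logs):
    segments.extend(align_and_trim(rec, log))

specs = [ModelSpec("logistic_regression", ({"C": 1.0},)),
         ModelSpec("decision_tree", ({"max_depth": 10},))]
table = window_sweep(segments, lengths=[2, 5, 10], task=BINARY,
                     model_specs=specs, sampling_rate=30.0, plan_seed=42)

print("mean outer-fold accuracy by window length (s):\n")
print(table.round(3).to_string())
print("\nbest length per family:")
print(table.idxmax().to_string())
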