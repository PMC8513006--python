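"""10-class activity recognition: pooled confusion and feature importances.

A random forest distinguishes the ten activities; the pooled confusion
matrix shows which tasks trade probability mass. The moving-items task —
whose carry cycles mimic a hand-to-face excursion — is confused with the
face-touching activities far more than the leisure walk is.
"""

from facetouch import (FT_ACTIVITIES, MULTICLASS, ModelSpec,
                       SimulationConfig, align_and_trim, extract_features,
                       make_nested_plan, run_nested_cv, simulate_dataset)

cfg = SimulationConfig(n_participants=7, activity_duration=60.0, seed=42)
recordings, logs = simulate_dataset(cfg)
segments = []
for rec, log in zip(recordings, logs):
    segments.extend(align_and_trim(rec, log))

matrix = extract_features(segments, window_length=5, sampling_rate=30.0)
plan = make_nested_plan(sorted(matrix["participant_id"].unique()), seed=42)
spec = ModelSpec("random_forest", ({"n_estimators": 100},))  # 1-point grid
report = run_nested_cv(matrix, MULTICLASS, spec, plan, 5)

print("10-class recognition, random forest:", report.summary_formatted())

cm = report.confusion
ft = list(FT_ACTIVITIES)
moving = "Moving items from one location to another"
walk = "Leisure walk"
print(f"\nconfusion mass exchanged with FT activities (percent points):")
print(f"  moving items: {cm.loc[moving, ft].sum() + cm.loc[ft, moving].sum():.1f}")
print(f"  leisure walk: {cm.loc[walk, ft].sum() + cm.loc[ft, walk].sum():.1f}")

print("\ntop 5 features by scaled impurity importance:")
print(report.importances.head(5).round(3).to_string())
print(f"\nsdangle scaled importance: {report.importances['sdangle']:.3f} "
      f"(rank {1 + list(report.importances.index).index('sdangle')})")
print("For separating all ten activities, orientation summaries (axis "
      "means/extrema) carry most of the split gain; the gravity-angle "
      "features matter most where FT and its mimics must be told apart.")
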