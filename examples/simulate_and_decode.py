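"""Generate a synthetic affective-EEG dataset and decode it end to end.

Builds 80 labeled trials (32 channels x 8064 samples at 128 Hz) with a 4x
alpha-band amplitude effect on five channels (Fp1, FC1, T7, O1, T8), then
runs the full two-step majority-voting pipeline: per-channel KNN under
10-fold cross-validation, top-5 channel vote per rhythm, and a final vote
across rhythms with the best rhythm duplicated to keep the count odd.
"""

import eegvote as ev
from eegvote.synthetic import SyntheticSpec, generate_dataset

spec = SyntheticSpec(n_trials=80, effect_gain=4.0, seed=7)
dataset = generate_dataset(spec)
result = ev.two_step_pipeline(dataset, cv=ev.CVConfig(seed=7))

print(f"trials: {dataset.n_trials}, channels: {dataset.n_channels}, "
      f"fs: {dataset.fs} Hz")
print("\nfirst-step (per-rhythm) voted accuracy:")
for name, rv in result.per_rhythm.items():
    print(f"  {name:5s}  acc={rv.accuracy:.4f}  top-5: {', '.join(rv.top_channels)}")
print(f"\nduplicated rhythm for the second vote: {result.duplicated_rhythm}")
print(f"final accuracy:    {result.accuracy:.4f}")
print(f"final sensitivity: {result.sensitivity:.4f}")
print(f"final specificity: {result.specificity:.4f}")
print("\nThe alpha rhythm should win (the planted effect lives at 8-12 Hz on")
print("exactly those five channels); the other rhythms sit near the chance-")
print("plus-selection-optimism floor, and the final vote follows alpha.")
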