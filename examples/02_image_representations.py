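"""Build every sEMG image representation from one window.

Shows the all-pairs-adjacent channel rearrangement (length 51 for 10
channels) and the tensor shape each representation produces.
"""

import numpy as np

import semgkit as sk
from semgkit.features import FeatureConfig

specs = sk.simulate.default_gesture_specs(G=4, C=10, kind="both")
rec = sk.simulate_dataset(specs, sk.SimConfig(seed=1))
w = sk.sliding_windows(rec, 200.0, 100.0)[0]  # 20 frames x 10 channels

seq = sk.build_channel_sequence(w.n_channels)
print(f"channel sequence for C=10: length {len(seq)}")
print(f"  order: {seq.order}")
# every pair of distinct channels is adjacent somewhere in this sequence,
# so 3x3 kernels on the rearranged axis see all pairwise channel relations

fcfg = FeatureConfig(feature_names=("MAV", "RMS", "WL", "ZC"))
images = {
    "raw-image1": sk.raw_image1(w),
    "raw-image2": sk.raw_image2(w),
    "signal-image1": sk.signal_image1(w, seq),
    "signal-image2": sk.signal_image2(w, seq),
    "activity-image1": sk.activity_image1(w, seq),
    "feature-signal-image1": sk.feature_signal_image1(w, fcfg, seq),
    "feature-signal-image2": sk.feature_signal_image2(w, fcfg, seq),
    "feature-flatten-image": sk.feature_flatten_image(w, fcfg),
}
for name, img in images.items():
    print(f"{name:24s} {img.shape}  (color x width x height)")

# high-density grid layout for a 128-electrode 16x8 array
hd_specs = sk.simulate.default_hd_specs(2, (16, 8))
hd_cfg = sk.SimConfig(n_channels=128, rate=1000.0, trials_per_class=1,
                      trial_s=0.5, seed=0, grid=(16, 8))
hd_rec = sk.simulate_hd_dataset(hd_specs, hd_cfg)
hd_w = sk.sliding_windows(hd_rec, 40.0, 40.0)[0]
print(f"{'hd-grid-image':24s} {sk.hd_grid_image(hd_w, (16, 8)).shape}")
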