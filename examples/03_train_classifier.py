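"""Train the attention-based hybrid CNN-RNN on synthetic data.

Uses the feature-signal-image1 representation with T=10 subsegments per
200 ms window, a 2/3-by-trial split, and a compact model (16 kernels,
FC 64-64-32, LSTM 64). Takes a couple of minutes on one CPU.
"""

import numpy as np

import semgkit as sk
from semgkit.features import FeatureConfig
from semgkit.network import CnnConfig
from semgkit.train import (TrainConfig, build_sequence_dataset, evaluate,
                           make_splits, select_windows, train_on_arrays)

specs = sk.simulate.default_gesture_specs(G=4, C=10, kind="both")
rec = sk.simulate_dataset(specs, sk.SimConfig(seed=1))
windows = sk.sliding_windows(rec, 200.0, 100.0)
train_ids, test_ids = make_splits(rec, "by_trial_fraction")  # 7/3 trials per class

fcfg = FeatureConfig(feature_names=("MAV", "RMS", "WL", "ZC"))
train_data = build_sequence_dataset(select_windows(windows, train_ids),
                                    "feature_signal1", T=10, feature_cfg=fcfg)
test_data = build_sequence_dataset(select_windows(windows, test_ids),
                                   "feature_signal1", T=10, feature_cfg=fcfg,
                                   classes=train_data.classes)
print(f"train {train_data.n_samples} windows, test {test_data.n_samples} windows")
print(f"per-window input: {train_data.X.shape[1:]} (T x color x W x H)")

cfg = TrainConfig(epochs=10, batch_size=64, learning_rate=0.05, seed=0, T=10,
                  mode="hybrid_attention", representation="feature_signal1",
                  cnn=CnnConfig(conv_channels=16, local_channels=16,
                                fc_sizes=(64, 64, 32)),
                  lstm_hidden=64, attention_dim=64)
result = train_on_arrays(train_data, cfg)
print("per-epoch loss:", " ".join(f"{v:.3f}" for v in result.loss_log))

report = evaluate(result.model, test_data)
print(f"held-out window accuracy: {report.window_accuracy:.1f}%")
print(f"held-out trial accuracy:  {report.trial_accuracy:.1f}%")
print("confusion (rows = true class):")
print(report.confusion)
# accuracy is 100 * correct / total over held-out trials the model never saw
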