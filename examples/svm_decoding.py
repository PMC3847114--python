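"""Two-class SVM brain decoding with decision-value feedback.

Trains a linear SVM on one synthetic session (two emotional conditions
activating disjoint ROIs, neutral baseline between blocks), then streams a
second session in feedback mode: each kept volume window is averaged,
baseline-normalised, projected on the hyperplane (x·w + b), and binned
onto the feedback figure grid.
"""

import tempfile
from pathlib import Path

from rtnf.protocols import emotional_protocol
from rtnf.runner import SessionConfig, run
from rtnf.synth import generate_session, stream_session

workdir = Path(tempfile.mkdtemp(prefix="rtnf_svm_"))

# training run: functional localizer + SVM fit (offline, after the stream)
train = generate_session(emotional_protocol(seed=2), workdir / "train")
stream_session(train, workdir / "watch1")
train_config = SessionConfig(
    mode="svm_train",
    rfi=train["rfi"], design=train["design"],
    n_volumes=train["n_volumes"], baseline_name="NEUTRAL",
    watch_dir=str(workdir / "watch1"), out_dir=str(workdir / "model"),
    fwhm_mm=6.0, svm_window=3,
    feature_mode="t_threshold", t_threshold=5.5)
train_log = run(train_config)
print(f"feature selection |t| > 5.5 kept {train_log.summary['n_features']} voxels")
print(f"training examples: {train_log.summary['n_examples']}, "
      f"training accuracy: {train_log.summary['training_accuracy']:.1f}%")

# feedback run: real-time classification of a fresh session
test = generate_session(emotional_protocol(seed=3), workdir / "test")
stream_session(test, workdir / "watch2")
test_config = SessionConfig(
    mode="svm_feedback",
    rfi=test["rfi"], design=test["design"],
    n_volumes=test["n_volumes"], baseline_name="NEUTRAL",
    watch_dir=str(workdir / "watch2"), out_dir=str(workdir / "feedback"),
    fwhm_mm=6.0,
    model_path=str(workdir / "model" / "decoder_model.json"))
log = run(test_config)
print(f"cumulative decoding accuracy on the held-out session: "
      f"{log.summary['cumulative_accuracy']:.1f}%")
# scored scans only: non-baseline volumes whose averaging window is clean;
# each feedback row carries the raw decision value and its figure bin
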