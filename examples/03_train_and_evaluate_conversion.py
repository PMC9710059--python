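"""Train a one-to-all conversion U-Net and evaluate it on held-out
subjects.

A shared encoder compresses a normalised lead-II segment; one decoder per
target lead reconstructs the synchronous segment of that lead.  Training
uses the l1 loss, Adam at 1e-3, and validation-based early stopping; the
report gives per-lead average/median Pearson r, RMSE and 1-D SSIM.

Scaled down (20 subjects, small model) so it runs in about a minute.
"""

from leadconv.evaluate import evaluate_conversion
from leadconv.models import ModelConfig, build_model
from leadconv.preprocess import SplitSpec, preprocess_pipeline, subject_split
from leadconv.synth import SynthConfig, generate_dataset
from leadconv.train import TrainConfig, fit

records = generate_dataset(SynthConfig(n_subjects=20, seed=0))
train_recs, val_recs, test_recs = subject_split(records, SplitSpec(seed=0))
leads = ("I", "II", "III", "aVR", "aVL", "aVF")
prep = lambda recs: preprocess_pipeline(recs, window_seconds=2.5,
                                        fs_target=250.0, leads=leads)
train_set, val_set, test_set = prep(train_recs), prep(val_recs), prep(test_recs)

config = ModelConfig(family="unet", reference_lead="II",
                     target_leads=("I", "III", "aVR", "aVL", "aVF"),
                     encoder_scheme="shared", depth=3, base_channels=8,
                     kernel_size=9, input_length=train_set.window_length)
model = build_model(config, seed=0)
model, history = fit(model, train_set, val_set,
                     TrainConfig(max_epochs=25, patience=6, batch_size=32,
                                 seed=0))
print(f"trained {history.n_epochs} epochs "
      f"(best validation l1 {min(history.val_loss):.3f} "
      f"at epoch {history.best_epoch})")

report = evaluate_conversion(model, test_set)[0]
print(report)
print("\nIII/aVR/aVF are algebraic functions of the limb potentials, so "
      "their r should be high; lead I requires demixing the second "
      "morphology component and is harder.")
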