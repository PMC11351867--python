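"""Train the three cascade stages at desk scale and save checkpoints.

Stage 1: coarse segmentation U-Net (SE + non-local attention), Dice loss.
Stage 2: rejection network regressing each coarse result's Dice quality
         from the coarse feature map + probability map (coarse frozen).
Stage 3: built-in box-prompted fine segmenter, cross-entropy + Dice loss,
         prompts jittered (0-60% expansion, corner shifts) during training.

Runs in a few minutes on one CPU at this reduced size; checkpoints land in
./scratch so the evaluation example can reuse them.
"""

import os

from cascadeseg._train_utils import TrainConfig
from cascadeseg.checkpoints import save_checkpoint
from cascadeseg.coarse_seg import CoarseNetConfig, build_coarse_net, train_coarse
from cascadeseg.prompt_seg import PromptSegConfig, builtin_prompt_net, \
    train_prompt_seg
from cascadeseg.rejection import RejectNetConfig, build_rejection_net, \
    train_rejection
from cascadeseg.synthetic_data import PhantomSpec, generate_cohort

spec = PhantomSpec(image_size=64, seed=42, lesion_count_range=(1, 3))
cohort = generate_cohort(spec, n_patients=16, slices_per_patient=4).normalized()

coarse = build_coarse_net(CoarseNetConfig(base_channels=8, seed=0))
coarse, hist = train_coarse(coarse, cohort,
                            TrainConfig(epochs=8, batch_size=16, lr=3e-3, seed=0))
print("coarse: best validation DSC on lesion slices =",
      round(max(h["val_dsc"] for h in hist), 3))

rej = build_rejection_net(
    RejectNetConfig.desk_scale(in_channels=coarse.feature_channels + 2, seed=1))
rej, rhist = train_rejection(rej, coarse, cohort,
                             TrainConfig(epochs=6, batch_size=16, lr=1e-3,
                                         seed=1, augment=False))
print("rejection: best validation MSE =",
      round(min(h["val_mse"] for h in rhist), 4))
# sqrt(MSE) is the typical error of the predicted quality score in Dice units

seg = builtin_prompt_net(PromptSegConfig(base_channels=8, seed=2))
seg, phist = train_prompt_seg(seg, cohort,
                              TrainConfig(epochs=8, batch_size=8, lr=3e-3,
                                          weight_decay=0.01, seed=2))
print("prompt segmenter: best validation DSC with truth-derived boxes =",
      round(max(h["val_dsc"] for h in phist), 3))

os.makedirs("scratch", exist_ok=True)
for model, name in ((coarse, "coarse"), (rej, "rejection"), (seg, "prompt")):
    save_checkpoint(model, f"scratch/example_{name}.npz")
print("checkpoints saved under scratch/")
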