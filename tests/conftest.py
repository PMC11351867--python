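"""Shared fixtures.

``mini_cohort`` is a small mixed-difficulty phantom cohort for contract
tests. ``trained_cascade`` trains all three desk-scale models once per
session on a mixed cohort sized so the quality-gating behaviour is
measurable; the end-to-end and acceptance tests share it.
"""

from dataclasses import dataclass

import numpy as np
import pytest

from cascadeseg._train_utils import TrainConfig
from cascadeseg.coarse_seg import CoarseNetConfig, build_coarse_net, train_coarse
from cascadeseg.prompt_seg import PromptSegConfig, builtin_prompt_net, train_prompt_seg
from cascadeseg.rejection import (RejectNetConfig, build_rejection_net,
                                  train_rejection)
from cascadeseg.synthetic_data import PhantomSpec, generate_cohort

DESK_IMAGE_SIZE = 64


def desk_cohort(seed: int, n_patients: int = 12, slices: int = 4,
                difficulty_range=(0.02, 0.98), lesions=(1, 3)):
    spec = PhantomSpec(image_size=DESK_IMAGE_SIZE, seed=seed,
                       lesion_count_range=lesions)
    return generate_cohort(spec, n_patients, slices_per_patient=slices,
                           difficulty_range=difficulty_range).normalized()


@pytest.fixture(scope="session")
def mini_cohort():
    return desk_cohort(seed=7)


@dataclass
class TrainedCascade:
    cohort: object
    coarse: object
    rejection: object
    segmenter: object
    coarse_history: list
    rejection_history: list
    prompt_history: list


@pytest.fixture(scope="session")
def trained_cascade():
    """Desk-scale three-stage training on a mixed-difficulty cohort.

    ~40 patients of 64x64 slices; difficulty spans [0, 1] so coarse quality
    (and hence the gate's usefulness) is heterogeneous. Epoch counts are
    desk-scale (well under 30 per stage) to keep the suite within budget.
    """
    cohort = desk_cohort(seed=11, n_patients=40, slices=6,
                         difficulty_range=(0.02, 0.98))
    coarse = build_coarse_net(CoarseNetConfig(base_channels=8, seed=0))
    coarse, ch = train_coarse(coarse, cohort,
                              TrainConfig(epochs=16, batch_size=16, lr=3e-3,
                                          seed=0))
    rej = build_rejection_net(
        RejectNetConfig.desk_scale(in_channels=coarse.feature_channels + 2,
                                   seed=1))
    rej, rh = train_rejection(rej, coarse, cohort,
                              TrainConfig(epochs=10, batch_size=16, lr=1e-3,
                                          seed=1, augment=False))
    seg = builtin_prompt_net(PromptSegConfig(base_channels=8, seed=2))
    seg, ph = train_prompt_seg(seg, cohort,
                               TrainConfig(epochs=10, batch_size=8, lr=3e-3,
                                           weight_decay=0.01, seed=2))
    return TrainedCascade(cohort=cohort, coarse=coarse, rejection=rej,
                          segmenter=seg, coarse_history=ch,
                          rejection_history=rh, prompt_history=ph)
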