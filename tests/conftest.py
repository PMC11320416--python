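"""Shared fixtures: small phantom cohorts and a trained tiny network.

Expensive artifacts (the trained segmentation net) are session-scoped so the
segmentation-quality, gating and oracle-mask tests share one training run.
"""

from dataclasses import replace

import numpy as np
import pytest

from m3 import phantom, segnet


@pytest.fixture(scope="session")
def tiny_encoder_config() -> segnet.EncoderConfig:
    return segnet.EncoderConfig(width_scale=1 / 16)


@pytest.fixture(scope="session")
def tumor_config() -> phantom.PhantomConfig:
    return phantom.get_preset("tumor3")


@pytest.fixture(scope="session")
def small_cohort(tumor_config):
    """20 balanced tumor-like cases (a subset-sized cohort of the preset)."""
    cfg = replace(tumor_config, class_balance=(10, 10), seed=11)
    return phantom.generate_cohort(cfg)


@pytest.fixture(scope="session")
def trained_model(tiny_encoder_config, small_cohort):
    """Tiny net trained class-blind for 50 epochs on 16 of the 20 cases."""
    model = segnet.build_model(tiny_encoder_config, seed=3)
    train = [c.without_class_label() for c in small_cohort[:8] + small_cohort[10:18]]
    model, history = segnet.train_segmentation(
        model,
        train,
        "T1ce",
        segnet.TrainConfig(epochs=50, batch_size=8, seed=3, loss="ce_plus_dice",
                           learning_rate=3e-3),
    )
    return model, history


@pytest.fixture(scope="session")
def heldout_cases(small_cohort):
    """The 4 cases (2 per class) not used by ``trained_model``."""
    return small_cohort[8:10] + small_cohort[18:20]
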