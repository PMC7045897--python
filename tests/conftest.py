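"""Shared fixtures: all image data is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from deuseg import PhantomConfig, generate_cohort, generate_study, preprocess_study


@pytest.fixture(scope="session")
def tiny_phantom_config() -> PhantomConfig:
    """Small dual-resolution phantom: 12 slices of 64x64 on the fine grid,
    coarse channel at half the in-plane resolution."""
    return PhantomConfig(
        grid_shape=(12, 64, 64),
        spacing_ch1=(4.0, 2.0, 2.0),
        spacing_ch2=(4.0, 1.0, 1.0),
        n_lesions=1,
        lesion_radius_range=(6.0, 10.0),
        t1_hypointense_fraction=0.5,
        confuser_count=3,
        confuser_radius_range=(4.0, 7.0),
        misregistration_offset=(0.0, 1.0, 1.0),
        noise_sd=0.02,
        seed=100,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_phantom_config):
    return generate_study(tiny_phantom_config)


@pytest.fixture(scope="session")
def preprocessed_cohort(tiny_phantom_config):
    """Twelve preprocessed phantom patients at 32x32 input size, shared by the
    training/evaluation tests (preprocessing is deterministic, so sharing is
    safe)."""
    studies = generate_cohort(tiny_phantom_config, 12, base_seed=100)
    return [preprocess_study(s, (32, 32)) for s in studies]


@pytest.fixture()
def tiny_net_kwargs() -> dict:
    """Architecture small enough for CPU training at 32x32."""
    return dict(input_size=(32, 32), base_channels=4, channels_per_stage=(4, 8, 8, 8),
                growth_rate=4, dense_micro_blocks=2, gn_groups=4)
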