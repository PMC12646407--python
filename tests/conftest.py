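"""Shared fixtures.

The expensive end-to-end artifact — a tiny-width network trained on seeded
64x64 phantoms — is built once per session and shared by the training,
compression and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from svncnet.arch import ArchConfig, build_svnc_net
from svncnet.phantom import PhantomConfig, generate_phantom, phantom_dataset
from svncnet.schedule import ScheduleConfig
from svncnet.training import RunConfig, train_model, training_dice

TINY_ARCH = dict(input_size=64, stage_widths=(8, 16, 32, 64), bottleneck_width=128)

PHANTOM_64 = dict(shape=(24, 64, 64),
                  semi_axes_range=((4.0, 7.0), (10.0, 18.0), (10.0, 18.0)),
                  center_jitter=5.0)


@pytest.fixture(scope="session")
def tiny_arch() -> ArchConfig:
    return ArchConfig(**TINY_ARCH)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def smoke(tiny_arch):
    """Tiny-width network trained 10 epochs on 64x64 phantom slices, with
    its training records and two held-out phantom volumes."""
    pcfg = PhantomConfig(n_volumes=16, seed=11, **PHANTOM_64)
    records, _ = phantom_dataset(pcfg, target_size=64)
    run = RunConfig(arch=tiny_arch, schedule=ScheduleConfig(cycle_lengths=(10,)),
                    epochs=10, batch_size=8, seed=7)
    model = build_svnc_net(tiny_arch, seed=run.seed)
    log = train_model(model, records, None, run)
    held_out = generate_phantom(PhantomConfig(n_volumes=2, seed=99, **PHANTOM_64))
    return {
        "model": model,
        "records": records,
        "log": log,
        "held_out": held_out,
        "train_dice": training_dice(model, records),
        "run": run,
    }
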