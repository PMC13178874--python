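"""Shared fixtures: small rendered datasets and trained models.

Expensive fixtures are session-scoped so the acceptance tests (multi-seed
replication, determinism audit) train each model set exactly once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fundusvae import preprocess as pp, simulate as sim
from fundusvae.experiments import run_replication, smoke_config
from fundusvae.pipeline import run_benchmark, stream_arrays, train_all_streams
from fundusvae.train import StreamVAE
from fundusvae.vae import StreamConfig


@pytest.fixture(scope="session")
def factor_table():
    return sim.sample_factors(30, pair_eyes=True, eye_noise_sd=0.02, seed=11)


@pytest.fixture(scope="session")
def rendered_samples(factor_table):
    return sim.render_dataset(factor_table, resolution=32, seed=11)


@pytest.fixture(scope="session")
def one_sample(rendered_samples):
    return rendered_samples[0]


@pytest.fixture(scope="session")
def tiny_arrays(rendered_samples):
    """NCHW input arrays for all four streams at 32 px."""
    return stream_arrays(rendered_samples, 32)


@pytest.fixture(scope="session")
def tiny_background_fit(tiny_arrays):
    """A 3-epoch background stream fit on the tiny dataset."""
    x, _ = tiny_arrays["background"]
    cfg = StreamConfig(stream="background", latent_dim=8, resolution=32,
                       base_width=8, kl_weight=3e-4, seed=5)
    return StreamVAE(x[:44], x[44:], cfg).fit(epochs=3, batch_size=16, seed=5)


@pytest.fixture(scope="session")
def tiny_vessel_fit(tiny_arrays):
    x, _ = tiny_arrays["vessel"]
    cfg = StreamConfig(stream="vessel", latent_dim=8, resolution=32,
                       base_width=8, kl_weight=3e-4, seed=6)
    return StreamVAE(x[:44], x[44:], cfg).fit(epochs=3, batch_size=16, seed=6)


@pytest.fixture(scope="session")
def replication_reports():
    """The canonical five-seed replication experiment (trains 20 models)."""
    return run_replication([1, 2, 3, 4, 5])


@pytest.fixture(scope="session")
def smoke_report_pair():
    """The same smoke benchmark run twice for the determinism audit."""
    import json

    from fundusvae.pipeline import _plain

    reports = []
    for _ in range(2):
        rep = run_benchmark(smoke_config(3))
        rep.pop("stage_seconds")  # wall-clock, legitimately differs
        reports.append(json.dumps(_plain(rep), sort_keys=True))
    return reports
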