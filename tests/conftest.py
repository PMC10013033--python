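"""Shared fixtures: small synthetic cohorts and hand-built epoch sets."""

from __future__ import annotations

import numpy as np
import pytest

from dnmcrit.epochs_io import CorrectedEpochs, EpochSet
from dnmcrit.preprocess import (
    PreprocessConfig,
    correct_epochs,
    extract_epochs,
    reject_artifacts,
)
from dnmcrit.synthetic import iter_study, scaled_config


def make_corrected(data, sampling_rate=500.0, subject_id="S1", group="HC"):
    """Wrap an epoch x channel x time array as CorrectedEpochs with a
    stimulus-onset-anchored time axis."""
    data = np.asarray(data, dtype=float)
    t = np.arange(data.shape[2]) * 1000.0 / sampling_rate
    return CorrectedEpochs(
        subject_id=subject_id, group=group, sampling_rate=sampling_rate,
        time_axis=t, data=data,
    )


def cohort_corrected(config):
    """Simulate a cohort and run it through the preprocessing chain."""
    pre = PreprocessConfig()
    out = []
    for rec in iter_study(config):
        es = reject_artifacts(extract_epochs(rec, pre), pre)
        out.append(correct_epochs(es))
    return out


@pytest.fixture(scope="session")
def small_cohort():
    """10 HC vs 10 PD subjects, 32 channels, 200 stimuli: big enough for
    node selection at the default thresholds, small enough to share."""
    cfg = scaled_config({"HC": 10, "PD": 10}, n_channels=32, n_stimuli=200, seed=11)
    return cfg, cohort_corrected(cfg)


@pytest.fixture(scope="session")
def trio_cohort():
    """HC/UHR/PD cohort used by group-contrast and risk tests."""
    cfg = scaled_config(
        {"HC": 12, "UHR": 8, "PD": 10}, n_channels=32, n_stimuli=250, seed=21
    )
    return cfg, cohort_corrected(cfg)


@pytest.fixture()
def tiny_epochset():
    rng = np.random.default_rng(3)
    std = rng.normal(size=(6, 4, 20))
    dev = rng.normal(size=(3, 4, 20))
    t = (np.arange(20) - 5) * 2.0
    return EpochSet(
        subject_id="T1", group="HC", sampling_rate=500.0, time_axis=t,
        standard_epochs=std, deviant_epochs=dev,
    )
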