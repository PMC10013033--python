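"""Epoching, baseline correction, artifact rejection, corrected epochs.

Corrected epochs — deviant epochs minus the subject's mean standard
response — are the empirical difference process that all downstream
criticality measures operate on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from dnmcrit.epochs_io import CorrectedEpochs, EpochSet
from dnmcrit.synthetic import OddballRecording

__all__ = ["PreprocessConfig", "extract_epochs", "reject_artifacts", "correct_epochs"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Epoching parameters.

    The epoch window (default −100..400 ms) covers the 100–250 ms mismatch
    search range plus a pre-stimulus baseline; samples are taken with an
    inclusive-start / exclusive-end convention on the sample grid.
    Artifact rejection drops any epoch whose absolute amplitude exceeds
    ``reject_amplitude`` (µV) on any channel.
    """

    epoch_window: tuple[float, float] = (-100.0, 400.0)
    baseline_window: tuple[float, float] = (-100.0, 0.0)
    reject_amplitude: float = 100.0
    bandpass: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        e0, e1 = self.epoch_window
        b0, b1 = self.baseline_window
        if e1 <= e0 or b1 <= b0:
            raise ValueError("windows must be increasing (start, end) pairs in ms")
        if b0 < e0 or b1 > e1:
            raise ValueError("epoch_window must contain baseline_window")
        if self.reject_amplitude <= 0:
            raise ValueError("reject_amplitude must be positive")


def _window_samples(window: tuple[float, float], fs: float) -> tuple[int, int]:
    """Map a ms window to sample offsets, inclusive start / exclusive end."""
    start = int(round(window[0] * fs / 1000.0))
    stop = int(round(window[1] * fs / 1000.0))
    return start, stop


def extract_epochs(recording: OddballRecording, config: PreprocessConfig) -> EpochSet:
    """Cut per-event epochs and subtract the per-epoch baseline mean.

    Events whose window would cross a recording edge are dropped with a
    logged count.  Optional zero-phase Butterworth band-pass filtering is
    applied to the continuous signal before epoching when
    ``config.bandpass`` is set.
    """
    fs = recording.sampling_rate
    sig = recording.signal
    if config.bandpass is not None:
        from scipy.signal import butter, sosfiltfilt

        lo, hi = config.bandpass
        sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        sig = sosfiltfilt(sos, sig, axis=1)

    start, stop = _window_samples(config.epoch_window, fs)
    b0, b1 = _window_samples(config.baseline_window, fs)
    n_time = stop - start
    time_axis = (np.arange(start, stop)) * 1000.0 / fs
    # baseline sample positions within the epoch
    bl = slice(b0 - start, b1 - start)

    stacks: dict[str, list[np.ndarray]] = {"standard": [], "deviant": []}
    dropped = 0
    for onset, kind in recording.events:
        lo_s, hi_s = onset + start, onset + stop
        if lo_s < 0 or hi_s > sig.shape[1]:
            dropped += 1
            continue
        ep = sig[:, lo_s:hi_s].copy()
        ep -= ep[:, bl].mean(axis=1, keepdims=True)
        stacks[kind].append(ep)
    if dropped:
        log.info("extract_epochs(%s): dropped %d edge events",
                 recording.subject_id, dropped)
    if not stacks["standard"] and not stacks["deviant"]:
        raise ValueError("extract_epochs: no epochs survived edge-dropping")

    def _stack(lst):
        if lst:
            return np.stack(lst)
        return np.zeros((0, sig.shape[0], n_time))

    return EpochSet(
        subject_id=recording.subject_id,
        group=recording.group,
        sampling_rate=fs,
        time_axis=time_axis,
        standard_epochs=_stack(stacks["standard"]),
        deviant_epochs=_stack(stacks["deviant"]),
    )


def reject_artifacts(epochs: EpochSet, config: PreprocessConfig) -> EpochSet:
    """Drop epochs whose absolute amplitude exceeds the threshold anywhere."""
    thr = config.reject_amplitude
    keep = {}
    for kind, arr in (
        ("standard", epochs.standard_epochs),
        ("deviant", epochs.deviant_epochs),
    ):
        if arr.shape[0] == 0:
            keep[kind] = arr
            continue
        ok = np.max(np.abs(arr), axis=(1, 2)) <= thr
        n_rej = int((~ok).sum())
        if n_rej:
            log.info("reject_artifacts(%s): rejected %d/%d %s epochs",
                     epochs.subject_id, n_rej, arr.shape[0], kind)
        keep[kind] = arr[ok]
    if keep["standard"].shape[0] == 0 and keep["deviant"].shape[0] == 0:
        raise ValueError("reject_artifacts: all epochs rejected")
    return EpochSet(
        subject_id=epochs.subject_id,
        group=epochs.group,
        sampling_rate=epochs.sampling_rate,
        time_axis=epochs.time_axis,
        standard_epochs=keep["standard"],
        deviant_epochs=keep["deviant"],
        channel_ids=epochs.channel_ids,
    )


def correct_epochs(epochs: EpochSet) -> CorrectedEpochs:
    """Subtract the mean standard response from every deviant epoch,
    sample by sample:  data[e, c, t] = deviant[e, c, t] − mean_std[c, t]."""
    if epochs.standard_epochs.shape[0] < 1:
        raise ValueError("correct_epochs: no standard epochs to average")
    if epochs.deviant_epochs.shape[0] < 1:
        raise ValueError("correct_epochs: no deviant epochs")
    mean_std = epochs.standard_epochs.mean(axis=0)
    return CorrectedEpochs(
        subject_id=epochs.subject_id,
        group=epochs.group,
        sampling_rate=epochs.sampling_rate,
        time_axis=epochs.time_axis,
        data=epochs.deviant_epochs - mean_std[np.newaxis],
        channel_ids=epochs.channel_ids,
    )
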