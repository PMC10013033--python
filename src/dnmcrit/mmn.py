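"""Mismatch negativity: waveform, peak latency, amplitude, group contrasts.

The MMN is the negative deflection of the corrected (deviant − standard)
event-related response, conventionally the most negative peak between 100
and 250 ms.  Amplitude is the mean of the corrected waveform over a fixed
window: 135–205 ms for duration deviants (dD), 100–200 ms for frequency
deviants (fD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from dnmcrit.epochs_io import CorrectedEpochs
from dnmcrit.stats import fdr_adjust, rank_sum_test

__all__ = [
    "MMNResult",
    "PEAK_SEARCH_WINDOW",
    "AMPLITUDE_WINDOWS",
    "erp_average",
    "mmn_peak_latency",
    "mmn_amplitude",
    "subject_mmn",
    "mmn_group_test",
]

#: peak search range, ms after stimulus onset
PEAK_SEARCH_WINDOW = (100.0, 250.0)

#: fixed amplitude-averaging windows per deviant kind, ms
AMPLITUDE_WINDOWS = {"dD": (135.0, 205.0), "fD": (100.0, 200.0)}


@dataclass(frozen=True)
class MMNResult:
    """Per-subject MMN summary: per-channel peak latency (ms), amplitude
    (µV, fixed-window mean) and the corrected waveform."""

    subject_id: str
    group: str
    deviant_kind: str
    peak_latency: np.ndarray
    amplitude: np.ndarray
    waveform: np.ndarray
    time_axis: np.ndarray


def erp_average(corrected: CorrectedEpochs) -> np.ndarray:
    """Arithmetic mean over corrected epochs (channel x time)."""
    if corrected.n_epochs < 1:
        raise ValueError("erp_average: need at least one epoch")
    return corrected.data.mean(axis=0)


def _window_mask(time_axis: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    mask = (time_axis >= window[0]) & (time_axis <= window[1])
    if not mask.any():
        raise ValueError(f"window {window} contains no samples of the time axis")
    return mask


def mmn_peak_latency(
    waveform: np.ndarray,
    time_axis: np.ndarray,
    search_window: tuple[float, float] = PEAK_SEARCH_WINDOW,
) -> np.ndarray:
    """Latency (ms) of the most negative sample inside the search window,
    per channel; ties resolve to the earliest latency (argmin convention)."""
    if search_window[0] < time_axis[0] or search_window[1] > time_axis[-1]:
        raise ValueError("search window extends beyond the waveform time axis")
    mask = _window_mask(time_axis, search_window)
    seg = np.atleast_2d(waveform)[:, mask]
    return np.asarray(time_axis[mask][np.argmin(seg, axis=1)], dtype=float)


def mmn_amplitude(
    waveform: np.ndarray,
    time_axis: np.ndarray,
    window: tuple[float, float],
) -> np.ndarray:
    """Mean of the waveform over the fixed window (µV), per channel."""
    if window[0] < time_axis[0] or window[1] > time_axis[-1]:
        raise ValueError("amplitude window extends beyond the waveform time axis")
    mask = _window_mask(time_axis, window)
    return np.atleast_2d(waveform)[:, mask].mean(axis=1)


def subject_mmn(corrected: CorrectedEpochs, deviant_kind: str = "dD") -> MMNResult:
    """Full per-subject MMN summary from corrected epochs."""
    if deviant_kind not in AMPLITUDE_WINDOWS:
        raise ValueError(f"deviant_kind must be one of {sorted(AMPLITUDE_WINDOWS)}")
    wave = erp_average(corrected)
    return MMNResult(
        subject_id=corrected.subject_id,
        group=corrected.group,
        deviant_kind=deviant_kind,
        peak_latency=mmn_peak_latency(wave, corrected.time_axis),
        amplitude=mmn_amplitude(
            wave, corrected.time_axis, AMPLITUDE_WINDOWS[deviant_kind]
        ),
        waveform=wave,
        time_axis=corrected.time_axis,
    )


#: contrasts reported throughout: (name, group_a, group_b, alternative);
#: one-sided where the clinical hypothesis is directional (reduced MMN /
#: criticality in illness), two-sided for UHR vs PD
GROUP_CONTRASTS = (
    ("HC_vs_PD", "HC", "PD", "two-sided"),
    ("HC_vs_UHR", "HC", "UHR", "two-sided"),
    ("UHR_vs_PD", "UHR", "PD", "two-sided"),
)


def mmn_group_test(results: list[MMNResult]) -> pd.DataFrame:
    """Per-channel Wilcoxon rank-sum contrasts of MMN amplitude between
    groups, Benjamini–Hochberg adjusted across channels within each
    contrast.

    Returns a tidy frame with columns contrast, channel (1-based), p_value,
    p_adjusted.  Channels where both groups are fully tied get p = 1.
    """
    if not results:
        raise ValueError("mmn_group_test: no subjects")
    amp = np.stack([r.amplitude for r in results])  # subject x channel
    groups = np.array([r.group for r in results])
    n_channels = amp.shape[1]

    rows = []
    for name, ga, gb, alternative in GROUP_CONTRASTS:
        a, b = amp[groups == ga], amp[groups == gb]
        if a.shape[0] < 2 or b.shape[0] < 2:
            continue
        pvals = np.array([
            rank_sum_test(a[:, c], b[:, c], alternative=alternative).p_value
            for c in range(n_channels)
        ])
        padj = fdr_adjust(pvals)
        for c in range(n_channels):
            rows.append({
                "contrast": name,
                "channel": c + 1,
                "p_value": pvals[c],
                "p_adjusted": padj[c],
            })
    return pd.DataFrame(rows)
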