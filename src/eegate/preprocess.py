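"""Algorithmic pre-processing: filtering, bad-channel and bad-segment rules.

These are the rule-based cleaning steps that can run without an operator:
broadband band-pass, power-line notch, neighbor-correlation bad-channel
detection with interpolation, and two-band amplitude-threshold bad-segment
detection.  Independent-component artifact removal and visual inspection are
deliberately out of scope; recordings whose total flagged time exceeds 60 s
only receive a review flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._filters import butter_bandpass, notch_iir
from .montage import Montage
from .recording import Recording

__all__ = ["SegmentFlags", "bandpass", "notch", "flag_bad_channels",
           "detect_bad_segments"]

REVIEW_THRESHOLD_S = 60.0


@dataclass
class SegmentFlags:
    """Flagged artifacts of one recording."""

    bad_intervals: list = field(default_factory=list)  # (start_s, end_s), merged
    bad_channels: list = field(default_factory=list)
    total_bad_s: float = 0.0
    needs_review: bool = False


def bandpass(recording: Recording, low: float = 0.5, high: float = 45.0,
             order: int = 4) -> Recording:
    """Zero-phase (forward-backward) Butterworth band-pass, length preserved."""
    return recording.with_data(
        butter_bandpass(recording.data, low, high, recording.fs, order))


def notch(recording: Recording, freq: float = 50.0, quality: float = 30.0) -> Recording:
    """Zero-phase notch filter removing power-line interference."""
    return recording.with_data(notch_iir(recording.data, freq, recording.fs, quality))


def flag_bad_channels(recording: Recording, montage: Montage,
                      r_min: float = 0.8, interpolate: bool = True
                      ) -> tuple[Recording, SegmentFlags]:
    """Flag channels poorly correlated with their neighbors; repair by neighbor mean.

    A channel is flagged when its best Pearson correlation with any montage
    neighbor falls below ``r_min`` (flat channels have undefined correlation,
    treated as 0, hence always flagged).  Flagged channels are replaced by
    the mean of their unflagged neighbors — a simpler stand-in for spherical
    spline interpolation; channels with no unflagged neighbor are left as-is
    but reported.

    Returns the (possibly repaired) recording and the flags.
    """
    missing = set(recording.channel_names) - set(montage.channel_names)
    if missing:
        raise ValueError(f"montage does not cover channels: {sorted(missing)}")
    data = recording.data
    sd = data.std(axis=1)
    bad = []
    for ci, ch in enumerate(recording.channel_names):
        neigh = [n for n in montage.neighbors(ch) if n in recording.channel_names]
        if not neigh:
            bad.append(ch)
            continue
        if sd[ci] == 0:
            bad.append(ch)
            continue
        best = -1.0
        for n in neigh:
            nj = recording.channel_names.index(n)
            r = 0.0 if sd[nj] == 0 else float(np.corrcoef(data[ci], data[nj])[0, 1])
            best = max(best, r)
        if best < r_min:
            bad.append(ch)
    flags = SegmentFlags(bad_channels=list(bad))
    if not (interpolate and bad):
        return recording, flags
    repaired = data.copy()
    bad_set = set(bad)
    for ch in bad:
        ci = recording.channel_names.index(ch)
        donors = [recording.channel_names.index(n) for n in montage.neighbors(ch)
                  if n in recording.channel_names and n not in bad_set]
        if donors:
            repaired[ci] = data[donors].mean(axis=0)
    return recording.with_data(repaired), flags


def _merge_intervals(intervals: list, min_gap: float = 0.0) -> list:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1] + min_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(iv) for iv in merged]


def detect_bad_segments(recording: Recording, low_band: tuple = (1.0, 15.0),
                        high_band: tuple = (15.0, 45.0), n_sd: float = 3.0,
                        high_thresh_uv: float = 40.0, pad_s: float = 0.2
                        ) -> SegmentFlags:
    """Two-band amplitude-threshold artifact segment detection.

    Low-frequency band (1–15 Hz): samples whose absolute filtered amplitude
    exceeds the channel's mean + ``n_sd``·SD are marked (an individual,
    signal-scaled threshold).  High-frequency band (15–45 Hz): a constant
    ``high_thresh_uv`` µV threshold, since high-frequency noise is smaller in
    amplitude.  Marks are dilated by ``pad_s`` seconds, merged across
    channels and bands, and summed; recordings with more than 60 s total are
    flagged for review (flag only — no manual step is modeled).
    """
    if recording.duration < 10.0:
        raise ValueError("recording must be at least 10 s for segment detection")
    fs = recording.fs
    lo = butter_bandpass(recording.data, *low_band, fs)
    hi = butter_bandpass(recording.data, *high_band, fs)
    # "mean + 3 SD of the filtered signal": the filtered mean is ~0, so for
    # Gaussian data the per-sample marked fraction approximates P(|z| > 3).
    thr_lo = lo.mean(axis=1, keepdims=True) + n_sd * lo.std(axis=1, keepdims=True)
    marked = (np.abs(lo) > thr_lo) | (np.abs(hi) > high_thresh_uv)
    any_marked = marked.any(axis=0)
    intervals = []
    in_run = False
    for i, m in enumerate(any_marked):
        if m and not in_run:
            start, in_run = i, True
        elif not m and in_run:
            intervals.append((start / fs - pad_s, i / fs + pad_s))
            in_run = False
    if in_run:
        intervals.append((start / fs - pad_s, recording.duration + pad_s))
    intervals = [(max(0.0, s), min(recording.duration, e)) for s, e in intervals]
    merged = _merge_intervals(intervals)
    total = float(sum(e - s for s, e in merged))
    return SegmentFlags(bad_intervals=merged, total_bad_s=total,
                        needs_review=total > REVIEW_THRESHOLD_S)
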