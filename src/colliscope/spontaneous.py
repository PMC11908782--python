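"""Spontaneous calcium-event detection in stimulus-free recordings.

Traces from nonresponsive cells are first detrended with a low-order
polynomial (photobleaching correction), then scored frame by frame
against a trailing 1-s sliding baseline: z = (x - mean) / SD over the
preceding window (29 frames at 29.9 Hz).  Frames with z strictly
greater than 3 mark events; consecutive supra-threshold frames merge
into one event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EventTable",
    "detrend_polynomial",
    "detect_events",
    "sliding_window_frames",
    "DEFAULT_WINDOW_S",
    "DEFAULT_Z_THRESHOLD",
    "DEFAULT_DETREND_ORDER",
]

DEFAULT_WINDOW_S = 1.0
DEFAULT_Z_THRESHOLD = 3.0
DEFAULT_DETREND_ORDER = 2


@dataclass
class EventTable:
    """Detected events for one trace, with the parameters used."""

    events: pd.DataFrame  # onset_frame, peak_z, duration_frames
    window_s: float
    z_threshold: float
    frame_rate_hz: float
    n_frames: int

    @property
    def n_events(self) -> int:
        return len(self.events)

    def rate_per_min(self) -> float:
        minutes = self.n_frames / self.frame_rate_hz / 60.0
        return self.n_events / minutes if minutes > 0 else np.nan


def sliding_window_frames(window_s: float, frame_rate_hz: float) -> int:
    """Frames in the sliding baseline window (floor; 29 at 29.9 Hz)."""
    n = int(window_s * frame_rate_hz)
    if n < 2:
        raise ValueError("window too short for the frame rate")
    return n


def detrend_polynomial(trace: np.ndarray, order: int = DEFAULT_DETREND_ORDER) -> np.ndarray:
    """Subtract a least-squares polynomial trend, preserving the level.

    The fitted polynomial is removed and its value at t=0 (the
    constant term) added back, so a constant trace passes through
    unchanged and the corrected trace keeps the original baseline
    level.
    """
    trace = np.asarray(trace, dtype=float)
    if order < 0:
        raise ValueError("order must be >= 0")
    if order >= trace.size - 1:
        raise ValueError(f"order {order} too high for trace of length {trace.size}")
    t = np.arange(trace.size, dtype=float)
    coef = np.polynomial.polynomial.polyfit(t, trace, order)
    fit = np.polynomial.polynomial.polyval(t, coef)
    return trace - fit + coef[0]


def detect_events(
    trace: np.ndarray,
    frame_rate_hz: float,
    window_s: float = DEFAULT_WINDOW_S,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    sd_mode: str = "window",
) -> EventTable:
    """Detect spontaneous transients by trailing-window z-score.

    For each frame after the initial window, z is the frame's
    deviation from the mean of the preceding ``window_s`` of data,
    scaled by that window's SD (``sd_mode='window'``) or by the global
    trace SD (``sd_mode='global'``).  An event is a maximal run of
    frames with z strictly above the threshold.  Frames whose window
    SD is zero are skipped.
    """
    trace = np.asarray(trace, dtype=float)
    w = sliding_window_frames(window_s, frame_rate_hz)
    if trace.size <= w:
        raise ValueError("trace shorter than the sliding window")
    windows = np.lib.stride_tricks.sliding_window_view(trace, w)[:-1]  # window ending before each scored frame
    means = windows.mean(axis=1)
    if sd_mode == "window":
        sds = windows.std(axis=1, ddof=0)
    elif sd_mode == "global":
        sds = np.full(windows.shape[0], trace.std(ddof=0))
    else:
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    scored = trace[w:]
    z = np.full(scored.size, -np.inf)
    ok = sds > 0
    if not ok.all():
        logger.info("%d frames skipped (zero sliding SD)", (~ok).sum())
    z[ok] = (scored[ok] - means[ok]) / sds[ok]

    above = z > z_threshold
    rows = []
    i = 0
    while i < above.size:
        if above[i]:
            j = i
            while j + 1 < above.size and above[j + 1]:
                j += 1
            rows.append(
                {
                    "onset_frame": i + w,
                    "peak_z": float(z[i : j + 1].max()),
                    "duration_frames": j - i + 1,
                }
            )
            i = j + 1
        else:
            i += 1
    events = pd.DataFrame(rows, columns=["onset_frame", "peak_z", "duration_frames"])
    return EventTable(events, window_s, z_threshold, frame_rate_hz, trace.size)
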