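"""Collapsing raw activity counts into epochs.

Classical actigraphic scoring starts by "collapsing" the device's count
series into scoring epochs: each epoch value is the maximum or the mean
of the counts inside a window (e.g. the largest 10-second count within
each minute).  Collapsing is downsampling with a non-standard sample
selection; done without a preceding low-pass stage it can alias
above-Nyquist movement rhythms into the epoch series, so an optional
anti-aliasing pre-filter is provided.  It is off by default because the
published algorithms were derived from, and must be reproduced with, the
raw collapsing procedure.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .types import ActivitySeries, EpochSeries

__all__ = ["collapse", "antialias_then_collapse"]

_METRICS = {"max": np.max, "mean": np.mean}


def _window_samples(series: ActivitySeries, seconds: float, what: str) -> int:
    n = seconds / series.sample_interval
    n_round = round(n)
    if abs(n - n_round) > 1e-9 or n_round < 1:
        raise ValueError(
            f"incommensurate window: {what} of {seconds} s is not a positive "
            f"integer multiple of the {series.sample_interval} s sample interval"
        )
    return int(n_round)


def collapse(
    series: ActivitySeries,
    metric: str,
    window_length: float,
    step: float | None = None,
) -> EpochSeries:
    """Collapse an activity series into epochs.

    Parameters
    ----------
    series
        Input counts.
    metric
        ``"max"`` or ``"mean"``: the statistic taken over each window.
    window_length
        Window width in seconds; must be an integer multiple of the
        sample interval.
    step
        Hop between consecutive windows in seconds (defaults to
        ``window_length``, i.e. non-overlapping).  ``step <
        window_length`` yields overlapping epochs, one value per step,
        time-stamped at the window start.  Trailing samples that do not
        fill a complete window are discarded.

    Returns
    -------
    EpochSeries
        ``floor((n_samples - window + step) / step)`` epoch values.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown collapse metric {metric!r}")
    if step is None:
        step = window_length
    w = _window_samples(series, window_length, "window")
    s = _window_samples(series, step, "step")
    n = len(series)
    if w > n:
        raise ValueError(
            f"series too short: window of {w} samples exceeds series of {n}"
        )
    windows = sliding_window_view(series.values, w)[::s]
    func = _METRICS[metric]
    values = func(windows, axis=1)
    return EpochSeries(
        values=values,
        epoch_length=float(step),
        collapse_metric=metric,
        window_length=float(window_length),
        overlapping=s < w,
        start_time=series.start_time,
    )


def antialias_then_collapse(
    series: ActivitySeries,
    metric: str,
    window_length: float,
    step: float | None = None,
    enable_prefilter: bool = False,
    filter_order: int = 4,
) -> EpochSeries:
    """Collapse with an optional low-pass stage at the post-collapse Nyquist.

    With ``enable_prefilter`` false this is exactly :func:`collapse`,
    reproducing the original (aliasing-prone) procedures.  With it true,
    a zero-phase Butterworth low-pass with cutoff at half the output
    epoch rate is applied to the counts first.  Filtered counts are
    clipped at zero (a low-pass stage can undershoot, but counts are
    non-negative by construction).
    """
    if not enable_prefilter:
        return collapse(series, metric, window_length, step)
    if step is None:
        step = window_length
    _window_samples(series, window_length, "window")  # validate early
    s = _window_samples(series, step, "step")
    nyquist_in = 0.5 / series.sample_interval
    cutoff_hz = 0.5 / (s * series.sample_interval)
    if cutoff_hz >= nyquist_in:
        filtered = series.values  # nothing to remove: output rate == input rate
        label = None
    else:
        sos = signal.butter(filter_order, cutoff_hz / nyquist_in, output="sos")
        filtered = signal.sosfiltfilt(sos, series.values)
        filtered = np.clip(filtered, 0.0, None)
        label = f"butterworth(order={filter_order}, cutoff={cutoff_hz:g} Hz, zero-phase)"
    prefiltered = ActivitySeries(
        values=filtered,
        sample_interval=series.sample_interval,
        mode_tag=series.mode_tag,
        start_time=series.start_time,
    )
    out = collapse(prefiltered, metric, window_length, step)
    return EpochSeries(
        values=out.values,
        epoch_length=out.epoch_length,
        collapse_metric=out.collapse_metric,
        window_length=out.window_length,
        overlapping=out.overlapping,
        prefilter=label,
        start_time=out.start_time,
    )
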