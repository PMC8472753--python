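"""Core containers for actigraphic scoring pipelines.

The processing chain is: raw activity counts (:class:`ActivitySeries`)
are collapsed into epochs (:class:`EpochSeries`), convolved with a
scoring kernel (:class:`ScoringKernel`) to yield a score trace
(:class:`ScoreSeries`), and thresholded into a per-epoch hypnogram
(:class:`SleepWakeSeries`).  :class:`TransmittanceProfile` holds the
frequency response of a kernel for spectral analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime

import numpy as np

__all__ = [
    "SLEEP",
    "WAKE",
    "MODE_TAGS",
    "ActivitySeries",
    "EpochSeries",
    "ScoringKernel",
    "ScoreSeries",
    "SleepWakeSeries",
    "TransmittanceProfile",
]

SLEEP: int = 0
WAKE: int = 1

MODE_TAGS = frozenset({"ZCM", "TAT", "DI", "raw", "unknown"})


def _as_float_array(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a one-dimensional series")
    return arr


@dataclass(frozen=True)
class ActivitySeries:
    """Raw activity counts sampled at a fixed interval.

    Parameters
    ----------
    values
        Non-negative activity counts, one per sample.  Counts are the
        device-level summary of movement intensity within each sampling
        interval (zero crossings, time above threshold, or digital
        integration, depending on the acquisition mode).
    sample_interval
        Seconds between consecutive samples (> 0).
    mode_tag
        Acquisition mode: one of ``ZCM``, ``TAT``, ``DI``, ``raw``,
        ``unknown``.
    start_time
        Optional wall-clock time of the first sample.
    """

    values: np.ndarray
    sample_interval: float
    mode_tag: str = "unknown"
    start_time: datetime | None = None

    def __post_init__(self) -> None:
        arr = _as_float_array(self.values)
        if not np.all(np.isfinite(arr)):
            raise ValueError("activity counts must be finite")
        if arr.size and arr.min() < 0:
            raise ValueError("activity counts must be non-negative")
        if not self.sample_interval > 0:
            raise ValueError("sample_interval must be strictly positive")
        if self.mode_tag not in MODE_TAGS:
            raise ValueError(f"unknown mode_tag {self.mode_tag!r}")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Total covered time in seconds."""
        return self.values.size * self.sample_interval


@dataclass(frozen=True)
class EpochSeries:
    """Counts collapsed into epochs.

    ``collapse_metric`` records how each epoch value was obtained from
    its source window (``max``, ``mean`` or ``identity`` for a pure
    relabelling), ``window_length`` the window width in seconds and
    ``overlapping`` whether successive windows overlapped.  ``prefilter``
    names the anti-aliasing filter applied before collapsing, if any.
    """

    values: np.ndarray
    epoch_length: float
    collapse_metric: str = "identity"
    window_length: float = 0.0
    overlapping: bool = False
    prefilter: str | None = None
    start_time: datetime | None = None

    def __post_init__(self) -> None:
        arr = _as_float_array(self.values)
        if not self.epoch_length > 0:
            raise ValueError("epoch_length must be strictly positive")
        if self.collapse_metric not in {"max", "mean", "identity"}:
            raise ValueError(f"unknown collapse_metric {self.collapse_metric!r}")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class ScoringKernel:
    """A two-sided FIR scoring kernel with threshold semantics.

    The score for epoch ``n`` is::

        score[n] = bias + scale * sum_{i=-F..P} w[i] * X[n - i]

    where ``i > 0`` indexes past epochs, ``i < 0`` future epochs,
    ``F = future_span`` and ``P = past_span``.  ``coefficients`` stores
    ``w`` ordered by increasing lag ``i = -F .. P``.  The equivalent
    causal filter has order ``K = F + P`` and pure delay ``F``.

    ``scale`` is the global multiplicative constant published with each
    algorithm (it sets the "weakening", i.e. the DC gain together with
    the coefficient sum) and ``bias`` an additive constant (zero for the
    Cole-Kripke family, the logistic intercept for Sazonov).  Labels are
    assigned by comparing the score against ``threshold``: with
    ``wake_above`` true, strictly greater means wake; otherwise strictly
    smaller means wake.  Ties always resolve to sleep.
    """

    coefficients: np.ndarray
    future_span: int
    past_span: int
    scale: float = 1.0
    bias: float = 0.0
    threshold: float = 1.0
    wake_above: bool = True
    algorithm_name: str = ""
    variant: str = ""
    domain_tag: str = "D"
    epoch_length: float = 60.0
    collapse: tuple = ()
    citation: str = ""
    synthetic: bool = False

    def __post_init__(self) -> None:
        arr = _as_float_array(self.coefficients)
        if self.future_span < 0 or self.past_span < 0:
            raise ValueError("spans must be non-negative")
        if arr.size != self.future_span + self.past_span + 1:
            raise ValueError(
                "coefficient vector length must equal future_span + past_span + 1"
            )
        if not np.any(arr != 0):
            raise ValueError("kernel needs at least one non-zero coefficient")
        if not np.all(np.isfinite(arr)):
            raise ValueError("coefficients must be finite")
        object.__setattr__(self, "coefficients", arr)

    @property
    def order(self) -> int:
        """Order of the equivalent causal FIR filter (taps minus one)."""
        return self.future_span + self.past_span

    @property
    def effective_coefficients(self) -> np.ndarray:
        """``scale`` folded into the coefficient vector."""
        return self.scale * self.coefficients

    @property
    def dc_gain(self) -> float:
        """Response to a constant input (scale times coefficient sum)."""
        return float(self.scale * self.coefficients.sum())

    @property
    def name(self) -> str:
        return f"{self.algorithm_name}-{self.variant}" if self.variant else self.algorithm_name

    def with_(self, **changes) -> "ScoringKernel":
        return replace(self, **changes)


@dataclass(frozen=True)
class ScoreSeries:
    """Per-epoch scores emitted by a kernel.

    Scores exist only where the kernel has full support: the first score
    corresponds to input epoch ``start_index`` (= past span) and the
    last to ``n_input - 1 - future span``.
    """

    values: np.ndarray
    domain_tag: str = "D"
    start_index: int = 0
    n_input: int | None = None

    def __post_init__(self) -> None:
        arr = _as_float_array(self.values)
        if self.domain_tag == "probability" and arr.size:
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError("probability scores must lie in [0, 1]")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size

    @property
    def epoch_indices(self) -> np.ndarray:
        """Indices into the source epoch series for each score."""
        return np.arange(self.start_index, self.start_index + self.values.size)


@dataclass(frozen=True)
class SleepWakeSeries:
    """Binary per-epoch labels: 0 = sleep, 1 = wake."""

    labels: np.ndarray
    rescored: bool = False
    start_index: int = 0
    epoch_length: float = 60.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels, dtype=np.int8)
        if arr.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if arr.size and not np.isin(arr, (SLEEP, WAKE)).all():
            raise ValueError("labels must be 0 (sleep) or 1 (wake)")
        object.__setattr__(self, "labels", arr)

    def __len__(self) -> int:
        return self.labels.size

    @property
    def wake_fraction(self) -> float:
        return float(self.labels.mean()) if self.labels.size else float("nan")

    def transitions(self) -> int:
        """Number of sleep/wake state changes along the series."""
        if self.labels.size < 2:
            return 0
        return int(np.count_nonzero(np.diff(self.labels)))


@dataclass(frozen=True)
class TransmittanceProfile:
    """Magnitude response |H| of a scoring kernel on a frequency grid."""

    frequencies_hz: np.ndarray
    magnitude: np.ndarray
    dc_gain: float
    epoch_length: float
    unit: str = "Hz"
    kernel_name: str = ""
    cutoff_hz: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        f = _as_float_array(self.frequencies_hz)
        m = _as_float_array(self.magnitude)
        if f.size != m.size:
            raise ValueError("frequency and magnitude grids differ in length")
        if m.size and m.min() < 0:
            raise ValueError("|H| cannot be negative")
        object.__setattr__(self, "frequencies_hz", f)
        object.__setattr__(self, "magnitude", m)
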