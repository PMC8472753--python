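"""The Sadeh scoring algorithms: a linear FIR part plus nonlinear features.

The Sadeh sleep/wake scores do not reduce to a pure convolution: the
score for epoch ``n`` is::

    PS[n] = (linear FIR part) + sum_k C_k * phi_n(k) + d

where the ``phi_n`` are nonlinear window features — a windowed standard
deviation, a band-count ("NAT": the number of nearby epochs whose
activity falls inside a configured band), and a log transform of the
current epoch.  Only the linear part (for the 1994 variant, an 11-point
centered moving average, i.e. an order-10 FIR filter advanced by 5
samples) is amenable to transfer-function analysis; the nonlinear
features act as edge detectors that suppress brief movement transients.

The 1994 variant ships with its published weights::

    PS = 7.601 - 0.065*MW - 1.08*NAT - 0.056*SD - 0.703*LG

    MW  = mean of the 11 epochs centered on n
    NAT = count of epochs in that window with activity in [50, 100)
    SD  = standard deviation of epoch n and the 5 preceding epochs
    LG  = ln(activity[n] + 1)

``PS >= 0`` scores sleep.  The standard deviation uses the sample
(n-1) divisor; the log transform uses a +1 offset so that zero activity
is well defined.  Both choices are recorded in the variant config.

The 1989 variant's published weights could not be sourced; its config
ships a synthetic surrogate (order-0 FIR plus SD/NAT/log features,
matching the documented structure) so the machinery is exercised, and
is clearly marked as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import EpochSeries, ScoreSeries, ScoringKernel

__all__ = [
    "SadehFeatureSet",
    "VARIANTS",
    "sadeh_features",
    "sadeh_score",
    "sadeh_linear_kernel",
    "sadeh_threshold",
]


@dataclass(frozen=True)
class SadehFeatureSet:
    """Feature values entering one epoch's Sadeh score."""

    window_mean: float
    window_sd: float
    nat_count: int
    log_term: float
    extra_terms: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.window_sd < 0:
            raise ValueError("window_sd cannot be negative")
        if self.nat_count < 0:
            raise ValueError("nat_count cannot be negative")


# Variant definitions.  Window conventions: mean_window = (before, after)
# epochs around n inclusive of n; sd_window likewise; NAT band is
# [low, high).  Weights multiply (mean, sd, nat, log); d is the constant.
VARIANTS: dict[str, dict] = {
    "1994": {
        "mean_window": (5, 5),
        "sd_window": (5, 0),
        "nat_window": (5, 5),
        "nat_band": (50.0, 100.0),
        "sd_ddof": 1,
        "weights": {"mean": -0.065, "sd": -0.056, "nat": -1.08, "log": -0.703},
        "d": 7.601,
        "synthetic": False,
    },
    # SYNTHETIC SURROGATE: structure per the 1989 description (order-0
    # FIR, SD-dominated nonlinear terms), weights invented for exercising
    # the machinery only.  Any number computed from it characterizes the
    # surrogate, not the published 1989 rule.
    "1989": {
        "mean_window": (0, 0),
        "sd_window": (5, 0),
        "nat_window": (5, 5),
        "nat_band": (50.0, 100.0),
        "sd_ddof": 1,
        "weights": {"mean": -0.05, "sd": -0.05, "nat": -0.5, "log": -0.5},
        "d": 4.0,
        "synthetic": True,
    },
}


def _variant(variant: str) -> dict:
    try:
        return VARIANTS[str(variant)]
    except KeyError:
        raise ValueError(f"unsupported Sadeh variant {variant!r}") from None


def _support(cfg: dict) -> tuple[int, int]:
    before = max(cfg["mean_window"][0], cfg["sd_window"][0], cfg["nat_window"][0])
    after = max(cfg["mean_window"][1], cfg["sd_window"][1], cfg["nat_window"][1])
    return before, after


def sadeh_features(epochs: EpochSeries, variant: str, n: int) -> SadehFeatureSet:
    """Compute the feature set for epoch ``n`` (full support required)."""
    cfg = _variant(variant)
    x = epochs.values
    before, after = _support(cfg)
    if n - before < 0 or n + after >= x.size:
        raise ValueError(
            f"epoch window out of range: epoch {n} needs {before} before and "
            f"{after} after within {x.size} epochs"
        )
    mb, ma = cfg["mean_window"]
    sb, sa = cfg["sd_window"]
    nb, na = cfg["nat_window"]
    lo, hi = cfg["nat_band"]
    mean_seg = x[n - mb : n + ma + 1]
    sd_seg = x[n - sb : n + sa + 1]
    nat_seg = x[n - nb : n + na + 1]
    return SadehFeatureSet(
        window_mean=float(mean_seg.mean()),
        window_sd=float(sd_seg.std(ddof=cfg["sd_ddof"])) if sd_seg.size > 1 else 0.0,
        nat_count=int(np.count_nonzero((nat_seg >= lo) & (nat_seg < hi))),
        log_term=float(np.log(x[n] + 1.0)),
    )


def sadeh_score(epochs: EpochSeries, variant: str = "1994") -> ScoreSeries:
    """Score every epoch with full window support (vectorised)."""
    cfg = _variant(variant)
    x = epochs.values
    before, after = _support(cfg)
    span = before + after + 1
    if x.size < span:
        raise ValueError(
            f"epoch window out of range: variant {variant} needs {span} epochs, "
            f"series has {x.size}"
        )
    idx = np.arange(before, x.size - after)
    w = cfg["weights"]

    def windowed(fn, wb, wa):
        width = wb + wa + 1
        from numpy.lib.stride_tricks import sliding_window_view

        views = sliding_window_view(x, width)
        # window centered on n starts at n - wb; valid n from the sliding
        # view are realigned onto the common support range.
        return fn(views[idx - wb])

    mb, ma = cfg["mean_window"]
    mean_t = windowed(lambda v: v.mean(axis=1), mb, ma)
    sb, sa = cfg["sd_window"]
    if sb + sa + 1 > 1:
        sd_t = windowed(lambda v: v.std(axis=1, ddof=cfg["sd_ddof"]), sb, sa)
    else:
        sd_t = np.zeros(idx.size)
    nb, na = cfg["nat_window"]
    lo, hi = cfg["nat_band"]
    nat_t = windowed(lambda v: ((v >= lo) & (v < hi)).sum(axis=1), nb, na)
    log_t = np.log(x[idx] + 1.0)

    ps = (
        cfg["d"]
        + w["mean"] * mean_t
        + w["sd"] * sd_t
        + w["nat"] * nat_t
        + w["log"] * log_t
    )
    return ScoreSeries(values=ps, domain_tag="PS", start_index=before, n_input=x.size)


def sadeh_linear_kernel(variant: str = "1994", include_weight: bool = False) -> ScoringKernel:
    """The FIR part of a Sadeh score as a :class:`ScoringKernel`.

    For the 1994 variant this is the order-10 moving-average filter with
    all 11 coefficients equal to 1/11, centered (5 future and 5 past
    taps).  With ``include_weight`` the published mean-term weight is
    applied as the kernel scale; without it the kernel computes the
    plain centered 11-epoch mean.
    """
    cfg = _variant(variant)
    if variant != "1994":
        raise ValueError(f"unsupported variant {variant!r}: only 1994 has a published FIR part")
    mb, ma = cfg["mean_window"]
    width = mb + ma + 1
    return ScoringKernel(
        coefficients=np.full(width, 1.0 / width),
        future_span=ma,
        past_span=mb,
        scale=cfg["weights"]["mean"] if include_weight else 1.0,
        bias=0.0,
        threshold=0.0,
        wake_above=False,
        algorithm_name="sadeh_linear",
        variant=variant,
        domain_tag="PS",
        epoch_length=60.0,
        collapse=(("mean", 60.0, 60.0),),
        citation="Sadeh A, Sharkey KM, Carskadon MA (1994). Activity-based "
        "sleep-wake identification: an empirical test of methodological issues. "
        "Sleep 17(3):201-207.",
        synthetic=cfg["synthetic"],
    )


def sadeh_threshold(scores: ScoreSeries, epoch_length: float = 60.0):
    """Label Sadeh scores: PS >= 0 scores sleep, PS < 0 wake."""
    from .types import SLEEP, WAKE, SleepWakeSeries

    labels = np.where(scores.values < 0, WAKE, SLEEP)
    return SleepWakeSeries(
        labels=labels, rescored=False, start_index=scores.start_index,
        epoch_length=epoch_length,
    )
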