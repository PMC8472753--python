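"""The common convolution scorer.

Every algorithm of the Cole-Kripke family (Cole-Kripke, Webster, UCSD,
Scripps Clinic) and the Sazonov logistic model computes, after epoch
collapsing, a weighted sum of nearby epochs::

    score[n] = bias + scale * sum_{i=-F..P} w[i] * X[n - i]

which is a two-sided FIR filter: shifting indices gives an ordinary
causal filter of order ``F + P`` whose output, advanced by ``F``
samples, reproduces the two-sided score exactly.  Thresholding the
score yields the sleep/wake label.  Sazonov's probability output maps
onto the same scheme through the logit transform, which also lets the
logistic intercept be folded into the decision threshold.
"""

from __future__ import annotations

import numpy as np
from scipy import signal, special

from .types import SLEEP, WAKE, EpochSeries, ScoreSeries, ScoringKernel, SleepWakeSeries

__all__ = [
    "score_convolve",
    "as_causal_fir",
    "threshold_labels",
    "score",
    "sazonov_alpha",
    "sazonov_alpha_inverse",
    "fold_bias_into_threshold",
    "score_multi_channel",
]


def as_causal_fir(kernel: ScoringKernel) -> tuple[np.ndarray, int]:
    """Return the causal coefficient vector ``b(0..K)`` and its delay.

    ``b[j] = w[j - F]`` for ``j = 0..K`` with ``K = F + P``; filtering
    causally with ``b`` and advancing the output by ``F`` samples
    reproduces :func:`score_convolve` exactly on the shared valid range.
    ``scale`` is folded into ``b``; ``bias`` is not (it is an additive
    constant, not a tap).
    """
    return kernel.effective_coefficients.copy(), kernel.future_span


def score_convolve(epochs: EpochSeries, kernel: ScoringKernel) -> ScoreSeries:
    """Convolve an epoch series with a scoring kernel.

    Scores are emitted only for epochs with full kernel support: the
    first ``past_span`` and last ``future_span`` epochs yield no score
    (no padding convention is ever fabricated).
    """
    x = epochs.values
    span = kernel.order + 1
    if len(x) < span:
        raise ValueError(
            f"insufficient epochs: kernel spans {span}, series has {len(x)}"
        )
    # score[n] = sum_i w[i] X[n-i] == full-convolution of X with the
    # lag-ordered coefficient vector, evaluated where overlap is complete.
    values = np.convolve(x, kernel.effective_coefficients, mode="valid")
    values = values + kernel.bias
    return ScoreSeries(
        values=values,
        domain_tag=kernel.domain_tag,
        start_index=kernel.past_span,
        n_input=len(x),
    )


def threshold_labels(scores: ScoreSeries, kernel: ScoringKernel) -> SleepWakeSeries:
    """Binarise scores; ties at the threshold always label sleep."""
    v = scores.values
    if kernel.wake_above:
        wake = v > kernel.threshold
    else:
        wake = v < kernel.threshold
    labels = np.where(wake, WAKE, SLEEP)
    return SleepWakeSeries(
        labels=labels,
        rescored=False,
        start_index=scores.start_index,
        epoch_length=kernel.epoch_length,
    )


def score(epochs: EpochSeries, kernel: ScoringKernel) -> tuple[ScoreSeries, SleepWakeSeries]:
    """Convenience: convolve then threshold."""
    s = score_convolve(epochs, kernel)
    return s, threshold_labels(s, kernel)


def sazonov_alpha(p):
    """Logit transform ``alpha = ln(p / (1 - p))`` of a probability.

    The logistic model's probability threshold ``p > 0.5`` is equivalent
    to ``alpha > 0``, which is what makes the model a member of the
    linear-scoring family.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("logit undefined at boundary: need 0 < p < 1")
    out = special.logit(p)
    return float(out) if out.ndim == 0 else out


def sazonov_alpha_inverse(alpha):
    """Inverse logit: map a real score back to a probability in (0, 1)."""
    out = special.expit(np.asarray(alpha, dtype=float))
    return float(out) if out.ndim == 0 else out


def fold_bias_into_threshold(kernel: ScoringKernel) -> ScoringKernel:
    """Eliminate the additive constant by shifting the threshold.

    ``bias + L > t  <=>  L > t - bias`` (and likewise for the
    wake-below direction), so labels are unchanged on any input.
    Idempotent.
    """
    if kernel.bias == 0:
        return kernel
    return kernel.with_(bias=0.0, threshold=kernel.threshold - kernel.bias)


def score_multi_channel(
    channels: list[tuple[EpochSeries, ScoringKernel]],
    bias: float = 0.0,
) -> ScoreSeries:
    """Sum single-channel FIR scores over differently collapsed inputs.

    Supports multi-channel logistic configurations in which one score is
    a linear combination of convolutions of several collapse variants of
    the same recording (e.g. a per-epoch maximum channel plus a mean
    channel), with a single shared additive constant.  All channels must
    produce equally many epochs.
    """
    if not channels:
        raise ValueError("need at least one channel")
    n = {len(e) for e, _ in channels}
    if len(n) != 1:
        raise ValueError("channels must have equal epoch counts")
    parts = []
    start = 0
    for epochs, kernel in channels:
        s = score_convolve(epochs, kernel.with_(bias=0.0))
        parts.append(s)
        start = max(start, kernel.past_span)
    end = min(s.start_index + len(s) for s in parts)
    total = None
    for s in parts:
        seg = s.values[start - s.start_index : end - s.start_index]
        total = seg if total is None else total + seg
    return ScoreSeries(values=total + bias, domain_tag="alpha", start_index=start, n_input=n.pop())


def causal_filter_scores(epochs: EpochSeries, kernel: ScoringKernel) -> ScoreSeries:
    """Score via ``scipy.signal.lfilter`` on the causal form plus delay
    compensation.  Numerically identical to :func:`score_convolve`; kept
    as an independent route for verification and streaming use.
    """
    b, delay = as_causal_fir(kernel)
    x = epochs.values
    if len(x) < b.size:
        raise ValueError("insufficient epochs")
    y = signal.lfilter(b, [1.0], x)
    # y[m] holds sum_j b[j] x[m-j]; full support from m = K onward.
    valid = y[kernel.order :] + kernel.bias
    return ScoreSeries(
        values=valid,
        domain_tag=kernel.domain_tag,
        start_index=kernel.past_span,
        n_input=len(x),
    )
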