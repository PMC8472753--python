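"""Synthetic actigraphy generator with known sleep/wake architecture.

Emulates the one property the scoring algorithms rely on: movement
intensity differs sharply between wake and sleep.  Counts are drawn from
a non-negative integer distribution (Poisson by default, matching the
counting nature of ZCM/DI acquisition) with a state-dependent mean, and
short elevated-rate movement bursts are injected into sleep so that
thresholding produces isolated wake-scored epochs for the rescoring
rules to clean up.  The ground-truth hypnogram is constructed, not
sampled, so agreement accounting against it is exact.

This is a test-harness generator: no circadian modulation, no sleep
stage microstructure, no device-specific count calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fir import score_convolve, threshold_labels
from .presets import epochs_for_kernel, table1_presets
from .types import SLEEP, WAKE, ActivitySeries, ScoringKernel, SleepWakeSeries

__all__ = ["SimulationConfig", "generate", "roundtrip_check"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic recording.

    Defaults describe an 8-hour night sampled at the classical 10-s
    device interval: lights-off wake of 30 min, one brief nocturnal
    awakening, early waking before getting up.  Wake movement averages
    150 counts per sample against 0.2 during sleep: strongly separated,
    as in wrist actigraphy of healthy sleepers, and on a count scale on
    which the published thresholds (normalized so that wake scores
    exceed them) sit between the sleep and wake score levels for every
    shipped algorithm.  Two brief movement bursts per hour of sleep.
    """

    total_duration: float = 28_800.0
    sample_interval: float = 10.0
    wake_bouts: tuple = ((0.0, 1_800.0), (14_400.0, 600.0), (27_000.0, 1_800.0))
    wake_count_mean: float = 150.0
    sleep_count_mean: float = 0.2
    burst_rate: float = 2.0
    burst_duration: float = 60.0
    burst_count_mean: float = 150.0
    noise_family: str = "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_duration <= 0 or self.sample_interval <= 0:
            raise ValueError("durations must be positive")
        if self.sleep_count_mean >= self.wake_count_mean:
            raise ValueError("sleep_count_mean must be below wake_count_mean")
        if self.sleep_count_mean < 0 or self.burst_rate < 0 or self.burst_duration <= 0:
            raise ValueError("rates must be non-negative, durations positive")
        if self.noise_family not in {"poisson"}:
            raise ValueError(f"unknown noise_family {self.noise_family!r}")
        for start, dur in self.wake_bouts:
            if dur < 0 or start < 0 or start + dur > self.total_duration:
                raise ValueError("wake bouts must lie within total_duration")


def generate(config: SimulationConfig) -> tuple[ActivitySeries, SleepWakeSeries]:
    """Generate counts and the exact sample-resolution ground truth."""
    rng = np.random.default_rng(config.seed)
    n = int(round(config.total_duration / config.sample_interval))
    truth = np.full(n, SLEEP, dtype=np.int8)
    t = np.arange(n) * config.sample_interval
    for start, dur in config.wake_bouts:
        truth[(t >= start) & (t < start + dur)] = WAKE

    lam = np.where(truth == WAKE, config.wake_count_mean, config.sleep_count_mean)

    # movement bursts: brief elevated-rate segments inside sleep; they do
    # not change the ground truth (they are sleep movement artifacts)
    sleep_idx = np.nonzero(truth == SLEEP)[0]
    if config.burst_rate > 0 and sleep_idx.size:
        sleep_hours = sleep_idx.size * config.sample_interval / 3600.0
        n_bursts = rng.poisson(config.burst_rate * sleep_hours)
        burst_samples = max(1, int(round(config.burst_duration / config.sample_interval)))
        starts = rng.choice(sleep_idx, size=n_bursts, replace=True) if n_bursts else []
        for s in np.sort(starts):
            seg = slice(s, min(s + burst_samples, n))
            lam[seg] = np.where(
                truth[seg] == SLEEP, config.burst_count_mean, lam[seg]
            )

    counts = rng.poisson(lam).astype(float)
    series = ActivitySeries(
        values=counts, sample_interval=config.sample_interval, mode_tag="ZCM"
    )
    ground_truth = SleepWakeSeries(
        labels=truth, rescored=False, epoch_length=config.sample_interval
    )
    return series, ground_truth


def _epoch_truth(truth: SleepWakeSeries, epoch_length: float) -> np.ndarray:
    """Majority-vote the sample-resolution truth onto the epoch grid."""
    per_epoch = int(round(epoch_length / truth.epoch_length))
    n_epochs = truth.labels.size // per_epoch
    trimmed = truth.labels[: n_epochs * per_epoch].reshape(n_epochs, per_epoch)
    return (trimmed.mean(axis=1) >= 0.5).astype(np.int8)


def _score_preset(series: ActivitySeries, kernel: ScoringKernel):
    epochs = epochs_for_kernel(series, kernel)
    scores = score_convolve(epochs, kernel)
    return threshold_labels(scores, kernel)


def roundtrip_check(
    config: SimulationConfig, presets: dict[str, ScoringKernel] | None = None
) -> dict:
    """Score a generated recording with each preset and summarise agreement.

    Returns a dict with per-preset epoch-level accuracy against the
    constructed ground truth and the pairwise agreement between preset
    outputs (evaluated on their shared valid range and common epoch
    grid).
    """
    if presets is None:
        presets = table1_presets()
    series, truth = generate(config)
    labelings: dict[str, tuple[np.ndarray, int, float]] = {}
    accuracy: dict[str, float] = {}
    for name, kernel in presets.items():
        labels = _score_preset(series, kernel)
        et = _epoch_truth(truth, kernel.epoch_length)
        sl = labels.labels
        idx = np.arange(labels.start_index, labels.start_index + sl.size)
        idx = idx[idx < et.size]
        accuracy[name] = float((sl[: idx.size] == et[idx]).mean())
        labelings[name] = (sl, labels.start_index, kernel.epoch_length)

    pairwise: dict[tuple[str, str], float] = {}
    names = sorted(labelings)
    for i, a in enumerate(names):
        la, sa, ea = labelings[a]
        for b in names[i + 1 :]:
            lb, sb, eb = labelings[b]
            if ea != eb:  # different epoch grids: compare on the coarser one
                ratio = int(round(max(ea, eb) / min(ea, eb)))
                if ea < eb:
                    la_c = la[: (la.size // ratio) * ratio].reshape(-1, ratio).mean(1) >= 0.5
                    lb_c, off_a, off_b = lb, sa // ratio, sb
                else:
                    lb_c = lb[: (lb.size // ratio) * ratio].reshape(-1, ratio).mean(1) >= 0.5
                    la_c, off_a, off_b = la, sa, sb // ratio
                la2, lb2 = np.asarray(la_c, dtype=np.int8), np.asarray(lb_c, dtype=np.int8)
            else:
                la2, lb2, off_a, off_b = la, lb, sa, sb
            start = max(off_a, off_b)
            end = min(off_a + la2.size, off_b + lb2.size)
            if end <= start:
                continue
            seg_a = la2[start - off_a : end - off_a]
            seg_b = lb2[start - off_b : end - off_b]
            pairwise[(a, b)] = float((seg_a == seg_b).mean())
    return {"accuracy": accuracy, "pairwise": pairwise, "n_samples": len(series)}
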