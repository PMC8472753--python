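"""End-to-end scoring: counts -> epochs -> scores -> labels -> rescoring."""

from __future__ import annotations

from dataclasses import dataclass

from . import sadeh as _sadeh
from .fir import score_convolve, threshold_labels
from .presets import epochs_for_kernel, load_preset
from .rescoring import apply_rules, load_rules
from .types import ActivitySeries, EpochSeries, ScoreSeries, SleepWakeSeries

__all__ = ["ScoringResult", "score_activity"]

_PRESET_RULES = {
    "cole_kripke": "cole",
    "webster": "webster",
}


@dataclass(frozen=True)
class ScoringResult:
    epochs: EpochSeries
    scores: ScoreSeries
    labels: SleepWakeSeries
    rescored: SleepWakeSeries | None


def score_activity(
    series: ActivitySeries,
    algorithm: str,
    variant: str = "",
    rescore: bool = True,
) -> ScoringResult:
    """Score raw counts with a named algorithm.

    ``algorithm`` is a preset name (``cole_kripke``, ``webster``,
    ``ucsd``, ``sazonov``, ``scripps_clinic``) or ``sadeh``; ``variant``
    selects among its published collapse variants where applicable.
    """
    if algorithm == "sadeh":
        variant = variant or "1994"
        kernel = _sadeh.sadeh_linear_kernel("1994")  # for collapse recipe/epoch length
        epochs = epochs_for_kernel(series, kernel)
        scores = _sadeh.sadeh_score(epochs, variant)
        labels = _sadeh.sadeh_threshold(scores)
        return ScoringResult(epochs, scores, labels, None)

    name = f"{algorithm}-{variant}" if variant else algorithm
    kernel = load_preset(name)
    epochs = epochs_for_kernel(series, kernel)
    scores = score_convolve(epochs, kernel)
    labels = threshold_labels(scores, kernel)
    rescored = None
    if rescore and _PRESET_RULES.get(algorithm):
        rules = load_rules(_PRESET_RULES[algorithm], kernel.epoch_length)
        rescored = apply_rules(labels, rules)
    return ScoringResult(epochs, scores, labels, rescored)
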