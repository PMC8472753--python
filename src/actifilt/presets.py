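"""Published scoring-algorithm presets.

Each preset is a TOML file describing one published sleep/wake scoring
rule: its collapse recipe (how raw counts become epochs), the FIR
coefficient vector, scale, bias and threshold, and the rescoring rule
set that traditionally accompanies it.  Coefficients are stored in the
order the original publications print them (most-past tap first).

Provenance matters here.  Files marked ``synthetic = true`` carry
surrogate coefficient vectors constructed by this package (uniform
weights over the documented tap span) because the original constants
could not be sourced; they preserve the documented structure — tap
count, lag layout, threshold semantics, scale variants — but not the
published numbers, and carry ``_synthetic`` in their file names.
"""

from __future__ import annotations

import tomllib
from functools import lru_cache
from importlib import resources

import numpy as np

from .epoching import collapse
from .types import ActivitySeries, EpochSeries, ScoringKernel

__all__ = [
    "preset_names",
    "load_preset",
    "preset_registry",
    "table1_presets",
    "epochs_for_kernel",
]

# Ordered as the summary table of cutoff frequencies is conventionally
# laid out: Cole-Kripke variants, Webster variants, UCSD, Sazonov,
# Scripps Clinic.
TABLE_ORDER = [
    "cole_kripke-max10s_nonoverlapping",
    "cole_kripke-max10s_overlapping",
    "cole_kripke-max30s_nonoverlapping",
    "cole_kripke-mean60s",
    "webster-max60s_overlapping",
    "webster-max10s_overlapping",
    "ucsd-a",
    "sazonov",
    "scripps_clinic",
]


def _data_dir():
    return resources.files("actifilt") / "presets" / "data"


def preset_names() -> list[str]:
    """Names of all packaged scoring presets."""
    names = []
    for item in _data_dir().iterdir():
        if item.name.endswith(".toml") and not item.name.startswith("rescoring"):
            names.append(item.name.removesuffix(".toml").removesuffix("_synthetic"))
    return sorted(names)


def _kernel_from_dict(cfg: dict, where: str) -> ScoringKernel:
    try:
        weights = np.asarray(cfg["weights"], dtype=float)
        n_past = int(cfg["n_past"])
        n_future = int(cfg["n_future"])
        kernel = ScoringKernel(
            # published order is most-past-first; internal order is by
            # increasing lag (most-future-first), hence the reversal
            coefficients=weights[::-1],
            future_span=n_future,
            past_span=n_past,
            scale=float(cfg.get("scale", 1.0)),
            bias=float(cfg.get("bias", 0.0)),
            threshold=float(cfg["threshold"]),
            wake_above=bool(cfg["wake_above"]),
            algorithm_name=cfg["algorithm"],
            variant=cfg.get("variant", ""),
            domain_tag=cfg.get("domain", "D"),
            epoch_length=float(cfg.get("epoch_length_s", 60.0)),
            collapse=tuple(
                (st["metric"], float(st["window_s"]), float(st["step_s"]))
                for st in cfg.get("collapse", [])
            ),
            citation=cfg.get("citation", ""),
            synthetic=bool(cfg.get("synthetic", False)),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ValueError(f"preset {where!r} failed validation: {exc}") from exc
    return kernel


@lru_cache(maxsize=None)
def load_preset(name: str) -> ScoringKernel:
    """Load one preset by name (e.g. ``"cole_kripke-mean60s"``)."""
    for suffix in (".toml", "_synthetic.toml"):
        path = _data_dir() / f"{name}{suffix}"
        if path.is_file():
            cfg = tomllib.loads(path.read_text())
            return _kernel_from_dict(cfg, name)
    raise ValueError(f"no such preset: {name!r} (known: {', '.join(preset_names())})")


def preset_registry() -> dict[str, ScoringKernel]:
    """All packaged single-channel presets, validated on load."""
    return {name: load_preset(name) for name in preset_names()}


def table1_presets() -> dict[str, ScoringKernel]:
    """The nine presets of the standard cutoff-frequency summary table."""
    return {name: load_preset(name) for name in TABLE_ORDER}


def epochs_for_kernel(series: ActivitySeries, kernel: ScoringKernel) -> EpochSeries:
    """Apply a preset's recorded collapse recipe to raw counts.

    Recipes are one or two ``(metric, window_s, step_s)`` stages; e.g.
    "maximum 10 s of each minute" is max over 10-s windows followed by
    max over each minute.  A ``step_s`` of 0 means "slide at the sample
    interval" (overlapping sub-windows).
    """
    current = series
    epochs: EpochSeries | None = None
    for metric, window_s, step_s in kernel.collapse:
        step = step_s if step_s > 0 else current.sample_interval
        epochs = collapse(current, metric, window_s, step)
        current = ActivitySeries(
            values=np.clip(epochs.values, 0, None),
            sample_interval=epochs.epoch_length,
            mode_tag=series.mode_tag,
            start_time=series.start_time,
        )
    if epochs is None:
        raise ValueError(f"preset {kernel.name!r} records no collapse recipe")
    return EpochSeries(
        values=epochs.values,
        epoch_length=kernel.epoch_length,
        collapse_metric=epochs.collapse_metric,
        window_length=epochs.window_length,
        overlapping=any(st[2] < st[1] and st[2] > 0 or st[2] == 0 for st in kernel.collapse),
        start_time=series.start_time,
    )
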