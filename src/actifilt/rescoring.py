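"""Run-length triggered rescoring of sleep/wake labels.

Classical actigraphic scoring optionally post-processes the thresholded
hypnogram with rules of the form "after at least X minutes scored as
wake, the next Y minutes scored as sleep are rescored wake".  The rules
smooth the label sequence: brief sleep scores inside long wake bouts
(and vice versa, depending on the rule) are absorbed into the
surrounding state.

Semantics, pinned for reproducibility:

* Triggers are evaluated on the labels as they were at the start of the
  rule application (no cascading within a single rule): a relabeled
  epoch never extends a triggering run of the same rule application.
* A maximal run of ``trigger_state`` of length >= ``min_run`` rescores
  the immediately following up-to-``affected_span`` epochs, but only
  those not already in ``target_state``; the affected span stops
  counting at its fixed width regardless of the states inside it.
* Rules in a list apply sequentially, each on the previous output, so a
  relabeled epoch *can* help satisfy a later rule's trigger.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .types import SLEEP, WAKE, SleepWakeSeries

__all__ = ["RescoringRule", "apply_rule", "apply_rules", "load_rules", "rules_from_minutes"]

_STATE = {"sleep": SLEEP, "wake": WAKE}


@dataclass(frozen=True)
class RescoringRule:
    """After >= ``min_run`` epochs of ``trigger_state``, relabel up to
    ``affected_span`` following epochs to ``target_state``."""

    trigger_state: int
    min_run: int
    affected_span: int
    target_state: int

    def __post_init__(self) -> None:
        if self.min_run < 1 or self.affected_span < 1:
            raise ValueError("min_run and affected_span must be >= 1")
        if self.trigger_state not in (SLEEP, WAKE) or self.target_state not in (SLEEP, WAKE):
            raise ValueError("states must be SLEEP (0) or WAKE (1)")

    @classmethod
    def from_names(cls, trigger: str, min_run: int, span: int, target: str) -> "RescoringRule":
        return cls(_STATE[trigger], int(min_run), int(span), _STATE[target])


def apply_rule(labels: SleepWakeSeries, rule: RescoringRule) -> SleepWakeSeries:
    """Apply one rescoring rule; triggers scan the original labels."""
    orig = labels.labels
    if orig.size == 0:
        raise ValueError("labels must be non-empty")
    out = orig.copy()
    n = orig.size
    i = 0
    while i < n:
        if orig[i] != rule.trigger_state:
            i += 1
            continue
        j = i
        while j < n and orig[j] == rule.trigger_state:
            j += 1
        if j - i >= rule.min_run:
            span_end = min(j + rule.affected_span, n)
            seg = slice(j, span_end)
            out[seg] = np.where(
                orig[seg] != rule.target_state, rule.target_state, out[seg]
            )
        i = j
    return SleepWakeSeries(
        labels=out,
        rescored=True,
        start_index=labels.start_index,
        epoch_length=labels.epoch_length,
    )


def apply_rules(labels: SleepWakeSeries, rules: list[RescoringRule]) -> SleepWakeSeries:
    """Apply an ordered rule list sequentially (order can matter)."""
    out = labels
    for rule in rules:
        out = apply_rule(out, rule)
    return out


def rules_from_minutes(
    rule_spec: list[tuple[str, float, float, str]], epoch_length: float
) -> list[RescoringRule]:
    """Convert minute-denominated published rules into epoch units."""
    rules = []
    for trigger, run_min, span_min, target in rule_spec:
        run = run_min * 60.0 / epoch_length
        span = span_min * 60.0 / epoch_length
        if abs(run - round(run)) > 1e-9 or abs(span - round(span)) > 1e-9:
            raise ValueError(
                f"rule ({run_min} min, {span_min} min) not commensurate with "
                f"{epoch_length} s epochs"
            )
        rules.append(RescoringRule.from_names(trigger, round(run), round(span), target))
    return rules


def load_rules(name: str, epoch_length: float = 60.0) -> list[RescoringRule]:
    """Load a packaged rescoring rule set (``"webster"`` or ``"cole"``)."""
    if name == "none":
        return []
    path = resources.files("actifilt") / "presets" / "data" / f"rescoring_{name}.toml"
    if not path.is_file():
        raise ValueError(f"no such rescoring preset: {name!r}")
    cfg = tomllib.loads(path.read_text())
    rule_spec = [
        (r["trigger"], float(r["min_run_min"]), float(r["span_min"]), r["target"])
        for r in cfg["rules"]
    ]
    return rules_from_minutes(rule_spec, epoch_length)
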