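"""Questionnaire battery: score ranges, vulnerable directions, categorical cutoffs.

Subscale scores enter the pipeline as numeric inputs; item-level scoring
manuals are out of scope.  What this module owns is (a) range validation,
(b) the published categorical cutoffs used in clinical interpretation, and
(c) the default registry mapping each subscale to its vulnerable direction
(+1: higher raw score = more vulnerable; -1: higher raw score = better off).

Direction rationale, subscale by subscale
-----------------------------------------
* TMT A/B (+1): trail-making completion time — the slower the test is
  completed, the more impaired attention/executive function.
* FACT-COG PCI/QOL/OTH/PCA (-1): self-reported cognitive function scales
  where higher scores mean better perceived functioning or quality of life.
* RAVLT immediate/learning/delayed/true-recognition/LOT (-1): verbal
  learning and episodic-memory scores where higher means better memory.
* RAVLT percent forgetting (+1): the one reversed RAVLT subscore — a higher
  forgetting percentage is worse.
* IPQ-R identity/consequences/timeline acute-chronic/timeline cyclical (+1):
  higher scores mean more strongly held beliefs about symptom load, negative
  consequences, chronicity and cyclicality of the illness.
* IPQ-R personal control/treatment control/coherence (-1): higher scores
  mean positive beliefs about controllability and understanding of the
  illness; their role in a vulnerability composite is debatable, so the
  default (-1) is deliberately user-overridable.
* HAD anxiety/depression (+1): higher symptom scores = more distress.
* CLCS control course and religious control (-1): perceived control over
  the disease course, judged positive for the patient; control cause (+1):
  self-blame/guilt attribution, negative for the patient.
* EORTC QLQ-C30 functional scales and global QoL (-1): higher = healthier
  functioning / better quality of life; symptom scales and single items
  (+1): higher = more symptom burden.
* PSQI (+1): higher global score = worse sleep quality.
* EPICES (+1): higher score = more precarious social situation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "Cutpoint",
    "InstrumentSpec",
    "classify",
    "default_instruments",
    "default_registry",
    "load_battery",
]


@dataclass(frozen=True)
class Cutpoint:
    """A category boundary: a new category starts at ``threshold``.

    If ``new_category_includes_threshold`` the boundary score itself belongs
    to the upper category (a ">=" cutoff, e.g. EPICES >= 30.2); otherwise the
    upper category starts strictly above it (a ">" cutoff, e.g. PSQI > 5).
    """

    threshold: float
    new_category_includes_threshold: bool = True


@dataclass(frozen=True)
class InstrumentSpec:
    """Score range, vulnerable direction and ordered categorical cutoffs."""

    name: str
    score_range: tuple[float, float]
    direction: int
    cutpoints: tuple[Cutpoint, ...] = ()
    categories: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        lo, hi = self.score_range
        if lo >= hi:
            raise ValueError(f"{self.name}: score_range must increase")
        thresholds = [c.threshold for c in self.cutpoints]
        if thresholds != sorted(thresholds) or len(set(thresholds)) != len(thresholds):
            raise ValueError(f"{self.name}: cutpoints must be strictly increasing")
        if any(t <= lo or t > hi for t in thresholds):
            raise ValueError(f"{self.name}: cutpoint outside score_range")
        if len(self.categories) != len(self.cutpoints) + 1:
            raise ValueError(
                f"{self.name}: need {len(self.cutpoints) + 1} category labels "
                f"for {len(self.cutpoints)} cutpoint(s)"
            )


def classify(instrument: InstrumentSpec, score: float) -> str:
    """Map an in-range score to its category label (a monotone step function)."""
    lo, hi = instrument.score_range
    if not (lo <= score <= hi):
        raise ValueError(
            f"{instrument.name}: score {score} outside range [{lo}, {hi}]"
        )
    idx = 0
    for cut in instrument.cutpoints:
        above = score >= cut.threshold if cut.new_category_includes_threshold else score > cut.threshold
        if above:
            idx += 1
        else:
            break
    return instrument.categories[idx]


def _battery_payload(path: str | Path | None = None) -> dict:
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            return json.load(fh)
    with resources.files("trajvuln.data").joinpath("battery.json").open(encoding="utf-8") as fh:
        return json.load(fh)


def load_battery(path: str | Path | None = None) -> tuple[dict[str, InstrumentSpec], dict[str, int]]:
    """Load instrument specs and the direction registry from JSON.

    With no argument the packaged battery resource is used; users may point
    at their own JSON with the same schema to override directions.
    """
    payload = _battery_payload(path)
    instruments = {}
    for name, spec in payload.get("instruments", {}).items():
        instruments[name] = InstrumentSpec(
            name=name,
            score_range=tuple(spec["score_range"]),
            direction=int(spec.get("direction", 1)),
            cutpoints=tuple(
                Cutpoint(c["threshold"], bool(c["new_category_includes_threshold"]))
                for c in spec.get("cutpoints", [])
            ),
            categories=tuple(spec.get("categories", [])),
        )
    directions = {str(k): int(v) for k, v in payload.get("directions", {}).items()}
    return instruments, directions


def default_instruments() -> dict[str, InstrumentSpec]:
    """The four instruments with published categorical cutoffs.

    DN4 >= 4 screens positive for neuropathic pain; HAD subscales class
    0-7 normal, 8-10 moderate, 11-21 severe; PSQI strictly greater than 5
    indicates a sleep disorder; EPICES >= 30.2 classifies precariousness.
    """
    return load_battery()[0]


def default_registry() -> dict[str, int]:
    """Vulnerable-direction registry over the full baseline battery.

    See the module docstring for the per-subscale polarity rationale.
    """
    return load_battery()[1]
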