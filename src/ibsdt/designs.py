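"""Experiment designs: which features exist and which questions are asked.

The five built-in designs emulate the single-critical-trial studies the
package analyses:

* ``exp1`` — brief red line, left or right; every subject is shown it
  (no absent condition); follow-up 2afc location question.
* ``exp2`` — brief red or blue line, left or right; 2/3 of subjects see
  it; follow-up one-interval colour question.
* ``exp3`` — as exp1 plus a 0-3 confidence rating on the yes/no answer;
  large-sample confidence-bin analysis.
* ``exp4`` — sustained display; black or white circle/triangle entering
  left or right while the subject tracks black or white squares
  (attended colour matters); 3/4 present; colour, shape and location
  follow-ups.
* ``exp5`` — as exp4 but orange/green stimuli and everyone attends white,
  removing the colour-congruency confound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = ["ExperimentDesign", "DESIGNS", "get_design"]


@dataclass(frozen=True)
class ExperimentDesign:
    experiment_id: str
    present_fraction: float
    colors: Optional[tuple[str, str]] = None  # binary stimulus colours, or None if fixed
    fixed_color: Optional[str] = None
    shapes: Optional[tuple[str, str]] = None
    has_side: bool = True
    attended_colors: Optional[tuple[str, ...]] = None
    has_confidence: bool = False
    features: tuple[str, ...] = field(default=("side",))  # follow-up questions asked

    def __post_init__(self) -> None:
        if not 0.0 < self.present_fraction <= 1.0:
            raise ValueError(
                f"present_fraction must be in (0,1], got {self.present_fraction}"
            )
        for f in self.features:
            if f not in {"color", "shape", "side"}:
                raise ValueError(f"unknown feature question {f!r}")

    @property
    def has_absent_condition(self) -> bool:
        return self.present_fraction < 1.0


DESIGNS: dict[str, ExperimentDesign] = {
    "exp1": ExperimentDesign(
        experiment_id="exp1",
        present_fraction=1.0,
        fixed_color="red",
        features=("side",),
    ),
    "exp2": ExperimentDesign(
        experiment_id="exp2",
        present_fraction=2.0 / 3.0,
        colors=("red", "blue"),
        features=("color",),
    ),
    "exp3": ExperimentDesign(
        experiment_id="exp3",
        present_fraction=1.0,
        fixed_color="red",
        has_confidence=True,
        features=("side",),
    ),
    "exp4": ExperimentDesign(
        experiment_id="exp4",
        present_fraction=0.75,
        colors=("black", "white"),
        shapes=("circle", "triangle"),
        attended_colors=("black", "white"),
        features=("color", "shape", "side"),
    ),
    "exp5": ExperimentDesign(
        experiment_id="exp5",
        present_fraction=0.75,
        colors=("orange", "green"),
        shapes=("circle", "triangle"),
        attended_colors=("white",),
        features=("color", "shape", "side"),
    ),
}


def get_design(name: str) -> ExperimentDesign:
    try:
        return DESIGNS[name]
    except KeyError:
        raise ValueError(
            f"unknown design {name!r}; available: {', '.join(sorted(DESIGNS))}"
        ) from None
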