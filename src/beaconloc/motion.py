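"""A priori motion models: the per-epoch transition-weight matrix M.

Three heuristic models describe how likely the wearer is to stay in, or
leave, the current area over one 10-s epoch:

* **model 1** — constant connection weight: ``M = A``.
* **model 2** — step-modulated self-transition: off-diagonal weights follow
  the adjacency, while the diagonal is 0.5 when the device counted more than
  2 steps in the epoch (likely moving) and 2.0 otherwise (likely dwelling).
* **model 3** — as model 2 for rooms, social areas and the stairway, but
  corridor self-transitions carry a constant weight ``w`` regardless of
  steps: corridor traversal weakly reflects step counts because corridors
  are long and always walked through.

``w`` is conventionally swept over 0.25…1.25 in steps of 0.25; ``w = 1``
treats corridors neutrally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .floorplan import Area

MODEL_IDS = ("model1", "model2", "model3")


@dataclass(frozen=True)
class StepEpoch:
    """Device step count for one 10-s localization epoch."""

    t_index: int
    steps: int

    def __post_init__(self) -> None:
        if self.steps < 0:
            raise ValueError(f"negative step count at epoch {self.t_index}")


@dataclass(frozen=True)
class MotionModel:
    """Selects one of the three a priori models and its weights.

    ``step_threshold`` (default 2): more steps than this marks the epoch as
    moving.  ``low_weight``/``high_weight`` are the moving/dwelling diagonal
    self-transition weights of models 2 and 3.  ``corridor_weight`` is model
    3's constant corridor diagonal ``w``.
    """

    model_id: str = "model3"
    corridor_weight: float = 1.0
    step_threshold: int = 2
    low_weight: float = 0.5
    high_weight: float = 2.0

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}; expected {MODEL_IDS}")
        if self.corridor_weight <= 0:
            raise ValueError("corridor_weight w must be positive")
        if self.low_weight <= 0 or self.high_weight <= 0:
            raise ValueError("diagonal weights must be positive")

    @property
    def uses_steps(self) -> bool:
        return self.model_id in ("model2", "model3")


def transition_matrix(
    model: MotionModel,
    adjacency: np.ndarray,
    areas: Sequence[Area],
    steps: StepEpoch | int | None = None,
) -> np.ndarray:
    """Per-epoch transition-weight matrix M for the chosen model.

    Off-diagonal entries always equal the adjacency; only self-transition
    weights differ between models.  Models 2 and 3 require the epoch's step
    count.
    """
    a = np.asarray(adjacency, dtype=float)
    n = a.shape[0]
    if a.shape != (n, n):
        raise ValueError("adjacency must be square")
    if len(areas) != n:
        raise ValueError(f"got {len(areas)} areas for a {n}x{n} adjacency")

    if model.model_id == "model1":
        return a.copy()

    if steps is None:
        raise ValueError(f"{model.model_id} requires a step count for the epoch")
    n_steps = steps.steps if isinstance(steps, StepEpoch) else int(steps)
    moving = n_steps > model.step_threshold
    step_diag = model.low_weight if moving else model.high_weight

    m = a.copy()
    for i, area in enumerate(areas):
        if model.model_id == "model3" and area.kind == "corridor":
            m[i, i] = model.corridor_weight
        else:
            m[i, i] = step_diag
    return m
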