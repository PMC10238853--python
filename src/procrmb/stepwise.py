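"""The 5+2 stepwise comparator design as a deterministic state machine.

A rule-based two-level design: Cohort 1 enrolls five patients at the lowest
dose, optionally expands to seven, and Cohort 2 enrolls seven patients at the
higher dose.  Fixed count thresholds on clinician-reported (C-DLT) and
patient-reported (P-DLT) events decide whether to open Cohort 2, expand,
declare a level the MTD, or declare the starting level infeasible.

Rule set (applied in order at each stage):

* Cohort-1 kill rule — at least 2 C-DLTs and/or at least 4 P-DLTs in
  Cohort 1 ends the study as infeasible.  This rule is unconditional on the
  cohort-1 stage, so it dominates the expansion rules.
* First five — 0 C-DLTs and at most 2 P-DLTs opens Cohort 2; exactly
  1 C-DLT and/or exactly 3 P-DLTs expands Cohort 1 to seven.
* Expanded seven — at most 1 C-DLT of 7 and at most 3 P-DLTs of 7 opens
  Cohort 2; otherwise the study is infeasible.
* Cohort 2 — at least 2 C-DLTs of 7 or at least 4 P-DLTs of 7 declares
  level 1 the MTD; otherwise level 2 is the MTD.

Terminal sample sizes are therefore 5, 7, 12 or 14.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Sequence

__all__ = ["Stage", "StepwiseOutcome", "StepwiseState", "initial_state", "step_5plus2"]


class Stage(enum.Enum):
    COHORT1_FIRST5 = "cohort1_first5"
    COHORT1_EXPANDED7 = "cohort1_expanded7"
    COHORT2 = "cohort2"
    TERMINAL = "terminal"


class StepwiseOutcome(enum.Enum):
    PENDING = "pending"
    MTD_LEVEL1 = "mtd_level1"
    MTD_LEVEL2 = "mtd_level2"
    INFEASIBLE = "infeasible"


#: Patients required by the next batch at each non-terminal stage.
BATCH_SIZES = {
    Stage.COHORT1_FIRST5: 5,
    Stage.COHORT1_EXPANDED7: 2,
    Stage.COHORT2: 7,
}


@dataclass(frozen=True)
class StepwiseState:
    """Current stage plus cumulative per-cohort (n, C-DLT, P-DLT) counts."""

    stage: Stage = Stage.COHORT1_FIRST5
    cohort1_n: int = 0
    cohort1_c: int = 0
    cohort1_p: int = 0
    cohort2_n: int = 0
    cohort2_c: int = 0
    cohort2_p: int = 0
    outcome: StepwiseOutcome = StepwiseOutcome.PENDING

    @property
    def total_n(self) -> int:
        return self.cohort1_n + self.cohort2_n

    @property
    def required_batch(self) -> int:
        if self.stage is Stage.TERMINAL:
            return 0
        return BATCH_SIZES[self.stage]


def initial_state() -> StepwiseState:
    return StepwiseState()


def step_5plus2(
    state: StepwiseState, observed: Sequence[tuple[int, int]]
) -> StepwiseState:
    """Advance the state machine by one enrolled batch.

    ``observed`` is one (c_dlt, p_dlt) 0/1 pair per patient in the batch;
    its length must equal the stage's required enrollment (5, 2 or 7).
    """
    if state.stage is Stage.TERMINAL:
        raise RuntimeError("the 5+2 design has already terminated")
    if len(observed) != state.required_batch:
        raise ValueError(
            f"stage {state.stage.value} requires a batch of "
            f"{state.required_batch}, got {len(observed)}"
        )
    c = sum(int(bool(pair[0])) for pair in observed)
    p = sum(int(bool(pair[1])) for pair in observed)

    if state.stage is Stage.COHORT1_FIRST5:
        c1, p1 = c, p
        new = replace(state, cohort1_n=5, cohort1_c=c1, cohort1_p=p1)
        if c1 >= 2 or p1 >= 4:  # kill rule
            return replace(new, stage=Stage.TERMINAL, outcome=StepwiseOutcome.INFEASIBLE)
        if c1 == 0 and p1 <= 2:
            return replace(new, stage=Stage.COHORT2)
        # c1 == 1 (p1 <= 3) and/or p1 == 3 (c1 <= 1): expand to seven
        return replace(new, stage=Stage.COHORT1_EXPANDED7)

    if state.stage is Stage.COHORT1_EXPANDED7:
        c1 = state.cohort1_c + c
        p1 = state.cohort1_p + p
        new = replace(state, cohort1_n=7, cohort1_c=c1, cohort1_p=p1)
        if c1 <= 1 and p1 <= 3:
            return replace(new, stage=Stage.COHORT2)
        return replace(new, stage=Stage.TERMINAL, outcome=StepwiseOutcome.INFEASIBLE)

    # Stage.COHORT2: evaluated only after all seven patients complete
    new = replace(state, cohort2_n=7, cohort2_c=c, cohort2_p=p)
    if c >= 2 or p >= 4:
        return replace(new, stage=Stage.TERMINAL, outcome=StepwiseOutcome.MTD_LEVEL1)
    return replace(new, stage=Stage.TERMINAL, outcome=StepwiseOutcome.MTD_LEVEL2)
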