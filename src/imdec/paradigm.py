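"""Block-design paradigm of the motion-imagery task.

Four directions of imagined motion are cued in blocks of four trials
(one trial per direction, randomly ordered within each block).  Trials
last 6 or 8 s; blocks are separated by jittered rests of 8, 10 or 12 s.
The default session is four runs of ten blocks, i.e. 160 trials and 40
per direction.  Rating-scale periods of the real task contribute no
modelled signal and are folded into the rests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import substream
from .containers import EventTable

__all__ = ["ParadigmSpec", "generate_events"]

#: Cardinal direction angles (degrees, counterclockwise from rightward).
CARDINAL_ANGLES = {1: 0.0, 2: 90.0, 3: 180.0, 4: 270.0}
#: Diagonal direction angles for the second subject group.
DIAGONAL_ANGLES = {1: 45.0, 2: 135.0, 3: 225.0, 4: 315.0}


@dataclass
class ParadigmSpec:
    """Timing and structure of one synthetic scanning session.

    All durations must be integer multiples of ``tr_s`` so that trial
    onsets align to the volume grid.  ``condition_angles_deg`` maps each
    condition label to the imagined motion direction it cues.
    """

    tr_s: float = 2.0
    n_runs: int = 4
    blocks_per_run: int = 10
    trials_per_block: int = 4
    conditions: tuple[int, ...] = (1, 2, 3, 4)
    condition_angles_deg: dict[int, float] = field(
        default_factory=lambda: dict(CARDINAL_ANGLES)
    )
    trial_durations_s: tuple[float, ...] = (6.0, 8.0)
    inter_block_rest_s: tuple[float, ...] = (8.0, 10.0, 12.0)
    pre_block_rest_s: float = 12.0
    post_run_rest_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.trials_per_block != len(self.conditions):
            raise ValueError(
                f"trials_per_block ({self.trials_per_block}) must equal the "
                f"number of conditions ({len(self.conditions)})"
            )
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2 (leave-one-run-out needs >= 2 folds)")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        durations = (
            list(self.trial_durations_s)
            + list(self.inter_block_rest_s)
            + [self.pre_block_rest_s, self.post_run_rest_s]
        )
        for d in durations:
            if abs(d / self.tr_s - round(d / self.tr_s)) > 1e-9:
                raise ValueError(f"duration {d} s is not a multiple of TR {self.tr_s} s")
        if set(self.condition_angles_deg) != set(self.conditions):
            raise ValueError("condition_angles_deg must cover exactly the conditions")

    @property
    def n_trials(self) -> int:
        return self.n_runs * self.blocks_per_run * self.trials_per_block

    @property
    def trials_per_condition(self) -> int:
        return self.n_runs * self.blocks_per_run


def generate_events(spec: ParadigmSpec) -> EventTable:
    """Draw one seeded event table for the paradigm.

    Each block is a random permutation of the conditions; trial durations
    and inter-block rests are drawn equiprobably from their allowed sets.
    Returns an :class:`EventTable` whose ``run_volumes`` covers each run's
    events plus the trailing rest.
    """
    spec.validate()
    rng = substream(spec.seed, "events")
    rows: list[tuple[int, float, float, int]] = []
    run_volumes: list[int] = []
    conditions = np.asarray(spec.conditions)
    for run in range(1, spec.n_runs + 1):
        t = spec.pre_block_rest_s
        for _ in range(spec.blocks_per_run):
            order = rng.permutation(conditions)
            for cond in order:
                dur = float(rng.choice(spec.trial_durations_s))
                rows.append((run, t, dur, int(cond)))
                t += dur
            t += float(rng.choice(spec.inter_block_rest_s))
        t += spec.post_run_rest_s
        run_volumes.append(int(round(t / spec.tr_s)))
    frame = pd.DataFrame(rows, columns=["run", "onset", "duration", "condition"])
    return EventTable(frame, run_volumes=tuple(run_volumes))
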