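"""Block-design task schedule for the two consumption conditions.

Each trial is an introduction (0.5 s), a task period (24 s shown as
three consecutive 8 s stimulus screens, one selection per screen) and a
rest period (35 s). Each condition is a contiguous block of 10 trials,
so one condition block spans 595 s (~10 min) — the continuous segment
later used for phase-locking analysis. The order of the two condition
blocks is randomized per participant and counterbalanced across
participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

CONDITIONS = ("OOC", "SOC")

INTRO_S = 0.5
TASK_S = 24.0
SCREEN_S = 8.0
N_SCREENS = 3
REST_S = 35.0
N_TRIALS = 10


@dataclass(frozen=True)
class ParadigmSchedule:
    """Timed trial/screen/rest sequence for both condition blocks.

    ``trials`` has one row per trial with columns ``condition``,
    ``trial`` (1-based within condition), ``intro_onset_s``,
    ``task_onset_s`` and ``rest_onset_s``. ``events`` has one row per
    stimulus screen (``onset_s``, ``duration_s``, ``condition``,
    ``screen_index``) — the selection events, three per trial.
    """

    trials: pd.DataFrame
    events: pd.DataFrame
    condition_order: tuple[str, str]
    intro_s: float = INTRO_S
    task_s: float = TASK_S
    screen_s: float = SCREEN_S
    n_screens: int = N_SCREENS
    rest_s: float = REST_S
    n_trials_per_condition: int = N_TRIALS
    lead_in_s: float = 5.0
    tail_s: float = 5.0
    inter_trial_gap_s: float = 0.0
    extra: dict = field(default_factory=dict, compare=False)

    @property
    def trial_span_s(self) -> float:
        return self.intro_s + self.task_s + self.rest_s + self.inter_trial_gap_s

    @property
    def block_span_s(self) -> float:
        return self.n_trials_per_condition * self.trial_span_s

    @property
    def session_span_s(self) -> float:
        return self.lead_in_s + 2 * self.block_span_s + self.tail_s

    def task_onsets(self, condition: str) -> np.ndarray:
        t = self.trials
        return t.loc[t["condition"] == condition, "task_onset_s"].to_numpy()

    def condition_segment(self, condition: str) -> tuple[float, float]:
        """Contiguous span of one condition block: first trial onset to
        the end of the last rest period (~595 s for the default design)."""
        t = self.trials[self.trials["condition"] == condition]
        start = float(t["intro_onset_s"].iloc[0])
        stop = float(t["rest_onset_s"].iloc[-1] + self.rest_s)
        return start, stop


def generate_paradigm(
    n_trials_per_condition: int = N_TRIALS,
    order_seed: int | np.random.Generator | None = 0,
    *,
    first_condition: str | None = None,
    intro_s: float = INTRO_S,
    task_s: float = TASK_S,
    n_screens: int = N_SCREENS,
    rest_s: float = REST_S,
    lead_in_s: float = 5.0,
    tail_s: float = 5.0,
    inter_trial_gap_s: float = 0.0,
) -> ParadigmSchedule:
    """Build a two-block schedule with randomized block order.

    Parameters
    ----------
    n_trials_per_condition : int
        Trials per condition block (10 in the study design).
    order_seed : int, Generator or None
        Seed deciding which condition block comes first. Ignored when
        ``first_condition`` is given (used for explicit counterbalancing
        across simulated participants).
    """
    if n_trials_per_condition < 1:
        raise InvalidArgumentError("n_trials_per_condition must be >= 1")
    if intro_s < 0 or task_s <= 0 or rest_s < 0 or inter_trial_gap_s < 0:
        raise InvalidArgumentError("durations must be non-negative (task > 0)")

    screen_s = task_s / n_screens
    if first_condition is None:
        rng = np.random.default_rng(order_seed)
        first_condition = CONDITIONS[int(rng.integers(2))]
    if first_condition not in CONDITIONS:
        raise InvalidArgumentError(f"unknown condition {first_condition!r}")
    second = CONDITIONS[1] if first_condition == CONDITIONS[0] else CONDITIONS[0]
    order = (first_condition, second)

    trial_rows = []
    event_rows = []
    t = lead_in_s
    trial_span = intro_s + task_s + rest_s + inter_trial_gap_s
    for condition in order:
        for k in range(n_trials_per_condition):
            intro_onset = t
            task_onset = intro_onset + intro_s
            rest_onset = task_onset + task_s
            trial_rows.append(
                {
                    "condition": condition,
                    "trial": k + 1,
                    "intro_onset_s": intro_onset,
                    "task_onset_s": task_onset,
                    "rest_onset_s": rest_onset,
                }
            )
            for s in range(n_screens):
                event_rows.append(
                    {
                        "onset_s": task_onset + s * screen_s,
                        "duration_s": screen_s,
                        "condition": condition,
                        "screen_index": s + 1,
                        "trial": k + 1,
                    }
                )
            t += trial_span

    return ParadigmSchedule(
        trials=pd.DataFrame(trial_rows),
        events=pd.DataFrame(event_rows),
        condition_order=order,
        intro_s=intro_s,
        task_s=task_s,
        screen_s=screen_s,
        n_screens=n_screens,
        rest_s=rest_s,
        n_trials_per_condition=n_trials_per_condition,
        lead_in_s=lead_in_s,
        tail_s=tail_s,
        inter_trial_gap_s=inter_trial_gap_s,
    )
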