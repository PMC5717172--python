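"""Probabilistic reversal-learning task: schedules, agents, and event timing.

The task alternates a *stable* sub-session (one option rewarded on 75% of
trials, the other on 25%) and a *volatile* sub-session (80/20, the better
option swapping every 20 trials).  Outcomes are coupled between the two
options: on every trial exactly one option is the rewarded one, so observing
the chosen option's outcome fully determines the counterfactual.

Sessions are simulated with a softmax Rescorla-Wagner agent choosing between
the two options based on displayed reward magnitudes weighted by its own
running reward-probability estimate.  Event timing mirrors a slow
event-related fMRI design: jittered decision phase (4-8 s) until a response,
a jittered anticipation ("predict") phase (4-8 s), a 3 s outcome phase and a
jittered inter-trial interval (3-7 s), giving a mean trial duration of about
20 s at TR = 3.0 s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TaskSchedule",
    "AgentParams",
    "TimingConfig",
    "BehaviorSession",
    "make_schedule",
    "simulate_agent",
]

STABLE_P = 0.75
VOLATILE_P = 0.80
STABLE_N_TRIALS = 60
VOLATILE_BLOCK = 20


@dataclass(frozen=True)
class TaskSchedule:
    """Per-trial reward probabilities, magnitudes and sub-session labels."""

    p_reward_A: np.ndarray          # probability that option A is the rewarded one
    magnitude_A: np.ndarray         # displayed points for option A
    magnitude_B: np.ndarray
    subsession_label: np.ndarray    # "stable" / "volatile" per trial
    order: str                      # "stable_first" or "volatile_first"

    @property
    def n_trials(self) -> int:
        return len(self.p_reward_A)

    def stable_trials(self) -> np.ndarray:
        return np.flatnonzero(self.subsession_label == "stable")

    def volatile_trials(self) -> np.ndarray:
        return np.flatnonzero(self.subsession_label == "volatile")


@dataclass(frozen=True)
class AgentParams:
    """Softmax Rescorla-Wagner agent standing in for a human subject."""

    agent_lr: float = 0.3
    inverse_temperature: float = 5.0
    magnitude_weight: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.agent_lr < 1.0:
            raise ValueError(f"agent_lr must be in (0, 1), got {self.agent_lr}")
        if self.inverse_temperature < 0:
            raise ValueError("inverse_temperature must be >= 0")


@dataclass(frozen=True)
class TimingConfig:
    """Event-timing parameters (seconds); defaults follow the task design."""

    decision_jitter: tuple[float, float] = (4.0, 8.0)
    predict_jitter: tuple[float, float] = (4.0, 8.0)
    outcome_duration: float = 3.0
    iti_jitter: tuple[float, float] = (3.0, 7.0)
    rt_median: float = 1.0
    rt_sigma: float = 0.3
    TR: float = 3.0
    end_buffer: float = 12.0


@dataclass
class BehaviorSession:
    """One simulated session: choices, outcomes and scanner-time events."""

    schedule: TaskSchedule
    choices: np.ndarray             # 0 = A, 1 = B
    R: np.ndarray                   # 1 if the *chosen* option was rewarded
    R_A: np.ndarray                 # 1 if option A was the rewarded one (coupled)
    chosen_magnitude: np.ndarray
    decision_onset: np.ndarray      # stimulus onset, seconds
    response_time: np.ndarray       # absolute time of the button press
    outcome_onset: np.ndarray
    TR: float
    n_volumes: int
    seed: int

    @property
    def n_trials(self) -> int:
        return len(self.choices)

    @property
    def rt(self) -> np.ndarray:
        """Reaction time relative to stimulus onset."""
        return self.response_time - self.decision_onset

    @property
    def stay_switch(self) -> np.ndarray:
        """0 = repeated previous choice, 1 = switched; first trial coded 0."""
        out = np.zeros(self.n_trials, dtype=int)
        out[1:] = (self.choices[1:] != self.choices[:-1]).astype(int)
        return out

    def events_frame(self) -> pd.DataFrame:
        """BIDS-style long events table (onset, duration, trial_type, ...)."""
        rows = []
        outcome_dur = 3.0
        for i in range(self.n_trials):
            common = dict(
                trial=i,
                magnitude=float(self.chosen_magnitude[i]),
                choice="A" if self.choices[i] == 0 else "B",
                outcome=int(self.R[i]),
            )
            rows.append(dict(onset=self.decision_onset[i],
                             duration=self.response_time[i] - self.decision_onset[i],
                             trial_type="decision", **common))
            rows.append(dict(onset=self.response_time[i],
                             duration=self.outcome_onset[i] - self.response_time[i],
                             trial_type="predict", **common))
            rows.append(dict(onset=self.outcome_onset[i],
                             duration=outcome_dur,
                             trial_type="outcome", **common))
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        self.events_frame().to_csv(path, sep="\t", index=False)
        sidecar = {
            "TR": self.TR,
            "n_volumes": int(self.n_volumes),
            "n_trials": int(self.n_trials),
            "order": self.schedule.order,
            "seed": int(self.seed),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def make_schedule(order: str = "stable_first",
                  n_volatile_trials: int = 60,
                  seed: int = 0,
                  magnitude_range: tuple[int, int] = (1, 100)) -> TaskSchedule:
    """Build the reward-probability schedule for one session.

    Parameters
    ----------
    order:
        "stable_first" or "volatile_first".
    n_volatile_trials:
        Length of the volatile sub-session; must be a positive multiple of
        20 because the better option swaps every 20 trials.
    seed:
        Seeds the volatile starting side and the per-trial magnitudes.
    magnitude_range:
        Inclusive integer range for the displayed reward magnitudes.
    """
    if order not in ("stable_first", "volatile_first"):
        raise ValueError(f"order must be stable_first or volatile_first, got {order!r}")
    if n_volatile_trials <= 0 or n_volatile_trials % VOLATILE_BLOCK != 0:
        raise ValueError(
            f"n_volatile_trials must be a positive multiple of {VOLATILE_BLOCK}, "
            f"got {n_volatile_trials}")
    rng = np.random.default_rng(seed)

    # stable: one side is the 75% option for the whole block
    stable_side_A = bool(rng.integers(2))
    p_stable = np.full(STABLE_N_TRIALS, STABLE_P if stable_side_A else 1 - STABLE_P)

    # volatile: 80/20 swapping every 20 trials
    n_blocks = n_volatile_trials // VOLATILE_BLOCK
    vol_start_A = bool(rng.integers(2))
    p_vol = np.concatenate([
        np.full(VOLATILE_BLOCK,
                VOLATILE_P if (vol_start_A ^ (b % 2 == 1))
                else round(1 - VOLATILE_P, 10))
        for b in range(n_blocks)
    ])

    if order == "stable_first":
        p = np.concatenate([p_stable, p_vol])
        label = np.array(["stable"] * STABLE_N_TRIALS + ["volatile"] * n_volatile_trials)
    else:
        p = np.concatenate([p_vol, p_stable])
        label = np.array(["volatile"] * n_volatile_trials + ["stable"] * STABLE_N_TRIALS)

    n = len(p)
    lo, hi = magnitude_range
    mag_A = rng.integers(lo, hi + 1, size=n)
    mag_B = rng.integers(lo, hi + 1, size=n)
    return TaskSchedule(p_reward_A=p, magnitude_A=mag_A, magnitude_B=mag_B,
                        subsession_label=label, order=order)


def simulate_agent(schedule: TaskSchedule,
                   params: AgentParams = AgentParams(),
                   timing: TimingConfig = TimingConfig(),
                   seed: int = 0) -> BehaviorSession:
    """Simulate one agent performing the task with realistic event timing.

    The agent keeps its own Rescorla-Wagner estimate ``q`` of p(A rewarded)
    (learning rate ``agent_lr``), values each option as
    ``magnitude_weight * magnitude * probability`` and chooses by softmax
    with slope ``inverse_temperature`` on values scaled to [0, 1].
    Outcomes are coupled: R_A ~ Bernoulli(p_reward_A); the chosen option is
    rewarded iff it is the scheduled rewarded one.
    """
    rng = np.random.default_rng(seed)
    n = schedule.n_trials

    q = 0.5  # agent's estimate that A is the rewarded option
    choices = np.empty(n, dtype=int)
    R_A = np.empty(n, dtype=int)
    R = np.empty(n, dtype=int)
    mag_scale = max(schedule.magnitude_A.max(), schedule.magnitude_B.max())
    for i in range(n):
        vA = params.magnitude_weight * schedule.magnitude_A[i] / mag_scale * q
        vB = params.magnitude_weight * schedule.magnitude_B[i] / mag_scale * (1 - q)
        z = params.inverse_temperature * (vA - vB)
        p_choose_A = 1.0 / (1.0 + np.exp(-z))
        choices[i] = 0 if rng.random() < p_choose_A else 1
        R_A[i] = int(rng.random() < schedule.p_reward_A[i])
        R[i] = R_A[i] if choices[i] == 0 else 1 - R_A[i]
        q = q + params.agent_lr * (R_A[i] - q)

    # event timing
    dec_on = np.empty(n)
    resp_t = np.empty(n)
    out_on = np.empty(n)
    t = float(rng.uniform(*timing.iti_jitter))  # lead-in before the first trial
    for i in range(n):
        dec_on[i] = t
        stim_dur = rng.uniform(*timing.decision_jitter)
        rt = timing.rt_median * np.exp(rng.normal(0.0, timing.rt_sigma))
        resp_t[i] = dec_on[i] + stim_dur + rt
        out_on[i] = resp_t[i] + rng.uniform(*timing.predict_jitter)
        t = out_on[i] + timing.outcome_duration + rng.uniform(*timing.iti_jitter)

    n_volumes = int(np.ceil((out_on[-1] + timing.outcome_duration + timing.end_buffer)
                            / timing.TR))
    chosen_mag = np.where(choices == 0, schedule.magnitude_A, schedule.magnitude_B)
    return BehaviorSession(schedule=schedule, choices=choices, R=R, R_A=R_A,
                           chosen_magnitude=chosen_mag.astype(float),
                           decision_onset=dec_on, response_time=resp_t,
                           outcome_onset=out_on, TR=timing.TR,
                           n_volumes=n_volumes, seed=seed)
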