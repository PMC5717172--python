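"""Rescorla-Wagner value traces over the full 99-learning-rate bank.

For every learning rate alpha in {0.01, ..., 0.99} the delta rule

    p(a_i) = p(a_{i-1}) + alpha * (R_i - p(a_{i-1}))

tracks the estimated probability that option A is the rewarded one.  Because
outcomes are coupled between the two options, the same outcome sequence
drives the update regardless of which option was chosen; p(B) = 1 - p(A)
exactly.  From the traces we derive per trial

* ``p_chosen`` — the estimate for the option the agent actually chose,
  evaluated *before* observing that trial's outcome (the decision-phase
  value signal), and
* ``PE = R - p_chosen`` — the probability prediction error, unweighted by
  reward magnitude (the outcome-phase signal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .task import BehaviorSession

__all__ = ["LR_GRID_FULL", "ValueTraces", "rw_update", "compute_value_traces"]

#: the full learning-rate bank: 0.01 ... 0.99 in steps of 0.01
LR_GRID_FULL = np.round(np.arange(1, 100) * 0.01, 2)


@dataclass(frozen=True)
class ValueTraces:
    """Trial x LR matrices of value estimates and prediction errors."""

    alphas: np.ndarray   # (n_lr,)
    p_A: np.ndarray      # (n_trials, n_lr): estimate *before* trial i's outcome
    p_chosen: np.ndarray  # (n_trials, n_lr)
    PE: np.ndarray       # (n_trials, n_lr)
    p0: float

    @property
    def n_trials(self) -> int:
        return self.p_A.shape[0]


def rw_update(p_prev: float, alpha: float, R: int) -> float:
    """One Rescorla-Wagner step: p + alpha * (R - p)."""
    if not 0.0 <= p_prev <= 1.0:
        raise ValueError(f"p_prev must be in [0, 1], got {p_prev}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if R not in (0, 1):
        raise ValueError(f"R must be 0 or 1, got {R}")
    return p_prev + alpha * (R - p_prev)


def compute_value_traces(session: BehaviorSession,
                         alphas: np.ndarray = LR_GRID_FULL,
                         p0: float = 0.5) -> ValueTraces:
    """Run the delta rule over a session for every learning rate at once.

    ``p_A[i]`` is the pre-outcome estimate used at trial i's decision, i.e.
    the prediction formed from trials 0..i-1.  Learning is continuous across
    the unannounced sub-session transition; sub-session analyses slice these
    traces rather than restarting them.
    """
    if session.n_trials < 1:
        raise ValueError("session must contain at least one trial")
    alphas = np.asarray(alphas, dtype=float)
    n, k = session.n_trials, len(alphas)

    p_A = np.empty((n, k))
    p = np.full(k, float(p0))
    for i in range(n):
        p_A[i] = p                       # prediction entering trial i
        p = p + alphas * (session.R_A[i] - p)

    chosen_A = (session.choices == 0)[:, None]
    p_chosen = np.where(chosen_A, p_A, 1.0 - p_A)
    PE = session.R[:, None] - p_chosen
    return ValueTraces(alphas=alphas, p_A=p_A, p_chosen=p_chosen, PE=PE, p0=p0)
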