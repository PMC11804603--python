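"""Generative Rescorla-Wagner models and bandit-task simulators.

Behavioral layer of the latent-input pipeline: a two-armed bandit
(``instrumental`` mode) or a choice-free conditioning schedule
(``pavlovian`` mode) simulated under a Rescorla-Wagner learner with
optional outcome sensitivity ``gamma`` and an exponentially decaying
learning rate.

Model
-----
On trial ``t`` the learner holds a value ``V`` per option.  The chosen
option's prediction error and update are::

    PE_t = gamma * O_t - V[chosen]
    V[chosen] <- V[chosen] + alpha_t * PE_t
    alpha_t = alpha0 * exp(-decay_rate * (t - 1))        # t is 1-based

Choices follow a softmax on the value difference with inverse
temperature ``beta``.  ``gamma = 1`` and ``decay_rate = 0`` recover the
standard static model.  Initial values are specified on the objective
outcome scale and enter the gamma-model as ``gamma * v0`` so that
outcome sensitivity rescales the whole value trajectory; this is what
makes (beta, gamma) and (beta * gamma, 1) produce identical choice
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

__all__ = [
    "TaskConfig",
    "RLParams",
    "BehavioralData",
    "compute_pe",
    "update_value",
    "softmax_prob",
    "effective_alpha",
    "simulate_agent",
    "pe_variance",
]

_MODES = ("instrumental", "pavlovian")


@dataclass(frozen=True)
class TaskConfig:
    """Two-armed bandit layout.

    Parameters
    ----------
    n_trials
        Number of trials (>= 1).
    reward_probs
        Per-option probability of the "good" outcome.
    outcome_values
        Magnitudes of the (good, bad) outcomes; the default is a
        win/lose-one-dollar framing (+1 / -1).
    mode
        ``instrumental``: outcomes depend on the softmax choice.
        ``pavlovian``: option 0 is delivered on every trial regardless of
        choice, so two subjects sharing a seed experience identical
        outcome sequences.
    """

    n_trials: int
    reward_probs: tuple[float, float] = (0.8, 0.2)
    outcome_values: tuple[float, float] = (1.0, -1.0)
    mode: str = "instrumental"

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not all(0.0 <= p <= 1.0 for p in self.reward_probs):
            raise ValueError("reward_probs must lie in [0, 1]")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")


@dataclass(frozen=True)
class RLParams:
    """Generative (or fitted) learner parameters.

    alpha: learning rate in [0, 1].  beta: softmax inverse temperature
    >= 0.  gamma: outcome sensitivity > 0 (1 = objective outcomes).
    decay_rate: per-trial exponential decay of the learning rate
    (0 = static model).  v0: initial option value on the outcome scale.
    """

    alpha: float
    beta: float
    gamma: float = 1.0
    decay_rate: float = 0.0
    v0: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.beta < 0.0:
            raise ValueError("beta must be >= 0")
        if self.gamma <= 0.0:
            raise ValueError("gamma must be > 0")
        if self.decay_rate < 0.0:
            raise ValueError("decay_rate must be >= 0")

    def replace(self, **kw) -> "RLParams":
        return replace(self, **kw)


@dataclass
class BehavioralData:
    """One simulated subject: choices, outcomes and the latent series.

    ``values`` holds the pre-update option values at each trial
    (shape ``(n_trials, 2)``); ``pe`` the trial-wise prediction errors of
    the chosen option; ``choice_probs`` the softmax probability of
    option 0 before each choice.
    """

    subject: str
    choices: np.ndarray
    outcomes: np.ndarray
    values: np.ndarray
    pe: np.ndarray
    choice_probs: np.ndarray
    mode: str = "instrumental"
    params: RLParams | None = None

    @property
    def n_trials(self) -> int:
        return int(self.choices.size)

    @property
    def value_chosen(self) -> np.ndarray:
        """Pre-update value of the chosen option on each trial."""
        return self.values[np.arange(self.n_trials), self.choices]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "subject": self.subject,
                "trial": np.arange(1, self.n_trials + 1),
                "choice": self.choices,
                "outcome": self.outcomes,
                "value_chosen": self.value_chosen,
                "pe": self.pe,
            }
        )


def compute_pe(outcome: float, value: float, gamma: float = 1.0):
    """Prediction error ``gamma * outcome - value``."""
    if np.any(np.asarray(gamma) <= 0):
        raise ValueError("gamma must be > 0")
    return gamma * outcome - value


def update_value(value: float, alpha: float, pe: float):
    """Delta-rule update ``value + alpha * pe``."""
    a = np.asarray(alpha)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("alpha must lie in [0, 1]")
    return value + alpha * pe


def softmax_prob(value_a: float, value_b: float, beta: float):
    """Probability of choosing option *a* under the softmax rule.

    Overflow-safe via the logistic sigmoid; saturates to 0/1 for large
    ``|beta * (value_a - value_b)|``.
    """
    if np.any(np.asarray(beta) < 0):
        raise ValueError("beta must be >= 0")
    return expit(beta * (np.asarray(value_a) - np.asarray(value_b)))


def effective_alpha(alpha0: float, decay_rate: float, t):
    """Learning rate at 1-based trial ``t``: ``alpha0 * exp(-decay_rate*(t-1))``."""
    if np.any(np.asarray(decay_rate) < 0):
        raise ValueError("decay_rate must be >= 0")
    t = np.asarray(t)
    if np.any(t < 1):
        raise ValueError("t is 1-based and must be >= 1")
    return alpha0 * np.exp(-decay_rate * (t - 1))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_agent(
    task: TaskConfig,
    params: RLParams,
    seed,
    outcome_schedule: np.ndarray | None = None,
) -> BehavioralData:
    """Simulate one subject on the bandit task.

    The uniform draws for choices and outcomes are generated up front,
    so two pavlovian subjects sharing a seed receive identical outcome
    sequences regardless of their learning parameters.

    Parameters
    ----------
    outcome_schedule
        Optional fixed outcome sequence (length ``n_trials``) overriding
        the probabilistic outcome generation; used for worked examples
        and fully yoked designs.
    """
    rng = _as_rng(seed)
    n = task.n_trials
    u_choice = rng.random(n)
    u_out = rng.random(n)

    if outcome_schedule is not None:
        outcome_schedule = np.asarray(outcome_schedule, dtype=float)
        if outcome_schedule.size != n:
            raise ValueError("outcome_schedule length must equal n_trials")

    good, bad = task.outcome_values
    v = np.full(2, params.gamma * params.v0, dtype=float)
    choices = np.empty(n, dtype=np.int64)
    outcomes = np.empty(n, dtype=float)
    values = np.empty((n, 2), dtype=float)
    pe = np.empty(n, dtype=float)
    probs = np.empty(n, dtype=float)

    for t in range(n):
        p0 = float(softmax_prob(v[0], v[1], params.beta))
        probs[t] = p0
        if task.mode == "instrumental":
            c = 0 if u_choice[t] < p0 else 1
        else:
            c = 0
        if outcome_schedule is not None:
            o = float(outcome_schedule[t])
        else:
            o = good if u_out[t] < task.reward_probs[c] else bad
        values[t] = v
        delta = params.gamma * o - v[c]
        v[c] = v[c] + effective_alpha(params.alpha, params.decay_rate, t + 1) * delta
        choices[t] = c
        outcomes[t] = o
        pe[t] = delta

    return BehavioralData(
        subject="0",
        choices=choices,
        outcomes=outcomes,
        values=values,
        pe=pe,
        choice_probs=probs,
        mode=task.mode,
        params=params,
    )


def pe_variance(data: BehavioralData) -> float:
    """Sample variance (n-1 denominator) of the prediction-error series."""
    if data.n_trials < 2:
        raise ValueError("pe_variance requires at least 2 trials")
    return float(np.var(data.pe, ddof=1))
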