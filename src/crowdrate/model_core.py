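"""Core decision model for sequential binary veracity ratings.

A rater classifies a message as true or false. The probability of a
*correct* classification is a logistic function of (i) the rater's
individual difficulty ``d`` with that message and (ii) the running rating
signal ``r`` accumulated by earlier raters, scaled by a susceptibility
``s``:

    Prob(correct) = 1 / (1 + d/(1-d) * exp(-s * r))

Difficulty is alignment-specific. A message with mean difficulty ``d_bar``
and bias activation ``b`` is rated at

    d_align = d_bar - b*v/2    (rater's ideology matches the message lean)
    d_mis   = d_bar + b*v/2    (rater's ideology opposes the message lean)

where ``v`` is +1 for a true message and -1 for a false one: bias makes
congenial content easier to accept and harder to reject, so aligned raters
find true aligned messages *easier* and false aligned messages *harder*.

The rating signal seen by rater ``i`` is the mean of the previous raters'
correctness, coded +1 (correct) / -1 (incorrect); it is 0 for the first
rater. With ``s = 0`` the signal is ignored and raters act independently,
each correct with probability ``1 - d``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .errors import InvalidParameterError

Ideology = Literal["liberal", "conservative"]

_IDEOLOGIES = ("liberal", "conservative")


@dataclass(frozen=True)
class MessageSpec:
    """A rateable message.

    Parameters
    ----------
    message_id:
        Stable identifier.
    veracity:
        +1 for a true message, -1 for a false one.
    lean:
        Ideological lean, ``"liberal"`` or ``"conservative"``.
    mean_difficulty:
        Population-mean probability ``d_bar`` of misclassifying the message
        when rating independently, in [0, 1].
    bias:
        Bias activation ``b`` in [0, 1]; the absolute gap between the
        aligned and misaligned difficulties.
    """

    message_id: str
    veracity: int
    lean: Ideology
    mean_difficulty: float
    bias: float = 0.0

    def __post_init__(self) -> None:
        if self.veracity not in (1, -1):
            raise InvalidParameterError(
                f"veracity must be +1 or -1, got {self.veracity!r}"
            )
        if self.lean not in _IDEOLOGIES:
            raise InvalidParameterError(f"unknown lean {self.lean!r}")
        if not 0.0 <= self.bias <= 1.0:
            raise InvalidParameterError(f"bias must be in [0, 1], got {self.bias}")
        lo = self.mean_difficulty - self.bias / 2.0
        hi = self.mean_difficulty + self.bias / 2.0
        if lo < 0.0 or hi > 1.0:
            raise InvalidParameterError(
                "mean_difficulty +/- bias/2 must stay inside [0, 1]; got "
                f"d_bar={self.mean_difficulty}, b={self.bias}"
            )

    @property
    def d_align(self) -> float:
        """Difficulty for raters whose ideology matches the lean."""
        return difficulty_for(self, aligned=True)

    @property
    def d_mis(self) -> float:
        """Difficulty for raters whose ideology opposes the lean."""
        return difficulty_for(self, aligned=False)


@dataclass(frozen=True)
class AgentSpec:
    """A rater, characterised solely by ideology."""

    subject_id: str
    ideology: Ideology

    def __post_init__(self) -> None:
        if self.ideology not in _IDEOLOGIES:
            raise InvalidParameterError(f"unknown ideology {self.ideology!r}")

    def is_aligned(self, message: MessageSpec) -> bool:
        """Alignment is a pure function: ideology equals the message lean."""
        return self.ideology == message.lean


@dataclass(frozen=True)
class ModelParams:
    """Population-level model parameters.

    ``susceptibility`` (s >= 0) scales how strongly the rating signal shifts
    the log-odds of a correct decision; s = 0 is the independence limit.
    ``group_size`` (N) is the number of sequential raters per group.
    """

    susceptibility: float = 2.35
    group_size: int = 50

    def __post_init__(self) -> None:
        if self.susceptibility < 0:
            raise InvalidParameterError(
                f"susceptibility must be >= 0, got {self.susceptibility}"
            )
        if self.group_size < 1:
            raise InvalidParameterError(
                f"group_size must be positive, got {self.group_size}"
            )


def difficulty_for(message: MessageSpec, aligned: bool) -> float:
    """Alignment-specific difficulty d_align or d_mis.

    ``d_align = d_bar - b*v/2`` and ``d_mis = d_bar + b*v/2``; the sign of
    the veracity ``v`` flips which side of the mean each alignment class
    sits on.
    """
    shift = message.bias * message.veracity / 2.0
    d = message.mean_difficulty - shift if aligned else message.mean_difficulty + shift
    if not -1e-12 <= d <= 1.0 + 1e-12:
        raise InvalidParameterError(
            f"derived difficulty {d} outside [0, 1] for message "
            f"{message.message_id!r}"
        )
    return min(max(d, 0.0), 1.0)


def rating_signal(prior_decisions: Iterable[bool | int]) -> float:
    """Mean of prior decisions coded +1 (correct) / -1 (incorrect).

    Returns 0.0 for an empty history (the first rater sees no signal).
    The result always lies in [-1, +1].
    """
    prior = np.asarray(list(prior_decisions), dtype=float)
    if prior.size == 0:
        return 0.0
    return float(np.mean(2.0 * prior - 1.0))


def prob_correct(
    difficulty: float | np.ndarray,
    susceptibility: float,
    signal: float | np.ndarray,
) -> float | np.ndarray:
    """Probability of a correct rating decision.

    ``(1 + d/(1-d) * exp(-s*r))**-1``: equals ``1 - d`` when ``s*r = 0``,
    increases in the signal for ``s > 0`` and decreases in difficulty.
    Boundary difficulties 0 and 1 return the limiting probabilities 1 and 0
    (the odds form is continuous there).
    """
    if susceptibility < 0:
        raise InvalidParameterError(
            f"susceptibility must be >= 0, got {susceptibility}"
        )
    d = np.asarray(difficulty, dtype=float)
    r = np.asarray(signal, dtype=float)
    if np.any((d < 0) | (d > 1)):
        raise InvalidParameterError("difficulty must lie in [0, 1]")
    if np.any((r < -1 - 1e-12) | (r > 1 + 1e-12)):
        raise InvalidParameterError("signal must lie in [-1, 1]")
    with np.errstate(divide="ignore"):
        odds_incorrect = np.where(d < 1.0, d / (1.0 - d), np.inf)
    p = 1.0 / (1.0 + odds_incorrect * np.exp(-susceptibility * r))
    p = np.where(d == 0.0, 1.0, np.where(d == 1.0, 0.0, p))
    if p.ndim == 0:
        return float(p)
    return p
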