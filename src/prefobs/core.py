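"""Shared domain types, the subjective-value model, and behavioral metrics.

The central construct is a scalar social preference ``P`` in [0, 1]: the
proportion of points a person ideally keeps for themself in a Dictator Game
(0 = fully prosocial, 1 = fully selfish).  An allocation ``x`` (also a
proportion-for-self) has subjective value ``s(x) = 1 - (x - P)**2``, so the
value of an option decays quadratically with its distance from the preferred
split.  Everything else in the package — decision difficulty, drift rates,
softmax choice probabilities, observer teaching signals — is built on top of
this single-peaked value function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Literal, Optional, Sequence

import numpy as np

Side = Literal["left", "right"]

__all__ = [
    "ObserverSession",
    "Side",
    "Condition",
    "AllocationPair",
    "Preference",
    "Decision",
    "Observation",
    "subjective_value",
    "difficulty",
    "accuracy",
    "consistency",
    "expected_chance_accuracy",
    "empirical_chance_level",
]


class Condition(Enum):
    """The four observation conditions of the 2x2 (choice x RT visibility) design."""

    NONE = "none"
    RT_ONLY = "rt_only"
    CHOICE_ONLY = "choice_only"
    BOTH = "both"

    @property
    def choice_visible(self) -> bool:
        return self in (Condition.CHOICE_ONLY, Condition.BOTH)

    @property
    def rt_visible(self) -> bool:
        return self in (Condition.RT_ONLY, Condition.BOTH)

    @classmethod
    def from_flags(cls, choice_visible: bool, rt_visible: bool) -> "Condition":
        return {
            (False, False): cls.NONE,
            (False, True): cls.RT_ONLY,
            (True, False): cls.CHOICE_ONLY,
            (True, True): cls.BOTH,
        }[(bool(choice_visible), bool(rt_visible))]


def _check_unit(value: float, name: str) -> float:
    value = float(value)
    if not np.isfinite(value) or not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class AllocationPair:
    """One Dictator-Game decision problem: two proportion-for-self options."""

    left: float
    right: float
    trial_index: int = 0

    def __post_init__(self) -> None:
        _check_unit(self.left, "left")
        _check_unit(self.right, "right")
        if self.left == self.right:
            raise ValueError("left and right allocations must differ")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.left + self.right)

    def allocation(self, side: Side) -> float:
        return self.left if side == "left" else self.right

    def other(self, side: Side) -> float:
        return self.right if side == "left" else self.left


@dataclass(frozen=True)
class Preference:
    """A social preference: the preferred proportion-for-self in [0, 1]."""

    value: float

    def __post_init__(self) -> None:
        _check_unit(self.value, "preference")

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class Decision:
    """A recorded choice and its response time (seconds)."""

    choice: Side
    rt: float

    def __post_init__(self) -> None:
        if self.choice not in ("left", "right"):
            raise ValueError(f"choice must be 'left' or 'right', got {self.choice!r}")
        if not np.isfinite(self.rt) or self.rt <= 0:
            raise ValueError(f"rt must be a positive finite number, got {self.rt!r}")


@dataclass(frozen=True)
class Observation:
    """What an observer sees on one trial: the options, plus whatever the
    condition reveals of the dictator's decision."""

    pair: AllocationPair
    condition: Condition
    choice: Optional[Side] = None
    rt: Optional[float] = None

    def __post_init__(self) -> None:
        if self.condition.choice_visible and self.choice is None:
            raise ValueError(f"choice required in condition {self.condition.value}")
        if self.condition.rt_visible and self.rt is None:
            raise ValueError(f"rt required in condition {self.condition.value}")


@dataclass
class ObserverSession:
    """One observer x dictator block: an ordered observation stream, slider
    estimation slots, and held-out prediction problems.

    ``reported_estimates`` / ``predicted_choices`` hold the observer's actual
    behavior when fitting; they are None for forward simulation.
    ``true_preference`` carries the synthetic ground truth when available.
    """

    observer_id: str
    dictator_id: str
    condition: Condition
    observations: list = field(default_factory=list)  # list[Observation]
    estimation_slots: tuple = (0, 4, 8, 12)
    prediction_pairs: list = field(default_factory=list)  # list[AllocationPair]
    reported_estimates: Optional[list] = None  # floats, one per slot
    predicted_choices: Optional[list] = None  # Side, one per prediction pair
    prediction_rts: Optional[list] = None
    dictator_prediction_choices: Optional[list] = None  # dictator's own choices
    true_preference: Optional[float] = None

    def __post_init__(self) -> None:
        for slot in self.estimation_slots:
            if slot < 0 or slot > len(self.observations):
                raise ValueError(
                    f"estimation slot {slot} outside 0..{len(self.observations)}"
                )
        if self.reported_estimates is not None and len(self.reported_estimates) != len(
            self.estimation_slots
        ):
            raise ValueError("one reported estimate required per estimation slot")
        if self.predicted_choices is not None and len(self.predicted_choices) != len(
            self.prediction_pairs
        ):
            raise ValueError("one predicted choice required per prediction pair")


def _as_pref(p) -> float:
    return _check_unit(float(p), "preference")


def subjective_value(x, preference) -> float | np.ndarray:
    """Subjective value ``s(x) = 1 - (x - P)**2`` of allocation ``x`` under
    preference ``P``.  Maximal (= 1) exactly when ``x == P``.

    Accepts scalars or numpy arrays for ``x``.
    """
    p = _as_pref(preference)
    x_arr = np.asarray(x, dtype=float)
    if np.any((x_arr < 0) | (x_arr > 1)) or not np.all(np.isfinite(x_arr)):
        raise ValueError("allocations must lie in [0, 1]")
    out = 1.0 - (x_arr - p) ** 2
    return out if out.ndim else float(out)


def difficulty(pair: AllocationPair, preference) -> float:
    """Trial difficulty ``|s(left) - s(right)|`` inverted: 0 means the two
    options are equally valued (hard), large means one clearly dominates."""
    p = _as_pref(preference)
    return float(abs(subjective_value(pair.left, p) - subjective_value(pair.right, p)))


def accuracy(estimate, truth) -> float:
    """Estimation accuracy ``1 - |estimate - truth|``: 1 is a perfect slider
    report, 0 the maximal possible error."""
    e = _check_unit(float(estimate), "estimate")
    t = _check_unit(float(truth), "truth")
    return 1.0 - abs(e - t)


def consistency(
    predicted_choice: Side, pair: AllocationPair, last_estimate
) -> Literal["consistent", "inconsistent", "tie"]:
    """Whether a predicted choice picks the allocation closest to the
    observer's own last preference estimate.

    Equidistant options are reported as ``"tie"`` so callers can exclude them
    from consistency rates rather than silently counting them either way.
    """
    est = _as_pref(last_estimate)
    chosen = pair.allocation(predicted_choice)
    other = pair.other(predicted_choice)
    d_chosen = abs(chosen - est)
    d_other = abs(other - est)
    if np.isclose(d_chosen, d_other, rtol=0.0, atol=1e-9):
        return "tie"
    return "consistent" if d_chosen < d_other else "inconsistent"


def expected_chance_accuracy(truth) -> float:
    """Closed-form expected accuracy of a uniform random guess against a
    fixed true preference ``P``.

    E[1 - |U - P|] over U ~ Uniform(0, 1) equals ``1 - (P**2 + (1-P)**2)/2``;
    it peaks at 0.75 for P = 0.5 and falls to 0.5 at the extremes.
    """
    p = _as_pref(truth)
    return 1.0 - (p**2 + (1.0 - p) ** 2) / 2.0


def empirical_chance_level(
    truths: Sequence[float], n_samples: int = 10_000, seed=None
) -> float:
    """Monte-Carlo chance level of the estimation task.

    For each true preference, draws ``n_samples`` uniform guesses, scores them
    with :func:`accuracy`, and averages; the mean over truths is the empirical
    chance level an entirely uninformed observer would attain.
    """
    truths = [_as_pref(t) for t in truths]
    if not truths:
        raise ValueError("truths must be non-empty")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    guesses = rng.uniform(0.0, 1.0, size=(len(truths), n_samples))
    acc = 1.0 - np.abs(guesses - np.asarray(truths)[:, None])
    return float(acc.mean(axis=1).mean())
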