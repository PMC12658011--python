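"""Social discounting task structure and indifference-point extraction.

The task asks a participant to imagine a list of 100 people ranked by
closeness and, for each of seven social distances N in {1, 2, 5, 10, 20,
50, 100}, to make nine binary choices between keeping an amount of money
(the "selfish" option, $155 down to $75 in $10 steps) and splitting it so
that both the participant and person N receive $75 (the "generous" option).

The indifference point for a block is the selfish amount on the trial at
which the participant first switches from selfish to generous responding;
an all-selfish block is censored at $75 and an all-generous block at $155.
The amount willing to forgo, v = indifference − 75, lies in [0, 80] and is
the quantity the discounting models in :mod:`socdisc.models` are fit to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import DataError

SELFISH = "selfish"
GENEROUS = "generous"

#: Canonical social distances, closest (1) to stranger (100).
SOCIAL_DISTANCES: tuple[int, ...] = (1, 2, 5, 10, 20, 50, 100)

#: Selfish amounts per trial, $155 decreasing by $10 to $75.
SELFISH_AMOUNTS: tuple[int, ...] = tuple(range(155, 74, -10))

#: Each party's share under the generous (split) option.
GENEROUS_SHARE = 75

#: Maximum amount a participant can forgo ($155 − $75).
MAX_FORGONE = 80


@dataclass(frozen=True)
class TrialSchedule:
    """The fixed 7-distance × 9-trial schedule of the discounting task."""

    social_distances: tuple[int, ...] = SOCIAL_DISTANCES
    selfish_amounts: tuple[int, ...] = SELFISH_AMOUNTS
    generous_self_amount: int = GENEROUS_SHARE
    generous_other_amount: int = GENEROUS_SHARE

    def __post_init__(self) -> None:
        if len(self.social_distances) != 7:
            raise DataError("schedule must contain exactly 7 social distances")
        if len(self.selfish_amounts) != 9:
            raise DataError("schedule must contain exactly 9 selfish amounts")
        steps = [a - b for a, b in zip(self.selfish_amounts, self.selfish_amounts[1:])]
        if self.selfish_amounts[0] != 155 or self.selfish_amounts[-1] != 75 or any(s != 10 for s in steps):
            raise DataError("selfish amounts must decrease from 155 to 75 in $10 steps")

    @property
    def n_trials(self) -> int:
        return len(self.social_distances) * len(self.selfish_amounts)

    def forgone_amounts(self) -> tuple[int, ...]:
        """Amount sacrificed by choosing the generous option on each trial."""
        return tuple(a - self.generous_self_amount for a in self.selfish_amounts)


def build_trial_schedule() -> TrialSchedule:
    """Return the canonical task schedule (7 distances × 9 trials)."""
    return TrialSchedule()


@dataclass(frozen=True)
class ChoiceBlock:
    """Nine ordered binary choices at one social distance."""

    social_distance: int
    choices: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.social_distance not in SOCIAL_DISTANCES:
            raise DataError(
                f"social distance {self.social_distance} not in canonical set {SOCIAL_DISTANCES}"
            )
        if len(self.choices) != 9:
            raise DataError(
                f"block at N={self.social_distance} has {len(self.choices)} trials, expected 9"
            )
        bad = [c for c in self.choices if c not in (SELFISH, GENEROUS)]
        if bad:
            raise DataError(f"unknown choice label(s) {sorted(set(bad))!r}; expected 'selfish' or 'generous'")


@dataclass(frozen=True)
class IndifferenceProfile:
    """Per-distance indifference points and amounts willing to forgo."""

    social_distances: tuple[int, ...]
    indifference_points: tuple[float, ...]
    forgone_v: tuple[float, ...]
    violations: tuple[bool, ...]

    def __post_init__(self) -> None:
        n = len(self.social_distances)
        if not (n == len(self.indifference_points) == len(self.forgone_v) == len(self.violations)):
            raise DataError("profile fields must have equal length")
        if tuple(self.social_distances) != SOCIAL_DISTANCES:
            raise DataError("profile must cover exactly the seven canonical distances, in order")

    @property
    def n_violations(self) -> int:
        return sum(self.violations)


def extract_indifference(block: ChoiceBlock, schedule: TrialSchedule | None = None) -> tuple[float, bool]:
    """Indifference point and monotonicity-violation flag for one block.

    All-selfish blocks are censored at $75 and all-generous blocks at $155;
    otherwise the indifference point is the selfish amount offered on the
    first trial with a generous choice. Any selfish choice after that first
    generous one marks the block as non-monotone (flagged, not discarded).
    """
    schedule = schedule or build_trial_schedule()
    choices = block.choices
    try:
        first_generous = choices.index(GENEROUS)
    except ValueError:
        return float(schedule.selfish_amounts[-1]), False
    violation = SELFISH in choices[first_generous:]
    return float(schedule.selfish_amounts[first_generous]), violation


def forgone_amount(indifference_point: float) -> float:
    """Amount willing to forgo: v = indifference point − $75."""
    if not 75 <= indifference_point <= 155:
        raise DataError(f"indifference point {indifference_point} outside [75, 155]")
    return float(indifference_point) - GENEROUS_SHARE


def build_profile(blocks: Iterable[ChoiceBlock], schedule: TrialSchedule | None = None) -> IndifferenceProfile:
    """Combine seven blocks (one per canonical distance) into a profile."""
    schedule = schedule or build_trial_schedule()
    by_distance: dict[int, ChoiceBlock] = {}
    for block in blocks:
        if block.social_distance in by_distance:
            raise DataError(f"duplicate block for social distance N={block.social_distance}")
        by_distance[block.social_distance] = block
    missing = [n for n in schedule.social_distances if n not in by_distance]
    if missing:
        raise DataError(f"missing block(s) for social distance(s) {missing}")

    points, vs, flags = [], [], []
    for n in schedule.social_distances:
        ip, violation = extract_indifference(by_distance[n], schedule)
        points.append(ip)
        vs.append(forgone_amount(ip))
        flags.append(violation)
    return IndifferenceProfile(
        social_distances=tuple(schedule.social_distances),
        indifference_points=tuple(points),
        forgone_v=tuple(vs),
        violations=tuple(flags),
    )
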