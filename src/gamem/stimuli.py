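"""Synthetic stimulus patterns and timed trial schedules.

A conditioned stimulus (CS) is a binary activation pattern over the N
receptors of the network; patterns are random and independent, each bit
Bernoulli(f) where f is the sparseness of the stimuli.  Stimuli are
presented in discrete trials: a CS pattern, optionally paired with the
unconditioned stimulus (US), applied for a fixed duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from ._rng import rng_from
from .bistable import TRIAL_DURATION

__all__ = [
    "Pattern",
    "Trial",
    "Protocol",
    "gen_pattern",
    "gen_patterns",
    "pairing_schedule",
    "conditioning_schedule",
    "DEFAULT_INTERTRIAL_GAP",
]

#: Default gap between consecutive trials (time units; 30 min at the
#: default physical anchor, i.e. hourly trial onsets).
DEFAULT_INTERTRIAL_GAP = 12.0


@dataclass(frozen=True)
class Pattern:
    """Binary receptor-activation vector with its generating sparseness."""

    bits: np.ndarray
    f: float
    id: str = ""

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=np.int8)
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("pattern bits must be 0/1")
        object.__setattr__(self, "bits", bits)

    @property
    def n(self) -> int:
        return self.bits.size

    def __eq__(self, other):
        return (
            isinstance(other, Pattern)
            and np.array_equal(self.bits, other.bits)
            and self.id == other.id
        )


@dataclass(frozen=True)
class Trial:
    """One stimulus presentation window.

    ``pattern is None`` means no CS (a US-alone trial); ``us`` flags the
    presence of the unconditioned stimulus.
    """

    onset: float
    duration: float
    pattern: Pattern | None
    us: int

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("trial duration must be positive")
        if self.us not in (0, 1):
            raise ValueError("us must be 0 or 1")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class Protocol:
    """Ordered, non-overlapping trials within a simulation horizon."""

    trials: tuple[Trial, ...]
    horizon: float

    def __post_init__(self):
        trials = tuple(self.trials)
        for a, b in zip(trials, trials[1:]):
            if b.onset < a.end:
                raise ValueError(
                    f"overlapping/unsorted trials at onsets {a.onset}, {b.onset}"
                )
        if trials and trials[-1].end > self.horizon:
            raise ValueError("trials extend beyond the protocol horizon")
        object.__setattr__(self, "trials", trials)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "horizon": self.horizon,
            "trials": [
                {
                    "onset": t.onset,
                    "duration": t.duration,
                    "pattern_id": None if t.pattern is None else t.pattern.id,
                    "us": t.us,
                }
                for t in self.trials
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def gen_pattern(
    N: int, f: float, rng, id: str = "", exact_count: bool = False
) -> Pattern:
    """Random stimulus pattern: independent Bernoulli(f) bits.

    With ``exact_count=True`` the pattern has exactly round(f*N) active
    bits at uniformly random positions (a variance-reduction variant; the
    independent-Bernoulli form is the default model).
    """
    if not 0 < f < 1:
        raise ValueError("sparseness f must lie in (0, 1)")
    rng = rng_from(rng)
    if exact_count:
        bits = np.zeros(N, dtype=np.int8)
        k = int(round(f * N))
        bits[rng.choice(N, size=k, replace=False)] = 1
    else:
        bits = (rng.random(N) < f).astype(np.int8)
    return Pattern(bits=bits, f=f, id=id)


def gen_patterns(
    N: int, f: float, count: int, rng, prefix: str = "pat", exact_count: bool = False
) -> list[Pattern]:
    rng = rng_from(rng)
    return [
        gen_pattern(N, f, rng, id=f"{prefix}{i}", exact_count=exact_count)
        for i in range(count)
    ]


def pairing_schedule(
    patterns: Sequence[Pattern],
    trial_duration: float = TRIAL_DURATION,
    gap: float = DEFAULT_INTERTRIAL_GAP,
    start: float = 0.0,
) -> Protocol:
    """One CS+US pairing trial per pattern, oldest first."""
    if not patterns:
        raise ValueError("need at least one pattern")
    trials = []
    t = start
    for pat in patterns:
        trials.append(Trial(onset=t, duration=trial_duration, pattern=pat, us=1))
        t += trial_duration + gap
    return Protocol(trials=tuple(trials), horizon=t)


def conditioning_schedule(
    pattern: Pattern,
    trial_duration: float = TRIAL_DURATION,
    period: float = 24.0,
) -> Protocol:
    """Classical-conditioning demonstration schedule for a single CS.

    Hourly slots (one ``period`` apart): US alone at slot 1; CS probe at
    slot 2; three CS+US pairings at slots 3-5; CS probes at 6-7; US alone
    at 8-11; CS probes at 12-13.  With the default physical anchor
    (period = 24 units = 1 h) this reproduces the canonical
    acquisition-then-extinction experiment.
    """
    def trial(slot: int, cs: bool, us: int) -> Trial:
        return Trial(
            onset=slot * period,
            duration=trial_duration,
            pattern=pattern if cs else None,
            us=us,
        )

    trials = [trial(1, False, 1), trial(2, True, 0)]
    trials += [trial(s, True, 1) for s in (3, 4, 5)]
    trials += [trial(s, True, 0) for s in (6, 7)]
    trials += [trial(s, False, 1) for s in (8, 9, 10, 11)]
    trials += [trial(s, True, 0) for s in (12, 13)]
    return Protocol(trials=tuple(trials), horizon=14 * period)
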