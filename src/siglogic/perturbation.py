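"""Scheduled extracellular perturbations.

Perturbations are delivered through a *virtual node*: an abstraction of the
extracellular environment that sits upstream of every input node and whose
activity is pinned to 1.  A scheduled event with level ``l`` installs, for the
iterations it covers, a virtual edge into its target — activating of weight
``l`` for ``l > 0``, inhibiting of weight ``|l|`` for ``l < 0``.  Because the
virtual node's activity is 1, the transmitted signal equals ``|l|``; full
inhibition is ``l = -1``.

Iterations are 1-based: "the 10th iteration" means the 10th synchronous
update applied to the state.  Events are persistent by default (no ``end``):
a drug added at iteration ``k`` keeps acting until the simulation stops.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .network import ACTIVATING, INHIBITING, Sign

__all__ = ["PerturbationEvent", "Schedule", "ScheduleError", "read_schedule"]


class ScheduleError(ValueError):
    """A perturbation event or schedule violates an invariant."""


@dataclass(frozen=True)
class PerturbationEvent:
    """One scheduled stimulus or inhibition.

    Parameters
    ----------
    target
        The input node the perturbation acts on.
    level
        Strength in [-1, 1]; positive stimulates, negative inhibits
        (-1 = full inhibition).  0 is legal and transmits no signal.
    start
        First iteration (1-based) at which the perturbation acts.
    end
        Last iteration covered (inclusive), or ``None`` for open-ended.
    """

    target: str
    level: float
    start: int = 1
    end: int | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.target, str) or not self.target:
            raise ScheduleError(f"event target must be a nonempty string, got {self.target!r}")
        if not -1.0 <= self.level <= 1.0:
            raise ScheduleError(f"perturbation level must lie in [-1, 1], got {self.level!r}")
        if not (isinstance(self.start, int) and self.start >= 1):
            raise ScheduleError(f"event start must be an iteration index >= 1, got {self.start!r}")
        if self.end is not None and (not isinstance(self.end, int) or self.end < self.start):
            raise ScheduleError(
                f"event end must be >= start ({self.start}) or None, got {self.end!r}"
            )

    def covers(self, iteration: int) -> bool:
        return self.start <= iteration and (self.end is None or iteration <= self.end)


class Schedule:
    """An ordered collection of perturbation events.

    At most one event may cover any (target, iteration) pair; overlap is
    rejected at construction so queries never have to break ties.
    """

    def __init__(self, events: Iterable[PerturbationEvent] = ()) -> None:
        self.events: tuple[PerturbationEvent, ...] = tuple(events)
        by_target: dict[str, list[PerturbationEvent]] = {}
        for ev in self.events:
            by_target.setdefault(ev.target, []).append(ev)
        for target, evs in by_target.items():
            evs = sorted(evs, key=lambda e: e.start)
            for a, b in zip(evs, evs[1:]):
                a_end = math.inf if a.end is None else a.end
                if b.start <= a_end:
                    raise ScheduleError(
                        f"overlapping events for target {target!r}: "
                        f"[{a.start}, {a.end or 'inf'}] and [{b.start}, {b.end or 'inf'}]"
                    )
        self._by_target = {t: tuple(sorted(evs, key=lambda e: e.start))
                           for t, evs in by_target.items()}

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[PerturbationEvent]:
        return iter(self.events)

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(self._by_target)

    def active_signal(self, target: str, iteration: int) -> float | None:
        """The level of the event covering ``(target, iteration)``, or
        ``None`` if no event is active there (the node evolves freely)."""
        if iteration < 1:
            raise ValueError(f"iteration must be >= 1, got {iteration}")
        for ev in self._by_target.get(target, ()):
            if ev.covers(iteration):
                return ev.level
        return None

    def virtual_edges(self, iteration: int) -> list[tuple[str, Sign, float]]:
        """The virtual edges active at ``iteration``.

        Each active event with nonzero level contributes one
        ``(target, sign, weight)`` triple with ``weight = |level|``; since the
        virtual node's activity is constant 1 the transmitted signal is
        ``|level|`` itself.  Zero-level events emit nothing.
        """
        out: list[tuple[str, Sign, float]] = []
        for ev in self.events:
            if ev.covers(iteration) and ev.level != 0.0:
                sign = ACTIVATING if ev.level > 0 else INHIBITING
                out.append((ev.target, sign, abs(ev.level)))
        return out


def read_schedule(path: str | Path) -> Schedule:
    """Read a schedule from CSV (columns ``target, level, start[, end]``) or
    from a JSON list of event objects; format inferred from the suffix."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        if not isinstance(records, list):
            raise ScheduleError(f"{path}: expected a JSON list of events")
    else:
        with open(path, newline="") as fh:
            records = list(csv.DictReader(fh))
    events = []
    for i, rec in enumerate(records):
        try:
            end_raw = rec.get("end")
            end = None if end_raw in (None, "", "inf") else int(end_raw)
            events.append(
                PerturbationEvent(
                    target=str(rec["target"]),
                    level=float(rec["level"]),
                    start=int(rec.get("start", 1) or 1),
                    end=end,
                )
            )
        except ScheduleError:
            raise
        except (KeyError, TypeError, ValueError) as exc:
            raise ScheduleError(f"{path}: malformed event record {i}: {exc}") from exc
    return Schedule(events)
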