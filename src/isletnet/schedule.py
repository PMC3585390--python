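"""Stimulation-protocol schedules.

An experiment is segmented into named half-open time intervals
``[t_start_s, t_end_s)``.  The canonical protocol has five regimes:

``LG1``
    low (6 mM) glucose before stimulation,
``ON``
    activation transient after switching to stimulatory (12 mM) glucose,
``HG``
    sustained activity in high glucose (plateau with oscillations),
``OFF``
    deactivation transient after glucose is lowered again,
``LG2``
    low glucose after stimulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import yaml

__all__ = ["Regime", "RegimeSchedule", "CANONICAL_REGIMES"]

CANONICAL_REGIMES = ("LG1", "ON", "HG", "OFF", "LG2")

#: Default regime bounds in seconds (half-open intervals).
_DEFAULT_BOUNDS = {
    "LG1": (0.0, 300.0),
    "ON": (300.0, 420.0),
    "HG": (600.0, 1000.0),
    "OFF": (1080.0, 1200.0),
    "LG2": (1400.0, 1800.0),
}


@dataclass(frozen=True)
class Regime:
    """A named half-open time interval ``[t_start_s, t_end_s)``."""

    name: str
    t_start_s: float
    t_end_s: float

    def __post_init__(self) -> None:
        if not self.t_end_s > self.t_start_s:
            raise ValueError(
                f"regime {self.name!r}: t_end_s ({self.t_end_s}) must exceed "
                f"t_start_s ({self.t_start_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s

    def contains(self, t: float) -> bool:
        return self.t_start_s <= t < self.t_end_s


class RegimeSchedule(Mapping[str, Regime]):
    """Ordered collection of non-overlapping named regimes.

    Behaves as a mapping from regime name to :class:`Regime`.
    """

    def __init__(self, regimes: Iterable[Regime | tuple | dict]):
        parsed: list[Regime] = []
        for r in regimes:
            if isinstance(r, Regime):
                parsed.append(r)
            elif isinstance(r, dict):
                parsed.append(Regime(r["name"], float(r["t_start_s"]), float(r["t_end_s"])))
            else:
                name, t0, t1 = r
                parsed.append(Regime(str(name), float(t0), float(t1)))
        if not parsed:
            raise ValueError("schedule must contain at least one regime")
        names = [r.name for r in parsed]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate regime names in schedule: {names}")
        ordered = sorted(parsed, key=lambda r: r.t_start_s)
        for a, b in zip(ordered, ordered[1:]):
            if b.t_start_s < a.t_end_s:
                raise ValueError(
                    f"regimes {a.name!r} and {b.name!r} overlap "
                    f"([{a.t_start_s}, {a.t_end_s}) vs [{b.t_start_s}, {b.t_end_s}))"
                )
        self._regimes = {r.name: r for r in ordered}

    # -- mapping protocol -------------------------------------------------
    def __getitem__(self, name: str) -> Regime:
        try:
            return self._regimes[name]
        except KeyError:
            raise KeyError(
                f"schedule has no regime {name!r}; available: {list(self._regimes)}"
            ) from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._regimes)

    def __len__(self) -> int:
        return len(self._regimes)

    # ---------------------------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._regimes)

    @property
    def total_duration_s(self) -> float:
        """End of the last regime (experiment duration when LG2 closes it)."""
        return max(r.t_end_s for r in self._regimes.values())

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self._regimes]
        if missing:
            raise KeyError(f"schedule is missing required regime(s): {missing}")

    @classmethod
    def default(cls) -> "RegimeSchedule":
        """The canonical five-regime glucose-stimulation protocol."""
        return cls([Regime(n, *_DEFAULT_BOUNDS[n]) for n in CANONICAL_REGIMES])

    # -- serialisation ----------------------------------------------------
    def to_dicts(self) -> list[dict]:
        return [
            {"name": r.name, "t_start_s": r.t_start_s, "t_end_s": r.t_end_s}
            for r in self._regimes.values()
        ]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"regimes": self.to_dicts()}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RegimeSchedule":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if isinstance(payload, dict):
            payload = payload["regimes"]
        return cls(payload)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        parts = ", ".join(
            f"{r.name}=[{r.t_start_s:g},{r.t_end_s:g})" for r in self._regimes.values()
        )
        return f"RegimeSchedule({parts})"

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegimeSchedule):
            return NotImplemented
        return self.to_dicts() == other.to_dicts()
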