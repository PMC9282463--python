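"""Fishery-management timeline.

Regulation episodes map (date range, zone) to an effort level:

* ``Y`` — fishery allowed (the default everywhere before any regulation),
* ``L`` — limited fishery (buffer zones),
* ``N`` — fishery ban.

Resolving a (date, point) first locates the point's zone in the study
geometry, then looks the zone up in the episode table; anything not covered
resolves to ``Y``.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

LEVELS = ("Y", "L", "N")


@dataclass(frozen=True)
class Episode:
    start: date
    end: date
    zone: str
    level: str

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ValueError(f"unknown fishery level {self.level!r}")
        if self.end < self.start:
            raise ValueError("episode end precedes start")


class ManagementTimeline:
    """Ordered, per-zone non-overlapping regulation episodes."""

    def __init__(self, episodes: list[Episode] | None = None):
        episodes = sorted(episodes or [], key=lambda e: (e.zone, e.start))
        for a, b in zip(episodes, episodes[1:]):
            if a.zone == b.zone and b.start <= a.end:
                raise ValueError(
                    f"overlapping episodes for zone {a.zone!r}: "
                    f"{a.start}..{a.end} and {b.start}..{b.end}")
        self.episodes = episodes

    def level_for_zone(self, when: date, zone: str | None) -> str:
        if zone is None:
            return "Y"
        for ep in self.episodes:
            if ep.zone == zone and ep.start <= when <= ep.end:
                return ep.level
        return "Y"

    def resolve(self, when: date, lon: float, lat: float, geometry) -> str:
        """Fishery level at a point on a date (default Y outside all zones)."""
        return self.level_for_zone(when, geometry.zone_of(lon, lat))


def make_management_timeline(episodes: list[tuple] | None = None) -> ManagementTimeline:
    """Build a timeline from (start, end, zone, level) tuples.

    ``None`` gives the default synthetic history: open fishery everywhere
    until mid-2015, then a ban in zone A with limited fishery in the two
    buffer zones B and C.
    """
    if episodes is None:
        episodes = default_episodes()
    return ManagementTimeline([Episode(*e) for e in episodes])


def default_episodes() -> list[tuple]:
    far = date(2030, 12, 31)
    start = date(2015, 7, 1)
    return [
        (start, far, "A", "N"),
        (start, far, "B", "L"),
        (start, far, "C", "L"),
    ]
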