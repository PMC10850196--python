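"""Calendar-quarter identifiers.

Spontaneous-report databases are published quarterly, and every time axis in
this package (report receipt, label-revision announcements, feature cut-offs)
is expressed in calendar quarters serialised as ``"YYYYQn"``.  Ordering and
arithmetic go through a linear quarter index so that string ordering never
matters.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass
from functools import total_ordering

_QUARTER_RE = re.compile(r"^(\d{4})Q([1-4])$")

_QUARTER_START_MONTH = {1: 1, 2: 4, 3: 7, 4: 10}


@total_ordering
@dataclass(frozen=True)
class Quarter:
    """A calendar quarter, e.g. ``Quarter(2019, 3)`` == "2019Q3"."""

    year: int
    q: int

    def __post_init__(self) -> None:
        if not 1 <= self.q <= 4:
            raise ValueError(f"quarter number must be 1-4, got {self.q}")

    @classmethod
    def parse(cls, s: "str | Quarter") -> "Quarter":
        if isinstance(s, Quarter):
            return s
        m = _QUARTER_RE.match(str(s).strip())
        if m is None:
            raise ValueError(f"not a quarter id (expected 'YYYYQn'): {s!r}")
        return cls(int(m.group(1)), int(m.group(2)))

    @classmethod
    def from_date(cls, d: dt.date) -> "Quarter":
        return cls(d.year, (d.month - 1) // 3 + 1)

    @classmethod
    def from_index(cls, i: int) -> "Quarter":
        return cls(i // 4, i % 4 + 1)

    @property
    def index(self) -> int:
        """Linear index: year * 4 + (q - 1).  Safe for ordering/arithmetic."""
        return self.year * 4 + self.q - 1

    def start_date(self) -> dt.date:
        return dt.date(self.year, _QUARTER_START_MONTH[self.q], 1)

    def end_date(self) -> dt.date:
        return (self + 1).start_date() - dt.timedelta(days=1)

    def n_days(self) -> int:
        return (self.end_date() - self.start_date()).days + 1

    def __add__(self, n: int) -> "Quarter":
        return Quarter.from_index(self.index + int(n))

    def __sub__(self, other: "int | Quarter"):
        if isinstance(other, Quarter):
            return self.index - other.index
        return Quarter.from_index(self.index - int(other))

    def __lt__(self, other: "Quarter") -> bool:
        return self.index < other.index

    def __str__(self) -> str:
        return f"{self.year}Q{self.q}"


def quarter_range(start: "str | Quarter", end: "str | Quarter") -> list[Quarter]:
    """Inclusive list of quarters from `start` through `end`."""
    a, b = Quarter.parse(start), Quarter.parse(end)
    if b < a:
        raise ValueError(f"end quarter {b} precedes start quarter {a}")
    return [Quarter.from_index(i) for i in range(a.index, b.index + 1)]
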