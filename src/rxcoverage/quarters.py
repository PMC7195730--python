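"""Calendar quarters as the analysis time unit.

A :class:`QuarterId` is a civil calendar quarter with half-open date bounds
``[start, next-quarter start)``; quarter lengths are therefore 90, 91 or 92
days.  The whole pipeline indexes quarters as the number of quarters since
the first study quarter (index 0).

A :class:`StudyWindow` bundles a contiguous run of analysis periods with the
intervention period marked.  The default periods are calendar quarters; a
fixed-90-day tiling from the study start is available for the idealized
"90-day quarter" reading of the coverage rule.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass
from functools import total_ordering
from typing import Iterator

import numpy as np

_LABEL_RE = re.compile(r"^(\d{4})\s*Q([1-4])$", re.IGNORECASE)


@total_ordering
@dataclass(frozen=True)
class QuarterId:
    """One calendar quarter, e.g. ``QuarterId(2013, 2)`` == 2013Q2."""

    year: int
    quarter: int

    def __post_init__(self) -> None:
        if not 1 <= self.quarter <= 4:
            raise ValueError(f"quarter must be in 1..4, got {self.quarter}")

    # -- ordering -----------------------------------------------------
    def _key(self) -> int:
        return self.year * 4 + (self.quarter - 1)

    def __lt__(self, other: "QuarterId") -> bool:
        return self._key() < other._key()

    # -- bounds -------------------------------------------------------
    @property
    def start(self) -> dt.date:
        return dt.date(self.year, 3 * (self.quarter - 1) + 1, 1)

    @property
    def end(self) -> dt.date:
        """Exclusive end: the start of the following quarter."""
        return self.next().start

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days

    # -- arithmetic ---------------------------------------------------
    def next(self) -> "QuarterId":
        return self.offset(1)

    def offset(self, k: int) -> "QuarterId":
        key = self._key() + k
        return QuarterId(key // 4, key % 4 + 1)

    def index(self, origin: "QuarterId") -> int:
        """Number of quarters since ``origin`` (origin has index 0)."""
        return self._key() - origin._key()

    # -- parsing / formatting ----------------------------------------
    @classmethod
    def from_label(cls, label: str) -> "QuarterId":
        m = _LABEL_RE.match(label.strip())
        if m is None:
            raise ValueError(f"cannot parse quarter label {label!r} (expected e.g. '2013Q2')")
        return cls(int(m.group(1)), int(m.group(2)))

    def __str__(self) -> str:
        return f"{self.year}Q{self.quarter}"


def quarter_of(date: dt.date) -> QuarterId:
    """Calendar quarter containing ``date``."""
    return QuarterId(date.year, (date.month - 1) // 3 + 1)


def quarter_bounds(q: QuarterId) -> tuple[dt.date, dt.date]:
    """Half-open ``(start, end_exclusive)`` bounds of a quarter."""
    return q.start, q.end


def quarter_range(first: QuarterId, last: QuarterId) -> list[QuarterId]:
    """Inclusive list of quarters from ``first`` to ``last``."""
    n = last.index(first)
    if n < 0:
        raise ValueError(f"{last} precedes {first}")
    return [first.offset(k) for k in range(n + 1)]


class StudyWindow:
    """Contiguous analysis periods with an intervention period marked.

    Attributes
    ----------
    starts, ends : np.ndarray of datetime64[D]
        Half-open bounds of each period, ``ends[i] == starts[i+1]``.
    labels : list of str
        Period labels ("2013Q2" or "P13" for fixed windows).
    intervention_index : int
        0-based index of the first post-intervention period.
    """

    def __init__(
        self,
        starts: np.ndarray,
        ends: np.ndarray,
        labels: list[str],
        intervention_index: int,
        quarters: list[QuarterId] | None = None,
    ) -> None:
        if not (0 < intervention_index < len(labels)):
            raise ValueError("intervention period must lie strictly inside the window")
        self.starts = np.asarray(starts, dtype="datetime64[D]")
        self.ends = np.asarray(ends, dtype="datetime64[D]")
        self.labels = labels
        self.intervention_index = intervention_index
        self.quarters = quarters

    # -- constructors -------------------------------------------------
    @classmethod
    def calendar_quarters(
        cls, first: QuarterId, last: QuarterId, intervention: QuarterId
    ) -> "StudyWindow":
        qs = quarter_range(first, last)
        starts = np.array([q.start for q in qs], dtype="datetime64[D]")
        ends = np.array([q.end for q in qs], dtype="datetime64[D]")
        return cls(starts, ends, [str(q) for q in qs], intervention.index(first), quarters=qs)

    @classmethod
    def fixed_90_day(
        cls, study_start: dt.date, n_periods: int, intervention_index: int
    ) -> "StudyWindow":
        """Tile ``n_periods`` 90-day windows from ``study_start``."""
        s0 = np.datetime64(study_start, "D")
        starts = s0 + 90 * np.arange(n_periods)
        ends = starts + 90
        labels = [f"P{i}" for i in range(n_periods)]
        return cls(starts, ends, labels, intervention_index)

    # -- accessors ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[tuple[np.datetime64, np.datetime64]]:
        return iter(zip(self.starts, self.ends))

    @property
    def n_days(self) -> np.ndarray:
        return (self.ends - self.starts).astype(int)

    @property
    def study_start(self) -> dt.date:
        return self.starts[0].astype(dt.date)

    @property
    def study_end(self) -> dt.date:
        """Exclusive end of the whole window."""
        return self.ends[-1].astype(dt.date)

    def period_index(self, dates: np.ndarray) -> np.ndarray:
        """Period index for each date; -1 before the window, len(self) after.

        Works for both calendar-quarter and fixed-width windows via
        searchsorted on the period starts.
        """
        d = np.asarray(dates, dtype="datetime64[D]")
        idx = np.searchsorted(self.starts, d, side="right") - 1
        idx = np.where(d >= self.ends[-1], len(self.labels), idx)
        return idx

    def day_offsets(self) -> np.ndarray:
        """Period boundary offsets in days from study start, length n+1."""
        bounds = np.concatenate([self.starts, self.ends[-1:]])
        return (bounds - self.starts[0]).astype(int)
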