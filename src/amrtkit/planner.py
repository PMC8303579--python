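"""DDA inclusion-list planning.

Every library compound gets an inclusion entry (precursor m/z, RT window of
±0.5 min by default) for data-dependent acquisition of samples.  The
instrument can only service a limited number of co-eluting precursors per
duty cycle (the loop count), so the library is split across several
inclusion-list files such that no file ever carries more than ``capacity``
temporally overlapping entries.  Interval partitioning sorted by window start
achieves the optimal file count ``ceil(max_concurrency / capacity)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .library_model import AMRTRecord

__all__ = [
    "InclusionEntry",
    "InclusionPlan",
    "entries_from_records",
    "max_concurrency",
    "build_inclusion_lists",
    "write_inclusion_files",
]


@dataclass(frozen=True)
class InclusionEntry:
    """One scheduled precursor: m/z with an RT window (minutes, half-width)."""

    mz: float
    rt_center: float
    rt_window: float
    polarity: str
    compound_id: str = ""

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("m/z must be > 0")
        if self.rt_window <= 0:
            raise ValueError("rt_window must be > 0")

    @property
    def start(self) -> float:
        return self.rt_center - self.rt_window

    @property
    def end(self) -> float:
        return self.rt_center + self.rt_window


@dataclass
class InclusionPlan:
    """Entries split across files, each respecting the concurrency capacity."""

    files: list[list[InclusionEntry]]
    capacity: int

    @property
    def n_files(self) -> int:
        return len(self.files)

    @property
    def n_entries(self) -> int:
        return sum(len(f) for f in self.files)


def entries_from_records(
    records: Sequence[AMRTRecord], rt_window: float = 0.5
) -> list[InclusionEntry]:
    return [
        InclusionEntry(
            mz=r.precursor.mz,
            rt_center=r.rt,
            rt_window=rt_window,
            polarity=r.precursor.polarity,
            compound_id=r.compound.id,
        )
        for r in records
    ]


def max_concurrency(entries: Sequence[InclusionEntry]) -> int:
    """Largest number of RT windows sharing any common time point.

    Windows are closed intervals: touching endpoints count as overlapping
    (conservative for scheduling).  Sweep-line over window endpoints.
    """
    if not entries:
        raise ValueError("no entries")
    # starts (kind 0) sort before ends (kind 1) at equal time -> closed intervals
    events = sorted(
        [(e.start, 0) for e in entries] + [(e.end, 1) for e in entries]
    )
    best = current = 0
    for _, kind in events:
        if kind == 0:
            current += 1
            best = max(best, current)
        else:
            current -= 1
    return best


def build_inclusion_lists(
    records_or_entries: Sequence[Union[AMRTRecord, InclusionEntry]],
    rt_window: float = 0.5,
    capacity: int = 5,
) -> InclusionPlan:
    """Split entries across the minimum number of inclusion files.

    Entries are sorted by window start and assigned first-fit to the first
    file whose concurrency over the new entry's window stays within
    ``capacity``.  Because earlier entries all start no later, concurrency
    inside the new window is maximal at its start, so the first-fit test only
    needs the entries still open there; the resulting file count equals
    ``ceil(max_concurrency / capacity)``.
    """
    if capacity < 1:
        raise ValueError(f"capacity must be >= 1, got {capacity}")
    if not records_or_entries:
        return InclusionPlan(files=[], capacity=capacity)
    if isinstance(records_or_entries[0], AMRTRecord):
        entries = entries_from_records(records_or_entries, rt_window)  # type: ignore[arg-type]
    else:
        entries = list(records_or_entries)  # type: ignore[assignment]
    polarities = {e.polarity for e in entries}
    if len(polarities) > 1:
        raise ValueError(
            f"plan one polarity at a time, got {sorted(polarities)}"
        )
    entries = sorted(entries, key=lambda e: (e.start, e.mz, e.compound_id))
    files: list[list[InclusionEntry]] = []
    for entry in entries:
        for f in files:
            open_here = sum(1 for other in f if other.end >= entry.start)
            if open_here < capacity:
                f.append(entry)
                break
        else:
            files.append([entry])
    return InclusionPlan(files=files, capacity=capacity)


def plan_is_valid(plan: InclusionPlan) -> bool:
    """Sweep-line check that every file respects the capacity."""
    return all(
        (not f) or max_concurrency(f) <= plan.capacity for f in plan.files
    )


def optimal_file_count(entries: Sequence[InclusionEntry], capacity: int) -> int:
    return math.ceil(max_concurrency(entries) / capacity)


def write_inclusion_files(
    plan: InclusionPlan, out_dir: Union[str, Path], prefix: str = "inclusion"
) -> list[Path]:
    """Write one vendor-importable CSV per file: m/z, RT start/end (min), polarity."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, entries in enumerate(plan.files, start=1):
        frame = pd.DataFrame(
            [
                {
                    "mz": e.mz,
                    "rt_start_min": e.start,
                    "rt_end_min": e.end,
                    "polarity": e.polarity,
                    "compound_id": e.compound_id,
                }
                for e in entries
            ]
        )
        path = out_dir / f"{prefix}_{i:02d}.csv"
        frame.to_csv(path, index=False)
        paths.append(path)
    return paths
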