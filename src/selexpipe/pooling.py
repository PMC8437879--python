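"""Collapse-and-count, normalization, ranking and cross-round enrichment.

A selection round's PASS inserts are collapsed by exact identity into a
:class:`PoolCounts`. Candidate reporting keeps sequences whose duplication
count strictly exceeds a threshold (default 25) ranked by count; cross-round
enrichment compares reads-per-million (RPM) between two rounds with a small
pseudocount so fold-changes stay finite.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

#: Default candidate threshold: report sequences with count strictly > 25.
DEFAULT_MIN_COUNT = 25
#: Default RPM pseudocount for fold-changes against unobserved sequences.
DEFAULT_PSEUDOCOUNT = 0.5


class UndefinedPoolError(ValueError):
    """Normalization requested on a pool with no passing reads."""


@dataclass
class PoolCounts:
    """Collapsed unique-insert counts for one selection round."""

    round_label: str
    counts: dict[str, int] = field(default_factory=dict)
    total_pass: int = field(default=-1)

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.counts.values()):
            raise ValueError("counts must be positive integers")
        total = sum(self.counts.values())
        if self.total_pass < 0:
            self.total_pass = total
        elif self.total_pass != total:
            raise ValueError(
                f"total_pass {self.total_pass} != sum of counts {total}"
            )

    def __len__(self) -> int:
        return len(self.counts)

    def rpm_of(self, sequence: str) -> float:
        return rpm(self.counts.get(sequence, 0), self.total_pass)


def collapse(inserts: Iterable[str], round_label: str = "") -> PoolCounts:
    """Reduce repeated identical inserts to unique sequences with counts."""
    tally = Counter(inserts)
    return PoolCounts(round_label=round_label, counts=dict(tally))


def rpm(count: int, total_pass: int) -> float:
    """Reads-per-million normalization: ``count / total_pass * 1e6``."""
    if total_pass <= 0:
        raise UndefinedPoolError("RPM undefined for a pool with total_pass == 0")
    if not 0 <= count <= total_pass:
        raise ValueError(f"count {count} outside [0, {total_pass}]")
    return count / total_pass * 1_000_000


def top_candidates(
    pool: PoolCounts, min_count: int = DEFAULT_MIN_COUNT
) -> pd.DataFrame:
    """Rank sequences whose read count strictly exceeds ``min_count``.

    Returns a DataFrame with columns ``rank, sequence, length, count, rpm``,
    sorted by count descending with lexicographic tie-break, ranks 1..k.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    rows = [
        (seq, len(seq), count, rpm(count, pool.total_pass))
        for seq, count in pool.counts.items()
        if count > min_count
    ]
    rows.sort(key=lambda r: (-r[2], r[0]))
    table = pd.DataFrame(rows, columns=["sequence", "length", "count", "rpm"])
    table.insert(0, "rank", range(1, len(table) + 1))
    return table


def enrichment(
    early: PoolCounts,
    late: PoolCounts,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_count: int = 0,
) -> pd.DataFrame:
    """Per-sequence RPM fold-change between two rounds.

    ``fold_change = (rpm_late + pseudocount) / (rpm_early + pseudocount)``
    over the union of sequences; absent sequences contribute count 0, so a
    positive pseudocount keeps every fold-change finite and positive. Rows
    are ranked by fold-change descending (lexicographic tie-break).
    ``min_count`` optionally restricts to sequences whose late-round count
    exceeds it.
    """
    if not early.counts or not late.counts:
        raise ValueError("both pools must be non-empty")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    sequences = set(early.counts) | set(late.counts)
    rows = []
    for seq in sequences:
        c_early = early.counts.get(seq, 0)
        c_late = late.counts.get(seq, 0)
        if c_late <= min_count and min_count > 0:
            continue
        r_early = rpm(c_early, early.total_pass)
        r_late = rpm(c_late, late.total_pass)
        fold = (r_late + pseudocount) / (r_early + pseudocount)
        rows.append((seq, len(seq), c_early, c_late, r_early, r_late, fold))
    rows.sort(key=lambda r: (-r[6], r[0]))
    table = pd.DataFrame(
        rows,
        columns=[
            "sequence", "length",
            "count_early", "count_late",
            "rpm_early", "rpm_late",
            "fold_change",
        ],
    )
    table.insert(0, "rank", range(1, len(table) + 1))
    table.attrs["early_round"] = early.round_label
    table.attrs["late_round"] = late.round_label
    table.attrs["pseudocount"] = pseudocount
    return table


def counts_from_table(
    table: Mapping[str, int] | pd.DataFrame,
    round_label: str = "",
    sequence_col: str = "sequence",
    count_col: str = "count",
) -> PoolCounts:
    """Build a :class:`PoolCounts` from a mapping or tidy table of counts."""
    if isinstance(table, pd.DataFrame):
        counts = dict(zip(table[sequence_col], table[count_col].astype(int)))
    else:
        counts = {str(k): int(v) for k, v in table.items()}
    return PoolCounts(round_label=round_label, counts=counts)
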