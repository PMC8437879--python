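"""Sequence and table I/O for SELEX pool analysis.

FASTQ input is the 4-line Sanger/Illumina dialect with Phred+33 qualities.
Collapsed pool counts are serialized as a small TSV
(``rank\\tsequence\\tlength\\tcount\\trpm``) plus an optional FASTA export in
the FASTAptamer header style (``>rank-count-rpm``).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator, Optional, Sequence, TextIO, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

if TYPE_CHECKING:  # pragma: no cover
    from .pooling import PoolCounts

PathLike = Union[str, Path]

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Mate suffixes: classic "/1" "/2" and Casava 1.8 " 1:N:0:..." comment fields.
_MATE_SUFFIX = re.compile(r"/[12]$")


class FastqParseError(ValueError):
    """Raised for structurally invalid FASTQ records; names the record index."""


class PairingError(ValueError):
    """Raised when R1/R2 streams cannot be paired."""


@dataclass(frozen=True)
class SeqRecord:
    """A single sequencing read.

    Parameters
    ----------
    read_id:
        Identifier without the leading ``@``.
    bases:
        Uppercase nucleotide string over ``{A, C, G, T, N}``.
    quals:
        Optional per-base Phred scores (offset already removed); same length
        as ``bases`` when present.
    """

    read_id: str
    bases: str
    quals: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"record {self.read_id!r}: empty sequence")
        if self.bases != self.bases.upper():
            object.__setattr__(self, "bases", self.bases.upper())
        bad = set(self.bases) - _VALID_BASES
        if bad:
            raise ValueError(
                f"record {self.read_id!r}: non-nucleotide characters {sorted(bad)}"
            )
        if self.quals is not None:
            if len(self.quals) != len(self.bases):
                raise ValueError(
                    f"record {self.read_id!r}: quality length {len(self.quals)} "
                    f"!= sequence length {len(self.bases)}"
                )
            if any(q < 0 for q in self.quals):
                raise ValueError(f"record {self.read_id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class ReadPair:
    """Mated forward/reverse reads for one sequenced fragment."""

    r1: SeqRecord
    r2: SeqRecord
    fragment_id: str = field(default="")

    def __post_init__(self) -> None:
        id1 = normalize_read_id(self.r1.read_id)
        id2 = normalize_read_id(self.r2.read_id)
        if id1 != id2:
            raise PairingError(f"mate IDs disagree: {id1!r} vs {id2!r}")
        if not self.fragment_id:
            object.__setattr__(self, "fragment_id", id1)


def normalize_read_id(raw_id: str) -> str:
    """Strip mate designators so both mates share one fragment ID.

    Handles the classic ``/1``/``/2`` suffix and the Casava 1.8+
    ``<id> 1:N:0:...`` comment dialect (anything after the first whitespace
    is dropped).
    """
    head = raw_id.split(None, 1)[0]
    return _MATE_SUFFIX.sub("", head)


def reverse_complement(bases: str) -> str:
    """Watson-Crick reverse complement; ``N`` maps to ``N``.

    Raises ``ValueError`` on characters outside ``{A, C, G, T, N}``.
    """
    bad = set(bases.upper()) - _VALID_BASES
    if bad:
        raise ValueError(f"cannot complement non-IUPAC characters {sorted(bad)}")
    return bases.upper().translate(_COMPLEMENT)[::-1]


def read_fastq(path: PathLike) -> Iterator[SeqRecord]:
    """Stream records from a 4-line FASTQ file (Phred+33).

    Yields records in file order with sequences uppercased. A malformed
    record aborts with :class:`FastqParseError` naming the 0-based index of
    the offending record.
    """
    with open(path) as handle:
        yield from parse_fastq(handle, source=str(path))


def parse_fastq(handle: TextIO, source: str = "<stream>") -> Iterator[SeqRecord]:
    index = -1
    iterator = FastqGeneralIterator(handle)
    while True:
        index += 1
        try:
            title, seq, qual = next(iterator)
        except StopIteration:
            return
        except ValueError as exc:
            raise FastqParseError(f"{source}: record {index}: {exc}") from exc
        try:
            yield SeqRecord(
                read_id=title.split(None, 1)[0] if title else title,
                bases=seq,
                quals=tuple(ord(c) - 33 for c in qual),
            )
        except ValueError as exc:
            raise FastqParseError(f"{source}: record {index}: {exc}") from exc


def write_fastq(records: Iterable[SeqRecord], path: PathLike) -> None:
    """Write 4-line FASTQ with Phred+33 qualities (Q30 default when absent)."""
    with open(path, "w") as out:
        for rec in records:
            quals = rec.quals if rec.quals is not None else (30,) * len(rec.bases)
            qline = "".join(chr(q + 33) for q in quals)
            out.write(f"@{rec.read_id}\n{rec.bases}\n+\n{qline}\n")


def pair_reads(
    r1_stream: Iterable[SeqRecord], r2_stream: Iterable[SeqRecord]
) -> Iterator[ReadPair]:
    """Zip mate streams into :class:`ReadPair` objects.

    Mate IDs are normalized (``/1``/``/2`` and Casava comments stripped)
    before the equality check; any disagreement or length mismatch is a
    fatal :class:`PairingError`.
    """
    sentinel = object()
    it1, it2 = iter(r1_stream), iter(r2_stream)
    position = 0
    while True:
        a = next(it1, sentinel)
        b = next(it2, sentinel)
        if a is sentinel and b is sentinel:
            return
        if a is sentinel or b is sentinel:
            longer = "R2" if a is sentinel else "R1"
            raise PairingError(
                f"unequal stream lengths: {longer} has extra records at position {position}"
            )
        yield ReadPair(r1=a, r2=b)  # type: ignore[arg-type]
        position += 1


# ---------------------------------------------------------------------------
# counts tables

_COUNTS_HEADER = ["rank", "sequence", "length", "count", "rpm"]


def write_counts_table(pool: "PoolCounts", path: PathLike) -> None:
    """Serialize a collapsed pool as a rank-ordered TSV.

    Output is byte-deterministic for a given pool: rows sorted by count
    descending then sequence lexicographically, RPM printed with 4 decimals.
    """
    with open(path, "w", newline="") as out:
        out.write(format_counts_table(pool))


def format_counts_table(pool: "PoolCounts") -> str:
    from .pooling import rpm  # local import to avoid a cycle

    buf = io.StringIO()
    buf.write("\t".join(_COUNTS_HEADER) + "\n")
    ordered = sorted(pool.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    for rank, (seq, count) in enumerate(ordered, start=1):
        value = rpm(count, pool.total_pass)
        buf.write(f"{rank}\t{seq}\t{len(seq)}\t{count}\t{value:.4f}\n")
    return buf.getvalue()


def read_counts_table(path: PathLike) -> "PoolCounts":
    """Read a counts TSV back into a :class:`~selexpipe.pooling.PoolCounts`."""
    from .pooling import PoolCounts

    counts: dict[str, int] = {}
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != _COUNTS_HEADER:
            raise ValueError(f"{path}: unexpected counts-table header {header}")
        for line in handle:
            _, seq, _, count, _ = line.rstrip("\n").split("\t")
            counts[seq] = int(count)
    return PoolCounts(round_label=Path(path).stem, counts=counts)


def write_counts_fasta(pool: "PoolCounts", path: PathLike) -> None:
    """FASTA export with FASTAptamer-style ``>rank-count-rpm`` headers."""
    from .pooling import rpm

    ordered = sorted(pool.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(path, "w") as out:
        for rank, (seq, count) in enumerate(ordered, start=1):
            out.write(f">{rank}-{count}-{rpm(count, pool.total_pass):.4f}\n{seq}\n")
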