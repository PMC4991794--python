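"""Combine mapped mate pairs into counting fragments.

Mate pairs mapped to the same reference whose outer span (``max(end) −
min(start)``) does not exceed ``max_distance`` (default 1 kb) are combined
into a single fragment covering the full insert.  Pairs spanning more than
the limit, or mapped to different references, are discarded.  Reads whose
partner never mapped are retained as single-mate fragments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple

from .io_formats import MATE_FIRST, MATE_SECOND, MATE_UNPAIRED, MappedRead

logger = logging.getLogger(__name__)

ORIGIN_PAIRED = "paired"
ORIGIN_SINGLE = "single"


class Fragment(NamedTuple):
    ref_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str
    origin: str  # paired | single


@dataclass
class AssemblyStats:
    """Bookkeeping for the pair-combination step.

    Conservation: ``2*combined + 2*discarded_pairs + singles`` equals the
    number of accepted (non-multimapped) input reads.
    """

    combined: int = 0
    discarded_pairs: int = 0
    singles: int = 0
    dropped_multimap_read_ids: int = 0
    total_reads: int = 0  # accepted reads (multimap-dropped excluded)

    def as_dict(self) -> dict[str, int]:
        return {
            "combined": self.combined,
            "discarded_pairs": self.discarded_pairs,
            "singles": self.singles,
            "dropped_multimap_read_ids": self.dropped_multimap_read_ids,
            "total_reads": self.total_reads,
        }


def _single_fragment(read: MappedRead) -> Fragment:
    # Library is forward-stranded on the first mate: a lone second mate
    # reports the opposite strand of the originating fragment.
    strand = read.strand
    if read.mate == MATE_SECOND:
        strand = "-" if strand == "+" else "+"
    return Fragment(read.ref_id, read.start, read.end, strand, ORIGIN_SINGLE)


def assemble_fragments(
    reads: Iterable[MappedRead],
    max_distance: int = 1000,
    multimap: str = "drop",
) -> tuple[list[Fragment], AssemblyStats]:
    """Group mappings by read_id and combine mates into fragments.

    Parameters
    ----------
    reads
        Accepted mappings (any order; grouping is by ``read_id``).
    max_distance
        Maximum outer span, in bp, for a pair to be combined (1 kb default).
    multimap
        Policy for read_ids with more than one mapping per mate:
        ``"drop"`` removes the whole read_id, ``"first"`` keeps the first
        mapping seen per mate.

    Returns the fragments (sorted by read_id group for order-independence)
    and the conservation statistics.
    """
    if multimap not in ("drop", "first"):
        raise ValueError(f"unknown multimap policy {multimap!r}")

    groups: dict[str, list[MappedRead]] = {}
    for r in reads:
        groups.setdefault(r.read_id, []).append(r)

    fragments: list[Fragment] = []
    stats = AssemblyStats()

    for read_id in sorted(groups):
        group = groups[read_id]
        by_mate: dict[str, MappedRead] = {}
        duplicated = False
        for r in group:
            if r.mate in by_mate:
                duplicated = True
                if multimap == "drop":
                    break
                # keep-first: ignore subsequent mappings of this mate
            else:
                by_mate[r.mate] = r
        if duplicated and multimap == "drop":
            stats.dropped_multimap_read_ids += 1
            logger.debug("read %s multimapped; dropped", read_id)
            continue

        stats.total_reads += len(by_mate)

        first = by_mate.get(MATE_FIRST)
        second = by_mate.get(MATE_SECOND)
        unpaired = by_mate.get(MATE_UNPAIRED)

        if unpaired is not None:
            fragments.append(_single_fragment(unpaired))
            stats.singles += 1

        if first is not None and second is not None:
            span_ok = (
                first.ref_id == second.ref_id
                and max(first.end, second.end) - min(first.start, second.start)
                <= max_distance
            )
            if span_ok:
                fragments.append(
                    Fragment(
                        first.ref_id,
                        min(first.start, second.start),
                        max(first.end, second.end),
                        first.strand,
                        ORIGIN_PAIRED,
                    )
                )
                stats.combined += 1
            else:
                stats.discarded_pairs += 1
        elif first is not None:
            fragments.append(_single_fragment(first))
            stats.singles += 1
        elif second is not None:
            fragments.append(_single_fragment(second))
            stats.singles += 1

    return fragments, stats


def write_fragments_bed(fragments: Iterable[Fragment], path) -> None:
    """Write fragments as BED6, carrying the origin in the name column."""
    with open(path, "w") as fh:
        for i, f in enumerate(fragments):
            fh.write(f"{f.ref_id}\t{f.start}\t{f.end}\t{f.origin}_{i}\t0\t{f.strand}\n")
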