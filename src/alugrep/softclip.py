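"""Characterize an insertion from soft-clipped alignments.

At a mobile-element insertion the aligner cannot place the inserted bases, so
reads crossing the breakpoint are soft-clipped there: right-clips carry the
start of the inserted element, left-clips carry its tail (element end,
poly(A), and the duplicated target site). Clustering clip positions recovers
the breakpoint; per-column majority voting over the clipped segments
reconstructs both ends of the insertion; the poly(A) tract and the target-site
duplication (TSD) are then read off the reconstructed 3' tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from .allele_model import InsertionEvent, wildtype_window

logger = logging.getLogger(__name__)

SIDE_LEFT = "left_clip"
SIDE_RIGHT = "right_clip"

_CIGAR_SOFT_CLIP = 4


class SamParseError(ValueError):
    """A SAM stream could not be parsed."""

    def __init__(self, path: str, record_index: int, reason: str):
        self.path = str(path)
        self.record_index = record_index
        super().__init__(f"malformed SAM record ~#{record_index} in {path}: {reason}")


@dataclass
class ClipCluster:
    """Clipped segments sharing one (reference position, side)."""

    position: int  # 0-based junction offset on the reference
    side: str  # SIDE_LEFT or SIDE_RIGHT
    segments: list[str] = field(default_factory=list)

    @property
    def support(self) -> int:
        return len(self.segments)


@dataclass
class InsertionCharacterization:
    """Breakpoint, reconstructed insertion ends, poly(A) and TSD."""

    breakpoint: int | None
    head_consensus: str = ""  # 5' end of the insertion (right-clip consensus)
    tail_consensus: str = ""  # 3' end of the insertion (left-clip consensus)
    polya: tuple[int, int] | None = None  # (start, length) within tail_consensus
    tsd: str = ""
    head_support: int = 0
    tail_support: int = 0


def collect_clip_clusters(
    sam_path: str | Path, min_clip_len: int = 5
) -> list[ClipCluster]:
    """Group soft-clipped segments by (reference position, side).

    Right-clips are anchored at the end of the aligned portion, left-clips at
    its start; unmapped, secondary and supplementary records are skipped, as
    are clips shorter than ``min_clip_len``. Clipped bases come from the SEQ
    field and are therefore in reference orientation.
    """
    if min_clip_len < 1:
        raise ValueError("min_clip_len must be >= 1")
    clusters: dict[tuple[int, str], ClipCluster] = {}
    try:
        samfile = pysam.AlignmentFile(str(sam_path), "r", check_sq=False)
    except (ValueError, OSError) as exc:
        raise SamParseError(str(sam_path), 0, str(exc)) from exc
    with samfile:
        index = -1
        try:
            for index, rec in enumerate(samfile):
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                cigar = rec.cigartuples
                seq = rec.query_sequence
                if not cigar or seq is None:
                    continue
                op0, len0 = cigar[0]
                if op0 == _CIGAR_SOFT_CLIP and len0 >= min_clip_len:
                    key = (rec.reference_start, SIDE_LEFT)
                    clusters.setdefault(
                        key, ClipCluster(rec.reference_start, SIDE_LEFT)
                    ).segments.append(seq[:len0])
                opn, lenn = cigar[-1]
                if len(cigar) > 1 and opn == _CIGAR_SOFT_CLIP and lenn >= min_clip_len:
                    key = (rec.reference_end, SIDE_RIGHT)
                    clusters.setdefault(
                        key, ClipCluster(rec.reference_end, SIDE_RIGHT)
                    ).segments.append(seq[-lenn:])
        except (ValueError, OSError) as exc:
            raise SamParseError(str(sam_path), index + 1, str(exc)) from exc
    return [clusters[k] for k in sorted(clusters)]


def call_breakpoint(
    clusters: list[ClipCluster], min_support: int = 3
) -> int | None:
    """Position of the best-supported clip cluster, or None.

    Support from left- and right-clip clusters at the same position is summed:
    both sides of a genuine insertion clip at the same reference offset. Ties
    are broken toward the smaller coordinate (logged).
    """
    support: dict[int, int] = {}
    for c in clusters:
        support[c.position] = support.get(c.position, 0) + c.support
    qualifying = {p: s for p, s in support.items() if s >= min_support}
    if not qualifying:
        return None
    best = max(qualifying.values())
    tied = sorted(p for p, s in qualifying.items() if s == best)
    if len(tied) > 1:
        logger.info(
            "breakpoint tie at support %d between positions %s; choosing %d",
            best,
            tied,
            tied[0],
        )
    return tied[0]


def clip_consensus(cluster: ClipCluster) -> str:
    """Per-column majority consensus of a cluster's clipped segments.

    Segments are anchored at the clip point: right-clips align at their left
    edge (all start at the junction), left-clips at their right edge (all end
    at the junction). Consensus length equals the longest segment; column ties
    go to the lexicographically smallest base (logged at debug level).
    """
    if not cluster.segments:
        raise ValueError("cannot build a consensus from an empty cluster")
    right_anchored = cluster.side == SIDE_LEFT
    segs = (
        [s[::-1] for s in cluster.segments] if right_anchored else cluster.segments
    )
    length = max(len(s) for s in segs)
    out = []
    for col in range(length):
        votes: dict[str, int] = {}
        for s in segs:
            if col < len(s):
                votes[s[col]] = votes.get(s[col], 0) + 1
        best = max(votes.values())
        tied = sorted(b for b, n in votes.items() if n == best)
        if len(tied) > 1:
            logger.debug("consensus tie at column %d among %s", col, tied)
        out.append(tied[0])
    consensus = "".join(out)
    return consensus[::-1] if right_anchored else consensus


def detect_polya(
    sequence: str, min_run: int = 8, purity: float = 0.9
) -> tuple[int, int] | None:
    """Locate the rightmost poly(A) tract: (start, length), or None.

    Finds the rightmost window of ``min_run`` bases whose A-fraction is at
    least ``purity``, then extends it outward over consecutive A's only.
    Purity below 1 tolerates errors inside the seed window; the extension is
    exact-A so that flanking sequence which merely contains A's cannot be
    absorbed into the tract (a purity-greedy extension would cross isolated
    non-A bases and systematically overshoot the tract boundary).
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if not (0.5 < purity <= 1.0):
        raise ValueError("purity must lie in (0.5, 1]")
    if min_run < 4:
        raise ValueError("min_run must be >= 4")
    n = len(sequence)
    if n < min_run:
        return None
    is_a = [c in "Aa" for c in sequence]
    prefix = [0]
    for flag in is_a:
        prefix.append(prefix[-1] + flag)

    def a_count(i: int, j: int) -> int:
        return prefix[j] - prefix[i]

    start = None
    for i in range(n - min_run, -1, -1):
        if a_count(i, i + min_run) >= purity * min_run:
            start = i
            break
    if start is None:
        return None
    end = start + min_run
    while end < n and is_a[end]:
        end += 1
    while start > 0 and is_a[start - 1]:
        start -= 1
    while start < end and not is_a[start]:
        start += 1
    while end > start and not is_a[end - 1]:
        end -= 1
    if end - start < min_run:
        return None
    return start, end - start


def detect_tsd(insertion_tail: str, left_flank: str, max_len: int = 30) -> str:
    """Longest common suffix of the insertion tail and the upstream reference.

    The target-site duplication is host sequence repeated at the end of the
    insertion, so it is simultaneously a suffix of the reconstructed tail and
    of the reference immediately 5' of the breakpoint. Capped at ``max_len``;
    empty string when the suffixes disagree at the last base.
    """
    if not insertion_tail or not left_flank:
        raise ValueError("insertion_tail and left_flank must be non-empty")
    limit = min(len(insertion_tail), len(left_flank), max_len)
    n = 0
    while n < limit and insertion_tail[-(n + 1)].upper() == left_flank[-(n + 1)].upper():
        n += 1
    return insertion_tail[len(insertion_tail) - n:] if n else ""


def characterize(
    sam_path: str | Path,
    event_or_reference: InsertionEvent | str,
    min_clip_len: int = 5,
    min_support: int = 3,
    min_run: int = 8,
    purity: float = 0.9,
    max_tsd_len: int = 30,
) -> InsertionCharacterization:
    """Full pipeline: clusters -> breakpoint -> consensus -> poly(A) + TSD.

    ``event_or_reference`` supplies the reference context: either an
    :class:`InsertionEvent` (its wildtype window, in the same window-local
    coordinates as the SAM) or the reference sequence itself as a string.

    The TSD is recovered first, as the longest common suffix of the
    reconstructed tail and the reference upstream of the breakpoint; the
    poly(A) is then searched in the tail with the TSD removed. Recovering the
    TSD from the reference-anchored suffix before the poly(A) keeps A-initial
    TSDs (such as AAAGAAAACAC) from being swallowed by the homopolymer
    detector.
    """
    if isinstance(event_or_reference, InsertionEvent):
        reference = wildtype_window(event_or_reference)
    else:
        reference = str(event_or_reference)
    clusters = collect_clip_clusters(sam_path, min_clip_len=min_clip_len)
    breakpoint_ = call_breakpoint(clusters, min_support=min_support)
    if breakpoint_ is None:
        logger.info("no clip cluster reached support %d; nothing to characterize", min_support)
        return InsertionCharacterization(breakpoint=None)

    by_key = {(c.position, c.side): c for c in clusters}
    head = by_key.get((breakpoint_, SIDE_RIGHT))
    tail = by_key.get((breakpoint_, SIDE_LEFT))
    result = InsertionCharacterization(
        breakpoint=breakpoint_,
        head_support=head.support if head else 0,
        tail_support=tail.support if tail else 0,
    )
    if head:
        result.head_consensus = clip_consensus(head)
    if tail:
        result.tail_consensus = clip_consensus(tail)
        upstream = reference[:breakpoint_]
        if upstream:
            result.tsd = detect_tsd(result.tail_consensus, upstream, max_len=max_tsd_len)
        trimmed = (
            result.tail_consensus[: len(result.tail_consensus) - len(result.tsd)]
            if result.tsd
            else result.tail_consensus
        )
        if len(trimmed) >= min_run:
            result.polya = detect_polya(trimmed, min_run=min_run, purity=purity)
    return result
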