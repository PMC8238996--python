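"""Junction-read genotyping directly from raw FASTQ.

The method is a grep-style screen: count reads that contain the mutant
5' junction k-mer (reference flank joined to the start of the inserted
element) and reads that contain the wildtype junction k-mer (the intact
reference across the insertion point), then form the variant allele fraction

    VAF = mutant_reads / (mutant_reads + wildtype_reads)

and classify: VAF < 0.1 -> no insertion, 0.1 <= VAF < 0.3 -> insertion
suspected, VAF >= 0.3 -> insertion detected. Matching is exact by default,
with an optional substitution-only (Hamming) mismatch allowance to tolerate
sequencing errors or rare SNVs inside the junction window. Both read
orientations are searched by default, because FASTQ reads sample both genomic
strands.

No alignment, duplicate marking or base-quality filtering is performed: the
screen runs on unprocessed reads.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .allele_model import InsertionEvent, JunctionQuery, junction_queries

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

CALL_NO_INSERTION = "No AluY insertion"
CALL_SUSPECTED = "AluY insertion suspected"
CALL_DETECTED = "AluY insertion detected"
CALL_INSUFFICIENT = "insufficient data"


class FastqParseError(ValueError):
    """A FASTQ stream violated the 4-line record format."""

    def __init__(self, path: str, record_index: int, reason: str):
        self.path = str(path)
        self.record_index = record_index
        super().__init__(
            f"malformed FASTQ record ~#{record_index} in {path}: {reason}"
        )


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class JunctionCounts:
    """Per-category junction read counts with an orientation breakdown."""

    mutant_reads: int = 0
    wildtype_reads: int = 0
    total_reads_scanned: int = 0
    mutant_forward: int = 0
    mutant_reverse: int = 0
    wildtype_forward: int = 0
    wildtype_reverse: int = 0
    dual_match_reads: int = 0  # reads matching both categories (query collision)

    def as_dict(self) -> dict:
        return {
            "mutant_reads": self.mutant_reads,
            "wildtype_reads": self.wildtype_reads,
            "total_reads_scanned": self.total_reads_scanned,
            "mutant_forward": self.mutant_forward,
            "mutant_reverse": self.mutant_reverse,
            "wildtype_forward": self.wildtype_forward,
            "wildtype_reverse": self.wildtype_reverse,
            "dual_match_reads": self.dual_match_reads,
        }


@dataclass(frozen=True)
class ClassificationPolicy:
    """VAF thresholds for the three-way call.

    Lower bounds are closed: VAF exactly at ``low_threshold`` is "suspected",
    exactly at ``high_threshold`` is "detected".
    """

    low_threshold: float = 0.1
    high_threshold: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 < self.low_threshold < self.high_threshold < 1.0):
            raise ValueError(
                "thresholds must satisfy 0 < low_threshold < high_threshold < 1"
            )


@dataclass
class GenotypeCall:
    """Result of screening one sample: counts, VAF, call, and parameters."""

    vaf: float | None
    call: str
    counts: JunctionCounts
    max_mismatch: int = 0
    search_revcomp: bool = True
    k_ref: int = 13
    k_alt: int = 13
    policy: ClassificationPolicy = field(default_factory=ClassificationPolicy)


def count_read_matches(read_sequence: str, query_sequence: str, max_mismatch: int = 0) -> int:
    """Number of offsets at which ``query_sequence`` matches the read.

    A match at an offset means Hamming distance <= ``max_mismatch`` over the
    query length (substitutions only). Positions holding non-ACGT characters
    (e.g. N) on either side never match. A query longer than the read yields 0.
    """
    if max_mismatch not in (0, 1, 2):
        raise ValueError("max_mismatch must be 0, 1 or 2")
    read = read_sequence.upper()
    query = query_sequence.upper()
    qlen = len(query)
    if qlen == 0 or qlen > len(read):
        return 0
    if max_mismatch == 0 and set(read) <= ALPHABET and set(query) <= ALPHABET:
        # exact matching on a clean read reduces to substring counting
        count = start = 0
        while True:
            i = read.find(query, start)
            if i < 0:
                return count
            count += 1
            start = i + 1
    count = 0
    for offset in range(len(read) - qlen + 1):
        mismatches = 0
        for j in range(qlen):
            r = read[offset + j]
            if r != query[j] or r not in ALPHABET:
                mismatches += 1
                if mismatches > max_mismatch:
                    break
        else:
            count += 1
    return count


def _matches(read: str, query: str, max_mismatch: int) -> bool:
    if max_mismatch == 0:
        return query in read
    qlen = len(query)
    if qlen > len(read):
        return False
    for offset in range(len(read) - qlen + 1):
        mismatches = 0
        for j in range(qlen):
            r = read[offset + j]
            if r != query[j] or r not in ALPHABET:
                mismatches += 1
                if mismatches > max_mismatch:
                    break
        else:
            return True
    return False


def _open_fastq(path: str | Path):
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _iter_fastq(path: str | Path):
    """Yield (index, sequence) from a FASTQ file, with parse-error context."""
    index = 0
    try:
        with _open_fastq(path) as handle:
            for _title, seq, qual in FastqGeneralIterator(handle):
                if len(seq) != len(qual):
                    raise FastqParseError(
                        str(path), index, "sequence and quality lengths differ"
                    )
                yield index, seq
                index += 1
    except FastqParseError:
        raise
    except ValueError as exc:
        raise FastqParseError(str(path), index, str(exc)) from exc


def scan_fastq(
    fastq_paths: Sequence[str | Path] | str | Path,
    queries: Iterable[JunctionQuery],
    max_mismatch: int = 0,
    search_revcomp: bool = True,
) -> JunctionCounts:
    """Stream FASTQ file(s) and count junction-supporting reads.

    Each read increments ``mutant_reads`` at most once if any mutant-kind query
    matches the read (or, with ``search_revcomp``, its reverse complement), and
    analogously ``wildtype_reads`` for the wildtype query. Only sequence lines
    are searched. A read matching both categories increments both and is
    tallied in ``dual_match_reads`` with a warning: that indicates a
    query-design collision worth inspecting, not a biological signal.
    """
    if isinstance(fastq_paths, (str, Path)):
        fastq_paths = [fastq_paths]
    queries = list(queries)
    mutant_queries = [q.sequence.upper() for q in queries if q.is_mutant]
    wildtype_queries = [q.sequence.upper() for q in queries if not q.is_mutant]
    if not mutant_queries or not wildtype_queries:
        raise ValueError(
            "need at least one mutant-kind query and the wildtype query"
        )

    counts = JunctionCounts()
    for path in fastq_paths:
        for _index, seq in _iter_fastq(path):
            counts.total_reads_scanned += 1
            read = seq.upper()
            rc = reverse_complement(read) if search_revcomp else None

            mut_fwd = any(_matches(read, q, max_mismatch) for q in mutant_queries)
            mut_rev = (
                rc is not None
                and not mut_fwd
                and any(_matches(rc, q, max_mismatch) for q in mutant_queries)
            )
            wt_fwd = any(_matches(read, q, max_mismatch) for q in wildtype_queries)
            wt_rev = (
                rc is not None
                and not wt_fwd
                and any(_matches(rc, q, max_mismatch) for q in wildtype_queries)
            )

            if mut_fwd or mut_rev:
                counts.mutant_reads += 1
                counts.mutant_forward += int(mut_fwd)
                counts.mutant_reverse += int(mut_rev)
            if wt_fwd or wt_rev:
                counts.wildtype_reads += 1
                counts.wildtype_forward += int(wt_fwd)
                counts.wildtype_reverse += int(wt_rev)
            if (mut_fwd or mut_rev) and (wt_fwd or wt_rev):
                counts.dual_match_reads += 1
                logger.warning(
                    "read #%d in %s matches both mutant and wildtype junction "
                    "queries; check query design",
                    _index,
                    path,
                )
    return counts


def compute_vaf(counts: JunctionCounts) -> float | None:
    """mutant / (mutant + wildtype); None when no junction reads were seen."""
    denominator = counts.mutant_reads + counts.wildtype_reads
    if denominator == 0:
        return None
    return counts.mutant_reads / denominator


def classify_call(
    vaf: float | None, policy: ClassificationPolicy | None = None
) -> str:
    """Map a VAF onto the three-way call (or "insufficient data" for None)."""
    if policy is None:
        policy = ClassificationPolicy()
    if vaf is None:
        return CALL_INSUFFICIENT
    if not (0.0 <= vaf <= 1.0):
        raise ValueError(f"vaf must lie in [0, 1], got {vaf}")
    if vaf < policy.low_threshold:
        return CALL_NO_INSERTION
    if vaf < policy.high_threshold:
        return CALL_SUSPECTED
    return CALL_DETECTED


def genotype_sample(
    fastq_paths: Sequence[str | Path] | str | Path,
    event: InsertionEvent,
    k_ref: int = 13,
    k_alt: int = 13,
    max_mismatch: int = 0,
    search_revcomp: bool = True,
    policy: ClassificationPolicy | None = None,
    include_3prime: bool = False,
) -> GenotypeCall:
    """Screen a sample's FASTQ file(s) for the insertion and call the genotype."""
    if policy is None:
        policy = ClassificationPolicy()
    queries = junction_queries(
        event, k_ref=k_ref, k_alt=k_alt, include_3prime=include_3prime
    )
    counts = scan_fastq(
        fastq_paths, queries, max_mismatch=max_mismatch, search_revcomp=search_revcomp
    )
    vaf = compute_vaf(counts)
    call = classify_call(vaf, policy)
    return GenotypeCall(
        vaf=vaf,
        call=call,
        counts=counts,
        max_mismatch=max_mismatch,
        search_revcomp=search_revcomp,
        k_ref=k_ref,
        k_alt=k_alt,
        policy=policy,
    )
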