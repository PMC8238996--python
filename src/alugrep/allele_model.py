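"""Model of a mobile-element insertion allele and its diagnostic junctions.

An Alu retrotransposition event leaves a characteristic anatomy at the
integration site: the element body, a 3' poly(A) tract, and a short target-site
duplication (TSD) — a direct repeat of the host sequence immediately upstream of
the breakpoint, copied to the far side of the insertion during target-primed
reverse transcription. :class:`InsertionEvent` captures that anatomy together
with its genomic anchor, and :func:`junction_queries` derives the short
flank+element k-mers (13 bp reference side + 13 bp element side by default) that
discriminate reads from the insertion allele from reads of the intact
reference.

Coordinates are 0-based half-open internally; ``position`` is the gap offset of
the insertion point between two reference bases. Entry points that face users
(:func:`build_event_from_reference`, the CLI) accept 1-based positions.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

ALPHABET = frozenset("ACGT")

KIND_MUTANT_5P = "mutant_5prime"
KIND_MUTANT_3P = "mutant_3prime"
KIND_WILDTYPE = "wildtype"


class AlleleModelError(ValueError):
    """Base class for invalid insertion-event construction."""


class AlphabetError(AlleleModelError):
    """A sequence contains characters outside {A, C, G, T}."""


class InvalidEventError(AlleleModelError):
    """Event fields violate the insertion-allele invariants."""


def _require_acgt(name: str, seq: str) -> None:
    if not set(seq) <= ALPHABET:
        bad = sorted(set(seq) - ALPHABET)
        raise AlphabetError(f"{name} contains non-ACGT characters: {bad}")


@dataclass(frozen=True)
class InsertionEvent:
    """An insertion allele: reference flanks plus body + poly(A) + TSD.

    ``tsd`` must equal the suffix of ``left_flank`` of the same length: the
    duplication is host sequence, present once in the reference and twice in
    the insertion allele (behind the poly(A) tail).
    """

    contig: str
    position: int  # 0-based gap offset between two reference bases
    left_flank: str
    right_flank: str
    body: str
    polya_len: int
    tsd: str
    label: str = ""

    def __post_init__(self) -> None:
        _require_acgt("left_flank", self.left_flank)
        _require_acgt("right_flank", self.right_flank)
        _require_acgt("body", self.body)
        if self.tsd:
            _require_acgt("tsd", self.tsd)
        if not self.body:
            raise InvalidEventError("insertion body must be non-empty")
        if self.polya_len < 0:
            raise InvalidEventError("polya_len must be >= 0")
        if self.position < 0:
            raise InvalidEventError("position must be >= 0")
        if self.tsd and not self.left_flank.endswith(self.tsd):
            raise InvalidEventError(
                "tsd must equal the suffix of left_flank of the same length"
            )

    @property
    def inserted_length(self) -> int:
        """Total inserted bases: body + poly(A) tract + duplicated TSD."""
        return len(self.body) + self.polya_len + len(self.tsd)

    @property
    def position_1based(self) -> int:
        """1-based position of the reference base immediately 5' of the gap."""
        return self.position


@dataclass(frozen=True)
class JunctionQuery:
    """A short search string spanning an allele-diagnostic junction.

    ``kind`` is one of ``mutant_5prime`` (reference flank into element body),
    ``mutant_3prime`` (poly(A) context + TSD into the downstream flank; only
    informative with the poly(A) context prefix, since TSD + right flank alone
    is identical in both alleles) or ``wildtype`` (the intact reference across
    the insertion point).
    """

    kind: str
    sequence: str
    k_ref: int
    k_alt: int

    def __post_init__(self) -> None:
        if self.kind not in (KIND_MUTANT_5P, KIND_MUTANT_3P, KIND_WILDTYPE):
            raise InvalidEventError(f"unknown junction kind {self.kind!r}")
        _require_acgt("query sequence", self.sequence)

    @property
    def is_mutant(self) -> bool:
        return self.kind in (KIND_MUTANT_5P, KIND_MUTANT_3P)


def build_event(
    contig: str,
    position: int,
    left_flank: str,
    right_flank: str,
    body: str,
    polya_len: int,
    tsd_len: int,
    label: str = "",
) -> InsertionEvent:
    """Construct a validated :class:`InsertionEvent`.

    The TSD is taken as the last ``tsd_len`` bases of ``left_flank`` — the
    duplicated host sequence is by definition the reference immediately
    upstream of the insertion point.
    """
    if tsd_len < 0:
        raise InvalidEventError("tsd_len must be >= 0")
    if tsd_len > len(left_flank):
        raise InvalidEventError(
            f"tsd_len {tsd_len} exceeds left flank length {len(left_flank)}"
        )
    tsd = left_flank[len(left_flank) - tsd_len:] if tsd_len else ""
    return InsertionEvent(
        contig=contig,
        position=position,
        left_flank=left_flank,
        right_flank=right_flank,
        body=body,
        polya_len=polya_len,
        tsd=tsd,
        label=label,
    )


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def build_event_from_reference(
    fasta_path: str | Path,
    contig: str,
    position_1based: int,
    flank_len: int,
    body: str,
    polya_len: int,
    tsd_len: int,
    label: str = "",
) -> InsertionEvent:
    """Build an event by extracting flanks from a reference FASTA.

    ``position_1based`` is the 1-based coordinate of the last reference base
    before the insertion point; the left flank is the ``flank_len`` bases
    ending at that base, the right flank the ``flank_len`` bases after it.
    The FASTA may be plain or gzip-compressed and multi-line.
    """
    with _open_maybe_gzip(fasta_path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id == contig:
                ref = str(record.seq).upper()
                break
        else:
            raise KeyError(f"contig {contig!r} not found in {fasta_path}")
    position = position_1based  # 0-based gap offset after that base
    if position_1based < 1 or position - flank_len < 0 or position + flank_len > len(ref):
        raise IndexError(
            f"flanks of length {flank_len} around 1-based position "
            f"{position_1based} fall outside contig {contig!r} (length {len(ref)})"
        )
    left_flank = ref[position - flank_len: position]
    right_flank = ref[position: position + flank_len]
    return build_event(
        contig, position, left_flank, right_flank, body, polya_len, tsd_len, label
    )


def wildtype_window(event: InsertionEvent) -> str:
    """The intact reference across the insertion point (both flanks joined)."""
    return event.left_flank + event.right_flank


def mutant_haplotype(event: InsertionEvent) -> str:
    """The insertion allele: left flank, body, poly(A), duplicated TSD, right flank."""
    return (
        event.left_flank
        + event.body
        + "A" * event.polya_len
        + event.tsd
        + event.right_flank
    )


def inserted_length(event: InsertionEvent) -> int:
    """Total inserted bases (body + poly(A) + TSD)."""
    return event.inserted_length


def junction_queries(
    event: InsertionEvent,
    k_ref: int = 13,
    k_alt: int = 13,
    polya_context: int = 6,
    include_3prime: bool = False,
) -> list[JunctionQuery]:
    """Derive the discriminative junction queries for an event.

    Returns the 5' mutant query (last ``k_ref`` bases of the left flank joined
    to the first ``k_alt`` bases of the body) and the wildtype query (the same
    reference bases joined to the first ``k_alt`` bases of the right flank).
    With ``include_3prime``, also returns the 3' mutant query —
    ``polya_context`` A's, the TSD, then the first ``k_ref`` bases of the right
    flank. The 3' query is off by default: the 5' junction alone is
    discriminative, and the naive 3' junction (TSD + right flank) occurs in
    both alleles.
    """
    if k_ref < 1 or k_alt < 1:
        raise IndexError("k_ref and k_alt must be >= 1")
    if k_ref > len(event.left_flank):
        raise IndexError(
            f"k_ref {k_ref} exceeds left flank length {len(event.left_flank)}"
        )
    if k_alt > len(event.body):
        raise IndexError(f"k_alt {k_alt} exceeds body length {len(event.body)}")
    if k_alt > len(event.right_flank) or k_ref > len(event.right_flank):
        raise IndexError(
            f"query size exceeds right flank length {len(event.right_flank)}"
        )
    ref_side = event.left_flank[-k_ref:]
    queries = [
        JunctionQuery(KIND_MUTANT_5P, ref_side + event.body[:k_alt], k_ref, k_alt),
        JunctionQuery(KIND_WILDTYPE, ref_side + event.right_flank[:k_alt], k_ref, k_alt),
    ]
    if include_3prime:
        context = "A" * min(polya_context, event.polya_len)
        queries.append(
            JunctionQuery(
                KIND_MUTANT_3P,
                context + event.tsd + event.right_flank[:k_ref],
                k_ref,
                k_alt,
            )
        )
    return queries
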