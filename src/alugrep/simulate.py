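"""Seeded synthetic read data for insertion alleles.

Generates FASTQ reads (plus a tab-separated truth table) and SAM alignments
from a diploid sample carrying an :class:`~alugrep.allele_model.InsertionEvent`
on zero, one or both haplotypes, so the junction genotyper and the soft-clip
characterizer can be exercised end to end with no external data.

The model is deliberately simple: uniform read starts over each source
haplotype, i.i.d. per-base substitution errors, a 50/50 strand flip, constant
base qualities. Capture or amplification bias against the insertion allele —
which in practice depresses the observed VAF on hybridization-capture
platforms relative to PCR-free genome sequencing — is emulated abstractly by
``alt_fraction``, the probability that a read of a heterozygote is drawn from
the insertion haplotype.

Alignments are emitted against the wildtype window in window-local
coordinates: insertion-haplotype reads crossing the breakpoint carry
soft-clips whose clipped bases are the inserted sequence, exactly the evidence
pattern a genome viewer shows at a mobile-element insertion. Everything is a
pure function of (config, seed): identical configs give byte-identical files.
"""

from __future__ import annotations

import gzip
import random
from dataclasses import dataclass, field
from pathlib import Path

from .allele_model import (
    InsertionEvent,
    build_event,
    junction_queries,
    mutant_haplotype,
    wildtype_window,
)
from .genotyper import reverse_complement

GENOTYPES = ("hom_ref", "het", "hom_alt")

_BASES = "ACGT"
_OTHER = {b: _BASES.replace(b, "") for b in _BASES}


class SimulatorConfigError(ValueError):
    """Invalid simulation parameters."""


@dataclass(frozen=True)
class SimulationConfig:
    event: InsertionEvent
    genotype: str = "het"
    depth: float = 60.0
    read_len: int = 100
    error_rate: float = 0.0
    alt_fraction: float = 0.5
    seed: int = 0
    paired: bool = False  # affects read naming only (/1 suffix); detection is single-end

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise SimulatorConfigError(f"genotype must be one of {GENOTYPES}")
        if not (0.0 <= self.error_rate < 0.2):
            raise SimulatorConfigError("error_rate must lie in [0, 0.2)")
        if not (0.0 < self.alt_fraction < 1.0):
            raise SimulatorConfigError("alt_fraction must lie in (0, 1)")
        if self.depth <= 0:
            raise SimulatorConfigError("depth must be > 0")
        if self.read_len < 26:
            raise SimulatorConfigError("read_len must be >= 26 (k_ref + k_alt)")
        region = len(self.event.left_flank) + len(self.event.right_flank)
        if region < self.read_len:
            raise SimulatorConfigError(
                f"wildtype window ({region} bp) shorter than read_len"
            )

    @property
    def region_length(self) -> int:
        """Genotype-weighted source length: the expected bases of haplotype
        sequence contributing reads, so that ``depth`` is per-base coverage on
        each haplotype at its configured allele fraction."""
        wt = len(self.event.left_flank) + len(self.event.right_flank)
        alt = wt + self.event.inserted_length
        if self.genotype == "hom_ref":
            return wt
        if self.genotype == "hom_alt":
            return alt
        return round(self.alt_fraction * alt + (1 - self.alt_fraction) * wt)

    @property
    def n_reads(self) -> int:
        return round(self.depth * self.region_length / self.read_len)

    @property
    def alt_read_probability(self) -> float:
        """Per-read probability of drawing the insertion haplotype.

        Weighted by haplotype length so that per-base coverage — and hence the
        expected fraction of junction-spanning reads — splits as
        ``alt_fraction`` : 1 - ``alt_fraction``. An unweighted per-read coin at
        ``alt_fraction`` would under-cover the longer insertion haplotype and
        bias the recovered VAF downward.
        """
        if self.genotype == "hom_ref":
            return 0.0
        if self.genotype == "hom_alt":
            return 1.0
        wt = len(self.event.left_flank) + len(self.event.right_flank)
        alt = wt + self.event.inserted_length
        # weight by the number of valid start positions: with uniform starts,
        # the coverage of any interior locus is n_hap * (read_len - w + 1) /
        # (L_hap - read_len + 1), so start-count weighting makes the junction
        # coverage ratio exactly alt_fraction : 1 - alt_fraction
        alt_starts = alt - self.read_len + 1
        wt_starts = wt - self.read_len + 1
        return self.alt_fraction * alt_starts / (
            self.alt_fraction * alt_starts + (1 - self.alt_fraction) * wt_starts
        )


@dataclass
class TruthRecord:
    """Ground truth for one simulated read."""

    read_id: str
    haplotype: str  # "ref" or "alt"
    start: int  # 0-based start on the source haplotype
    orientation: str  # "+" sampled forward, "-" sampled as reverse complement
    clip_side: str | None  # "left" / "right" when projected onto the reference
    clip_len: int
    unmapped: bool


@dataclass
class _SimulatedRead:
    read_id: str
    haplotype: str
    start: int
    orientation: str
    sequence: str  # haplotype-forward orientation, errors applied
    truth: TruthRecord = field(init=False)


def make_synthetic_event(
    seed: int,
    flank_len: int = 120,
    body_len: int = 300,
    polya_len: int = 20,
    tsd_len: int = 11,
    k_ref: int = 13,
    k_alt: int = 13,
    max_tries: int = 200,
) -> InsertionEvent:
    """Draw a random insertion event whose junctions are unambiguous.

    The left flank is forced to end with the drawn TSD. Candidate events are
    rejected and redrawn when (a) either junction query recurs anywhere in
    either haplotype beyond its one defining locus, or (b) the poly(A)/TSD
    boundary would be unobservable — the TSD starting with A, the flank base
    before the TSD being A, or the body ending in A all merge host or element
    A's into the poly(A) tract and make exact recovery ill-posed.
    """
    if flank_len < k_ref + tsd_len or flank_len < k_alt:
        raise SimulatorConfigError("flank_len must be >= k_ref + tsd_len")
    if body_len < k_alt:
        raise SimulatorConfigError("body_len must be >= k_alt")
    if tsd_len < 0 or polya_len < 0:
        raise SimulatorConfigError("tsd_len and polya_len must be >= 0")
    rng = random.Random(seed)
    for _ in range(max_tries):
        tsd = "".join(rng.choice(_BASES) for _ in range(tsd_len))
        left = (
            "".join(rng.choice(_BASES) for _ in range(flank_len - tsd_len)) + tsd
        )
        right = "".join(rng.choice(_BASES) for _ in range(flank_len))
        body = "".join(rng.choice(_BASES) for _ in range(body_len))
        if tsd and tsd[0] == "A":
            continue
        if tsd and left[-tsd_len - 1] == "A":
            continue
        if body[-1] == "A":
            continue
        event = build_event(
            contig="synthetic",
            position=flank_len,
            left_flank=left,
            right_flank=right,
            body=body,
            polya_len=polya_len,
            tsd_len=tsd_len,
            label=f"synthetic-seed{seed}",
        )
        mut_q, wt_q = junction_queries(event, k_ref=k_ref, k_alt=k_alt)[:2]
        wt_hap = wildtype_window(event)
        mut_hap = mutant_haplotype(event)
        # a TSD at least k_ref long inherently contains the whole reference
        # side of the wildtype query, so the mutant 3' junction (TSD + right
        # flank) reproduces it once; that occurrence is expected, not a
        # collision (the wildtype query stops being discriminative for such
        # events, which remain valid for breakpoint/TSD characterization)
        expected_wt_in_mut = 1 if tsd_len >= k_ref else 0
        if wt_hap.count(mut_q.sequence) != 0:
            continue
        if mut_hap.count(mut_q.sequence) != 1:
            continue
        if wt_hap.count(wt_q.sequence) != 1:
            continue
        if mut_hap.count(wt_q.sequence) != expected_wt_in_mut:
            continue
        return event
    raise SimulatorConfigError(
        f"could not draw a collision-free event in {max_tries} tries; "
        "constraints may be unsatisfiable"
    )


def _clip_expectation(
    start: int, read_len: int, flank_len: int, ins_len: int
) -> tuple[str | None, int, bool]:
    """(clip_side, clip_len, unmapped) for an insertion-haplotype read.

    ``flank_len`` is the junction offset on the reference (window-local);
    ``ins_len`` the inserted length. Reads crossing the 5' breakpoint are
    right-clipped at the junction; reads emerging from the insertion into the
    right flank are left-clipped; reads fully inside the insertion are
    unmapped (no reference anchor).
    """
    end = start + read_len
    if end <= flank_len or start >= flank_len + ins_len:
        return None, 0, False
    if start < flank_len:
        return "right", end - flank_len, False
    if end <= flank_len + ins_len:
        return None, 0, True
    return "left", flank_len + ins_len - start, False


def _draw_reads(config: SimulationConfig) -> list[_SimulatedRead]:
    rng = random.Random(config.seed)
    event = config.event
    wt_hap = wildtype_window(event)
    mut_hap = mutant_haplotype(event)
    flank_len = len(event.left_flank)
    ins_len = event.inserted_length
    suffix = "/1" if config.paired else ""

    reads = []
    p_alt = config.alt_read_probability
    for i in range(config.n_reads):
        if config.genotype == "hom_ref":
            hap_name = "ref"
        elif config.genotype == "hom_alt":
            hap_name = "alt"
        else:
            hap_name = "alt" if rng.random() < p_alt else "ref"
        hap = mut_hap if hap_name == "alt" else wt_hap
        start = rng.randrange(0, len(hap) - config.read_len + 1)
        orientation = "+" if rng.random() < 0.5 else "-"
        seq = hap[start: start + config.read_len]
        if config.error_rate > 0:
            chars = list(seq)
            for j in range(len(chars)):
                if rng.random() < config.error_rate:
                    chars[j] = rng.choice(_OTHER[chars[j]])
            seq = "".join(chars)
        read = _SimulatedRead(
            read_id=f"sim_{event.label or 'event'}_{i:06d}{suffix}",
            haplotype=hap_name,
            start=start,
            orientation=orientation,
            sequence=seq,
        )
        if hap_name == "alt":
            side, clip_len, unmapped = _clip_expectation(
                start, config.read_len, flank_len, ins_len
            )
        else:
            side, clip_len, unmapped = None, 0, False
        read.truth = TruthRecord(
            read_id=read.read_id,
            haplotype=hap_name,
            start=start,
            orientation=orientation,
            clip_side=side,
            clip_len=clip_len,
            unmapped=unmapped,
        )
        reads.append(read)
    return reads


def _count_informative(config: SimulationConfig, reads: list[_SimulatedRead], k_ref: int = 13, k_alt: int = 13) -> int:
    """Alt-haplotype reads spanning the 5' junction with full query context."""
    flank_len = len(config.event.left_flank)
    n = 0
    for r in reads:
        if r.haplotype != "alt":
            continue
        if r.start <= flank_len - k_ref and r.start + config.read_len >= flank_len + k_alt:
            n += 1
    return n


def simulate_reads(
    config: SimulationConfig,
    out_fastq: str | Path,
    out_truth: str | Path | None = None,
) -> dict:
    """Write FASTQ (gzip if the path ends in .gz) and an optional truth table.

    Reads sampled with "-" orientation are written reverse-complemented, as a
    sequencer would deliver them. Returns a summary dict with the number of
    reads written and the number of insertion-haplotype reads that span the
    5' junction with full query context on both sides.
    """
    reads = _draw_reads(config)
    out_fastq = Path(out_fastq)
    opener = gzip.open if out_fastq.suffix == ".gz" else open
    qual = "I" * config.read_len
    with opener(out_fastq, "wt") as handle:
        for r in reads:
            seq = r.sequence if r.orientation == "+" else reverse_complement(r.sequence)
            handle.write(f"@{r.read_id}\n{seq}\n+\n{qual}\n")
    if out_truth is not None:
        with open(out_truth, "wt") as handle:
            handle.write(
                "read_id\thaplotype\tstart\torientation\tclip_side\tclip_len\tunmapped\n"
            )
            for r in reads:
                t = r.truth
                handle.write(
                    f"{t.read_id}\t{t.haplotype}\t{t.start}\t{t.orientation}\t"
                    f"{t.clip_side or '.'}\t{t.clip_len}\t{int(t.unmapped)}\n"
                )
    return {
        "reads_written": len(reads),
        "mutant_informative_reads": _count_informative(config, reads),
    }


def simulate_alignments(config: SimulationConfig, out_sam: str | Path) -> dict:
    """Write SAM alignments of the simulated reads against the wildtype window.

    Coordinates are window-local: the reference is the concatenated flanks and
    the junction sits at offset len(left_flank). Wildtype-haplotype reads are
    fully aligned; insertion-haplotype reads crossing the breakpoint carry
    soft-clips whose clipped bases are inserted sequence; reads fully inside
    the insertion are emitted unmapped. SEQ is stored in reference (haplotype-
    forward) orientation, with the reverse flag set for "-" reads.
    """
    reads = _draw_reads(config)
    event = config.event
    flank_len = len(event.left_flank)
    ins_len = event.inserted_length
    region = len(event.left_flank) + len(event.right_flank)  # reference length
    qual = "I" * config.read_len
    rl = config.read_len

    lines = ["@HD\tVN:1.6\tSO:unknown", f"@SQ\tSN:{event.contig}\tLN:{region}"]
    n_clipped = n_unmapped = 0
    for r in reads:
        flag = 0 if r.orientation == "+" else 16
        t = r.truth
        if r.haplotype == "ref":
            pos, cigar = r.start + 1, f"{rl}M"
        elif t.unmapped:
            n_unmapped += 1
            lines.append(
                f"{r.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{r.sequence}\t{qual}"
            )
            continue
        elif t.clip_side == "right":
            matched = rl - t.clip_len
            pos, cigar = r.start + 1, f"{matched}M{t.clip_len}S"
            n_clipped += 1
        elif t.clip_side == "left":
            matched = rl - t.clip_len
            pos, cigar = flank_len + 1, f"{t.clip_len}S{matched}M"
            n_clipped += 1
        else:  # alt read entirely within a flank: shift into reference coords
            ref_start = r.start if r.start + rl <= flank_len else r.start - ins_len
            pos, cigar = ref_start + 1, f"{rl}M"
        lines.append(
            f"{r.read_id}\t{flag}\t{event.contig}\t{pos}\t60\t{cigar}"
            f"\t*\t0\t0\t{r.sequence}\t{qual}"
        )
    Path(out_sam).write_text("\n".join(lines) + "\n")
    return {
        "reads_written": len(reads),
        "soft_clipped_reads": n_clipped,
        "unmapped_reads": n_unmapped,
    }
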