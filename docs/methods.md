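# Methods

## The problem

A mobile-element insertion (MEI) longer than a sequencing read is invisible to
standard small-variant callers: reads from the insertion allele either fail to
map or map with their inserted tail soft-clipped away, and the event surfaces —
if at all — as a low-quality indel call destined for filtering. For a *known*
founder insertion, however, none of the machinery of genome-wide MEI discovery
is needed. The insertion junction is a fixed, short, diagnostic string: any raw
read containing the last bases of the reference flank joined to the first bases
of the inserted element proves the allele is present. `alugrep` implements this
junction-grep idea as a library and CLI for the founder AluY insertion in
*RP1* exon 4 (anchored at chr8:55,540,494, hg19), generalized to any
user-described insertion event.

## Allele model

An insertion event is described by its reference flanks and the inserted
sequence anatomy left behind by target-primed reverse transcription:

    mutant haplotype = left_flank + body + A^polya_len + tsd + right_flank
    wildtype window  = left_flank + right_flank

where `body` is the element body (for AluY, 282 bases), `A^polya_len` the 3'
poly(A) tract, and `tsd` the target-site duplication — a direct repeat of the
last `len(tsd)` bases of the left flank, copied to the far side of the
insertion. Total inserted length is `len(body) + polya_len + len(tsd)`; for
the packaged RP1 preset, 282 + 35 + 11 = 328. The poly(A) length of 35 is
derived from the other published quantities (total 328, body 282, TSD 11)
rather than printed directly, and is overridable.

Coordinates are 0-based half-open internally, with `position` the gap offset
between the two reference bases flanking the insertion point; user-facing
entry points take 1-based positions.

Two junction queries are derived per event (defaults `k_ref = k_alt = 13`):

* **mutant 5'**: last 13 bases of the left flank + first 13 bases of the body;
* **wildtype**: the same 13 reference bases + first 13 bases of the right
  flank.

A 3' mutant query (poly(A) context + TSD + right flank) is available but off
by default: without the poly(A) context prefix it occurs in both alleles, and
the 5' junction alone is discriminative. One documented degenerate case: if
the `k_ref − len(tsd)` reference bases immediately 5' of the TSD are all A,
the poly(A)+TSD tail of the mutant allele reproduces the wildtype query; the
scanner counts such dual-matching reads in both categories and logs a
warning rather than silently resolving the collision.

### The packaged preset

The `rp1-aluy-demo` preset is intended for simulation and self-tests. Its
282-base body uses the 43 published junction-proximal bases of the
characterized insertion verbatim and completes the remainder with the AluY
subfamily consensus; the five private divergent bases of the real allele are
not modelled. Its flanks are synthetic: the published description of the
reference side covers only the 11-base TSD (`AAAGAAAACAC`), and fabricating
the remaining genomic sequence would be worse than labelling it. Real-data
scans must therefore build an event from a genuine reference FASTA
(`build_event_from_reference` / `alugrep preset-build`), which extracts true
flanks and stores them in a reusable YAML event config.

## Genotyping

A read supports a category if any query of that category occurs in the read
or (by default) its reverse complement; each read increments each category at
most once. Matching is substitution-only Hamming distance with
`max_mismatch ∈ {0, 1, 2}` (default 0; 1 tolerates a sequencing error or a
rare SNV inside the 26-base junction window). Positions holding non-ACGT
characters never match. Indel-tolerant matching is deliberately excluded: an
indel inside the junction window would change the junction itself.

The variant allele fraction is

    VAF = mutant_reads / (mutant_reads + wildtype_reads)

undefined when no junction reads were seen, and the three-way call is

| VAF | call |
|---|---|
| < 0.1 | No AluY insertion |
| 0.1 ≤ VAF < 0.3 | AluY insertion suspected |
| ≥ 0.3 | AluY insertion detected |

with closed lower bounds. The 0.1 floor absorbs the occasional 1–2 spurious
junction-like reads seen in deep wildtype data; the 0.3 boundary separates
clean heterozygous signal from the depressed VAFs typical of
hybridization-capture data, where probe design biases coverage against the
insertion allele. Both thresholds are parameters (`ClassificationPolicy`).

No alignment, duplicate collapsing, or base-quality filtering is performed —
the method's point is to run on unprocessed FASTQ. Duplicate reads therefore
count individually; for PCR-heavy libraries this inflates both counts roughly
equally and leaves the VAF approximately unbiased, but it is a known
limitation.

## Read simulator

The simulator draws reads from the wildtype and/or mutant haplotype of an
event (genotypes `hom_ref`, `het`, `hom_alt`) with uniform start positions,
i.i.d. per-base substitution errors, a fair strand flip, and constant base
qualities ("I"). Everything is a pure function of the configuration,
including the seed: identical configs give byte-identical FASTQ, truth table
and SAM.

`alt_fraction` (default 0.5) is the expected fraction of *coverage* at the
junction contributed by the insertion haplotype. Because the insertion
haplotype is longer, a naive per-read coin at `alt_fraction` would spread its
reads more thinly and bias the recovered VAF low; the per-read haplotype
probability is therefore weighted by the number of valid read start positions
on each haplotype, which makes the expected junction VAF equal
`alt_fraction` exactly. Setting `alt_fraction` below 0.5 emulates capture
bias abstractly (no probe model is attempted). The read count is
`round(depth × region_length / read_len)` with `region_length` the
genotype-weighted source length, so `depth` is per-base haplotype coverage.

Simulated alignments are emitted as SAM against the wildtype window in
window-local coordinates (the junction sits at `len(left_flank)`):
insertion-haplotype reads crossing the 5' breakpoint are soft-clipped on the
right with the inserted bases as the clip; reads emerging from the insertion
into the right flank are left-clipped; reads fully inside the insertion are
emitted unmapped. Reads spanning the entire insertion (possible only when the
insertion is shorter than the read) are treated as right-clipped at the
junction. The simulator writes SAM as deterministic text; validity is
checked in the tests by round-tripping through pysam.

What the simulator does **not** model: empirical error and quality profiles,
indels, PCR duplicates, fragment-size distributions, capture probe geometry,
and reference mismapping. Passing tests therefore certify the detector's
logic and its statistical behavior under idealized noise, not performance on
real libraries.

## Soft-clip characterization

Given alignments (simulated or real), the characterizer:

1. clusters soft-clipped segments of length ≥ `min_clip_len` (default 5) by
   (reference position, clip side), skipping unmapped/secondary/supplementary
   records;
2. calls the breakpoint as the position with maximal summed support ≥
   `min_support` (default 3), ties toward the smaller coordinate (logged);
3. builds per-column majority consensus of the clipped segments on each side
   — right-clips anchored at their left edge (the insertion head), left-clips
   at their right edge (the insertion tail); column ties go to the
   lexicographically smallest base;
4. recovers the TSD as the longest common suffix (≤ `max_tsd_len`, default
   30) of the tail consensus and the reference upstream of the breakpoint;
5. finds the poly(A) tract in the tail consensus with the TSD removed: the
   rightmost `min_run` (default 8) window with A-fraction ≥ `purity` (default
   0.9), extended outward over consecutive A's, non-A ends trimmed.

Two ordering/extension choices deserve note. TSD-before-poly(A): an A-initial
TSD such as `AAAGAAAACAC` is continuous with the poly(A) tract, and a
homopolymer detector run first can absorb its leading A's; the common suffix
against the reference flank is the unambiguous signal, so it is taken first
and excised before the poly(A) search. Exact-A extension: extending the
poly(A) window greedily "while purity holds" crosses isolated non-A bases
(at purity 0.9 any tract of ≥ 9 A's licenses crossing one) and systematically
overshoots into A-containing flanking sequence; purity is therefore applied
only to the seed window, which still tolerates interior sequencing errors.

The poly(A)/TSD boundary is fundamentally unobservable when the host base
immediately 5' of the TSD is A, when the TSD itself starts with A, or when
the element body ends in A (as real AluY does — the packaged preset reports a
36-base tract, the 35 modelled A's plus the body's final A). The synthetic
event generator used for exact-recovery tests rejects such draws; real events
carry this ambiguity inherently and the recovered tract length should be read
with that ±1-or-so caveat. For TSDs of length ≥ `k_ref` the wildtype junction
query lies wholly inside the TSD and stops being discriminative for
genotyping; characterization is unaffected.

## Reports and batch summaries

A sample report embeds the counts (with orientation breakdown), the VAF
(printed to three decimals in TSV), the call, every parameter used, the tool
version and SHA-256 digests of the inputs, so a call is auditable and
reproducible from the report alone. Batch positivity is
`100 × positives / samples` rounded half-up to one decimal; "positive" means
detected-or-suspected by default (confirmed carriers on capture platforms
commonly sit in the suspected range), restrictable to detected-only.

## Problem sizes in the tests

The test and acceptance suites run entirely on simulated data: windows of
240–628 bases, read length 100, depths 40–400, up to 20 seeds or 50 control
replicates per property, and ~1200 random read/query pairs for the
matching-oracle equivalence. These sizes give the statistical assertions
(binomial VAF bounds, control specificity) comfortable power while keeping
the whole suite in the low seconds.

## Known limitations

* Single known event per scan; this is a targeted screen, not an MEI
  discovery tool (no discordant-pair evidence, no element-family library).
* Hamming-only approximate matching; junction indels defeat the query.
* Homozygous insertions yield VAF ≈ 1 and are called "detected", but the
  screen cannot distinguish hom-alt from het beyond the VAF itself.
* The demo preset's synthetic flanks mean demo scans say nothing about real
  genomes; build a real preset from a reference FASTA for actual screening.
* Duplicate reads and base qualities are ignored by design.
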