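"""Packaged insertion-event presets.

The ``rp1-aluy-demo`` preset models the founder AluY insertion in *RP1* exon 4
(anchored at chr8:55,540,494 on hg19): a 282-base AluY body, a 35-base poly(A)
tract and the 11-base target-site duplication AAAGAAAACAC, for a total of 328
inserted bases. Two caveats, both deliberate:

* The element body is reconstructed: its first 43 bases are the characterized
  insertion sequence; the remainder follows the AluY subfamily consensus. The
  five private divergent bases of the real allele are not modelled.
* The flanks are synthetic stand-ins (only the TSD of the real reference-side
  junction is modelled), so the demo preset is suitable for simulation and
  self-tests but NOT for scanning real sequencing data. For real use, build an
  event against a genuine reference with
  :func:`alugrep.allele_model.build_event_from_reference` (or the CLI
  ``preset-build`` subcommand), which extracts true flanks from a FASTA.
"""

from __future__ import annotations

from importlib import resources

from .allele_model import InsertionEvent, build_event

RP1_TSD = "AAAGAAAACAC"
RP1_POLYA_LEN = 35  # derived: 328 total inserted - 282 body - 11 TSD
RP1_POSITION_1BASED = 55540494  # hg19 chr8; last reference base before the gap

# Synthetic demo flanks, 150 bp each. The left flank ends with the TSD preceded
# by "TC" so the wildtype junction query cannot recur inside the mutant
# haplotype (an A-homopolymer immediately 5' of the TSD would make the wildtype
# query collide with the poly(A)+TSD tail of the insertion allele).
_DEMO_LEFT_FLANK = (
    "TGGTCGACGCACTTATTGGGACCACCGCTACCCATGCAGACGGCATGAGTCTGGGTTCCT"
    "GCGCCGTCGGTAGATGAGGCGCAGCCGCCTCGGGTATATGAGTGGGGTGTTGTTTTGGCA"
    "CGGTTGGTCTGCCTCAGTC" + RP1_TSD
)
_DEMO_RIGHT_FLANK = (
    "GGGTGTGGCCCACAGAAAGTGTAAAGATTGAATAGGAACGTGGGAATTGCTGGATAACAG"
    "CACGAGTATGCTTCGTCTACCAGAGCGGATACCGGATTACTGAATAGTGCCACACAGTTC"
    "TCTCGTAAGGCCCTTTTACCCTTACGAGGC"
)


def aluy_body() -> str:
    """The packaged 282-base AluY element body (poly(A) tail excluded)."""
    text = (
        resources.files("alugrep")
        .joinpath("data/aluy_body_consensus.fasta")
        .read_text()
    )
    return "".join(line.strip() for line in text.splitlines() if not line.startswith(">"))


def rp1_aluy_demo() -> InsertionEvent:
    """The packaged RP1-AluY demo event (synthetic flanks; see module docstring)."""
    return build_event(
        contig="chr8",
        position=RP1_POSITION_1BASED,
        left_flank=_DEMO_LEFT_FLANK,
        right_flank=_DEMO_RIGHT_FLANK,
        body=aluy_body(),
        polya_len=RP1_POLYA_LEN,
        tsd_len=len(RP1_TSD),
        label="rp1-aluy-demo",
    )


PRESETS = {
    "rp1-aluy-demo": rp1_aluy_demo,
    "rp1-aluy": rp1_aluy_demo,
}


def get_preset(name: str) -> InsertionEvent:
    """Look up a packaged preset by name."""
    try:
        factory = PRESETS[name]
    except KeyError:
        known = ", ".join(sorted(set(PRESETS)))
        raise KeyError(f"unknown preset {name!r}; available: {known}") from None
    return factory()
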