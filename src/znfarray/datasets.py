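"""Published grouped allele spectra bundled for reanalysis.

These are transcriptions of the printed per-(sub)species allele-occurrence
table for the combined *Pan* PRDM9 data set (81 sequences from 51
individuals).  One nucleotide allele is shared between the central and
eastern chimpanzee samples (p6 = E1; encoded here under the single label
``p6``), and at the amino-acid level the bonobo and eastern samples share
one allele (P1) because two nucleotide alleles differ only by synonymous
substitutions.
"""

from __future__ import annotations

from .diversity import GroupedAlleleSpectrum

EASTERN = "P. t. schweinfurthii"
CENTRAL = "P. t. troglodytes"
WESTERN = "P. t. verus"
BONOBO = "P. paniscus"

CHIMPANZEE_GROUPS = (EASTERN, CENTRAL, WESTERN)

#: Nucleotide-level allele occurrence counts per group.  Label ``p6`` in the
#: eastern group encodes the published E1 = p6 identity.
PAN_SPECTRUM_NT: dict[str, dict[str, int]] = {
    EASTERN: {"p1": 6, "p2": 1, "p3": 1, "p4": 1, "p6": 1},
    CENTRAL: {"p5": 1, "p6": 4, "p7": 1, "p8": 1},
    WESTERN: {
        "p9": 12,
        "p10": 1,
        "W2": 1,
        "W3a": 2,
        "W3b": 2,
        "W4": 1,
        "W5": 3,
        "W6": 12,
        "W7": 1,
        "W8": 2,
        "W9a": 1,
        "W9b": 1,
        "W10": 1,
        "W11a": 1,
        "W11b": 7,
        "W11c": 4,
    },
    BONOBO: {"p11": 8, "p12": 2, "B1": 2},
}

#: Amino-acid-level allele occurrence counts per group.  ``P1`` appears in
#: both the eastern and bonobo samples (synonymous nt difference between
#: p1 and p11); ``P6`` appears in both the eastern and central samples;
#: W11a and W11b merge into one aa allele.
PAN_SPECTRUM_AA: dict[str, dict[str, int]] = {
    EASTERN: {"P1": 6, "P2": 1, "P3": 1, "P4": 1, "P6": 1},
    CENTRAL: {"P5": 1, "P6": 4, "P7": 1, "P8": 1},
    WESTERN: {
        "P9": 12,
        "P10": 1,
        "W2": 1,
        "W3a": 2,
        "W3b": 2,
        "W4": 1,
        "W5": 3,
        "W6": 12,
        "W7": 1,
        "W8": 2,
        "W9a": 1,
        "W9b": 1,
        "W10": 1,
        "W11ab": 8,
        "W11c": 4,
    },
    BONOBO: {"P1": 8, "P11": 2, "B1": 2},
}

#: Published likelihood-ratio statistics for the nested codon site-model
#: comparisons on the repeat alignment: (2*delta_lnL, degrees of freedom).
PUBLISHED_LRT_STATISTICS: dict[tuple[str, str], tuple[float, int]] = {
    ("M0", "M3"): (29.61, 4),
    ("M1a", "M2a"): (13.50, 2),
    ("M7", "M8"): (14.33, 2),
}

#: Summary sizes of the compiled human comparison sets (sequences, alleles).
HUMAN_SET_SUMMARY = {
    "non-African": (446, 21),
    "African": (134, 19),
    "combined": (580, 36),
}


def pan_prdm9_spectrum(level: str = "nt") -> GroupedAlleleSpectrum:
    """The four-group *Pan* spectrum at the nt or aa level."""
    if level == "nt":
        return GroupedAlleleSpectrum.from_counts(PAN_SPECTRUM_NT)
    if level == "aa":
        return GroupedAlleleSpectrum.from_counts(PAN_SPECTRUM_AA)
    raise ValueError(f"level must be 'nt' or 'aa', got {level!r}")


def pan_species_spectrum(level: str = "nt") -> GroupedAlleleSpectrum:
    """Two-group spectrum: pooled chimpanzees (69 seqs) vs bonobos (12)."""
    return pan_prdm9_spectrum(level).pooled("chimpanzee", CHIMPANZEE_GROUPS)
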