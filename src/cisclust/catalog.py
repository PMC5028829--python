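"""Binding-sequence catalog for the six pigmentation transcription factors.

The melanocyte gene-expression network is driven by a small set of
sequence-specific transcription factors (CREB, FOXD3, LEF-1, MITF, POU3F2
and USF-1).  Their experimentally characterised binding sequences are short
(4-25 nt) and are expressed here as IUPAC degenerate consensus patterns,
e.g. the E-box ``CANNTG`` recognised by the bHLH factors MITF and USF-1.

A candidate window matches a motif when its *dissimilarity* — the fraction
of positions at which the window base falls outside the IUPAC class, times
100 — does not exceed the catalog threshold (default 15%).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "TFClass",
    "TF_COLORS",
    "IUPACMotif",
    "MotifCatalog",
    "parse_iupac",
    "expand_iupac",
    "dissimilarity",
    "reverse_complement",
    "load_paper_catalog",
    "write_catalog_tsv",
    "read_catalog_tsv",
]

#: IUPAC degenerate nucleotide alphabet -> set of concrete bases.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class TFClass(enum.Enum):
    """The six scanned pigmentation transcription factors."""

    CREB = "CREB"
    FOXD3 = "FOXD3"
    LEF1 = "LEF1"
    MITF = "MITF"
    POU3F2 = "POU3F2"
    USF1 = "USF1"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Display colour per factor (bijective; used by the module visualisation).
TF_COLORS: dict[TFClass, str] = {
    TFClass.CREB: "green",
    TFClass.FOXD3: "magenta",
    TFClass.LEF1: "orange",
    TFClass.MITF: "blue",
    TFClass.POU3F2: "red",
    TFClass.USF1: "purple",
}


class MotifError(ValueError):
    """Invalid motif pattern or catalog operation."""


def parse_iupac(pattern: str) -> str:
    """Validate and normalise an IUPAC nucleotide pattern.

    Returns the upper-cased pattern; raises :class:`MotifError` naming the
    first offending position (1-based) for any non-IUPAC character.
    """
    if not pattern:
        raise MotifError("empty pattern")
    norm = pattern.upper()
    for i, ch in enumerate(norm, start=1):
        if ch not in IUPAC_CODES:
            raise MotifError(f"invalid IUPAC code {ch!r} at position {i} in {pattern!r}")
    return norm


def degeneracy(pattern: str) -> int:
    """Product of per-position degeneracy counts of a validated pattern."""
    n = 1
    for ch in pattern:
        n *= len(IUPAC_CODES[ch])
    return n


def expand_iupac(pattern: str, cap: int = 4096) -> set[str]:
    """All concrete A/C/G/T sequences matching *pattern*.

    Refuses (with the computed cardinality in the message) when the
    expansion would exceed *cap*.
    """
    pattern = parse_iupac(pattern)
    card = degeneracy(pattern)
    if card > cap:
        raise MotifError(
            f"expansion of {pattern!r} has cardinality {card}, exceeding cap {cap}"
        )
    choices = [sorted(IUPAC_CODES[ch]) for ch in pattern]
    return {"".join(bases) for bases in product(*choices)}


def dissimilarity(pattern: str, window: str) -> float:
    """Percent of pattern positions the window base violates.

    The pattern is the reference: position *i* counts as a mismatch when
    ``window[i]`` is not a member of the IUPAC class at ``pattern[i]``.
    0.0 iff the window is a full match.  An ``N`` in the window never
    matches any pattern position (conservative: no wildcard credit).
    """
    if len(pattern) != len(window):
        raise MotifError(
            f"length mismatch: pattern {len(pattern)} vs window {len(window)}"
        )
    mismatches = sum(
        1 for p, w in zip(pattern, window) if w not in IUPAC_CODES[p] or w == "N"
    )
    return 100.0 * mismatches / len(pattern)


def reverse_complement(seq: str) -> str:
    """Reverse complement over the IUPAC alphabet (length-preserving involution)."""
    seq = seq.upper()
    for i, ch in enumerate(seq, start=1):
        if ch not in IUPAC_CODES:
            raise MotifError(f"invalid base {ch!r} at position {i}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class IUPACMotif:
    """A named binding-sequence pattern for one transcription-factor class."""

    tf_class: TFClass
    pattern: str
    source_label: str = ""
    is_paper_sourced: bool = False

    def __post_init__(self) -> None:
        norm = parse_iupac(self.pattern)
        if not 4 <= len(norm) <= 25:
            raise MotifError(
                f"pattern length {len(norm)} outside [4, 25]: {self.pattern!r}"
            )
        object.__setattr__(self, "pattern", norm)

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass
class MotifCatalog:
    """Ordered motif collection plus the matching threshold.

    ``max_dissimilarity_percent`` defaults to 15: the scan accepts a window
    when its mismatch fraction does not exceed 15% of pattern positions,
    a tolerance chosen because reptile regulatory sequence may diverge from
    the mammalian consensus the patterns were characterised in.
    """

    motifs: list[IUPACMotif] = field(default_factory=list)
    max_dissimilarity_percent: float = 15.0

    def __post_init__(self) -> None:
        if not 0 <= self.max_dissimilarity_percent <= 100:
            raise MotifError("max_dissimilarity_percent outside [0, 100]")

    def __iter__(self) -> Iterator[IUPACMotif]:
        return iter(self.motifs)

    def __len__(self) -> int:
        return len(self.motifs)

    @property
    def tf_classes(self) -> set[TFClass]:
        return {m.tf_class for m in self.motifs}

    def for_class(self, tf: TFClass) -> list[IUPACMotif]:
        return [m for m in self.motifs if m.tf_class is tf]

    def replace_class(self, tf: TFClass, motifs: Iterable[IUPACMotif]) -> "MotifCatalog":
        """Return a catalog with *tf*'s motifs swapped for user-supplied ones
        (the FOXD3 placeholder is expected to be replaced this way)."""
        new = [m for m in self.motifs if m.tf_class is not tf]
        new.extend(motifs)
        return MotifCatalog(new, self.max_dissimilarity_percent)


# Literature-compiled binding sequences, one tuple per catalog row:
# (TF class, pattern, source label, transcribed-from-literature flag).
# Bracketed alternations in the sources (e.g. [AT][AT]CAA[TA]) are written
# with the equivalent IUPAC codes (W W C A A W).
_PAPER_ROWS: list[tuple[TFClass, str, str, bool]] = [
    (TFClass.MITF, "CATGTG", "Bentley et al. 1994; Fuse et al. 1996 (M-box core)", True),
    (TFClass.MITF, "CACGTG", "Loftus et al. 2009 (E-box)", True),
    (TFClass.MITF, "CANNTG", "Murisier et al. 2006/2007 (E-box consensus)", True),
    (TFClass.MITF, "AGTCANNTGCT", "Murisier et al. 2007 (M-box)", True),
    (TFClass.MITF, "AGTCATGTGCT", "Vachtenheim & Borovansky 2010", True),
    (TFClass.MITF, "ACATGTGA", "Vachtenheim & Borovansky 2010", True),
    (TFClass.MITF, "AATCATGTGCT", "Vachtenheim & Borovansky 2010", True),
    (TFClass.MITF, "GGTCATGTGCT", "Vachtenheim & Borovansky 2010", True),
    (TFClass.MITF, "GCACATGAGT", "Vachtenheim & Borovansky 2010", True),
    (TFClass.MITF, "GCTCACATGCT", "Vachtenheim & Borovansky 2010", True),
    (TFClass.MITF, "TCACGTGTG", "Vachtenheim & Borovansky 2010", True),
    (TFClass.MITF, "TCACATGAA", "Vachtenheim & Borovansky 2010", True),
    (TFClass.MITF, "GGCACATGATG", "Vachtenheim & Borovansky 2010", True),
    (TFClass.MITF, "ACAGCTGA", "Vachtenheim & Borovansky 2010", True),
    (TFClass.MITF, "CCATATGA", "Vachtenheim & Borovansky 2010", True),
    (TFClass.USF1, "CACGTG", "Murisier et al. 2007 (core-enhancer E-box)", True),
    (TFClass.USF1, "CATGTG", "Bentley et al. 1994 (M-box core, USF)", True),
    (TFClass.CREB, "TGACGTCA", "Vance & Goding 2004 (CRE)", True),
    (TFClass.POU3F2, "ATGCAAAT", "Besch & Berking 2014 (octamer)", True),
    (TFClass.LEF1, "CTTTGAT", "Vance & Goding 2004", True),
    (TFClass.LEF1, "CTTTGGGTCATGTG", "Schwahn et al. 2005 (LEF-1 & M-box)", True),
    # FOXD3 has no literature-transcribed binding sequence in the compiled
    # table; a generic forkhead-core consensus serves as a replaceable
    # placeholder and is never flagged as literature-sourced.
    (TFClass.FOXD3, "TGTTTGT", "forkhead core consensus (placeholder)", False),
]

# SOX10 is a melanocyte factor with binding sequences in the same
# literature table but outside the six scanned classes; its patterns are
# kept here for completeness and excluded from the default catalog.
SOX10_PATTERNS: list[tuple[str, str]] = [
    ("AACAAA", "Murisier et al. 2006"),
    ("WWCAAW", "Murisier et al. 2006 ([AT][AT]CAA[TA])"),
    ("CATTGTC", "Vance & Goding 2004"),
    ("WWCAAWG", "Watanabe et al. 2002 ([AT][AT]CAA[AT]G)"),
    ("CATTGAA", "Watanabe et al. 2002 (s1)"),
    ("AACAAAA", "Watanabe et al. 2002 (s4)"),
    ("TTTTGTT", "Watanabe et al. 2002 (s3)"),
]


def load_paper_catalog(max_dissimilarity_percent: float = 15.0) -> MotifCatalog:
    """The default literature-compiled catalog covering all six TF classes."""
    motifs = [IUPACMotif(tf, pat, src, flag) for tf, pat, src, flag in _PAPER_ROWS]
    return MotifCatalog(motifs, max_dissimilarity_percent)


def write_catalog_tsv(catalog: MotifCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tf_class\tpattern\tsource_label\tis_paper_sourced\n")
        for m in catalog:
            fh.write(
                f"{m.tf_class.value}\t{m.pattern}\t{m.source_label}\t"
                f"{str(m.is_paper_sourced).lower()}\n"
            )


def read_catalog_tsv(
    path: str | Path, max_dissimilarity_percent: float = 15.0
) -> MotifCatalog:
    motifs: list[IUPACMotif] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            try:
                motifs.append(
                    IUPACMotif(
                        TFClass(cols[idx["tf_class"]]),
                        cols[idx["pattern"]],
                        cols[idx["source_label"]],
                        cols[idx["is_paper_sourced"]].lower() == "true",
                    )
                )
            except (KeyError, IndexError, ValueError) as exc:
                raise MotifError(f"{path}: malformed catalog row at line {lineno}: {exc}")
    return MotifCatalog(motifs, max_dissimilarity_percent)
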