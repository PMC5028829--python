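"""Both-strand motif scanning of promoter-proximal upstream regions.

Each upstream region is the 1500 bases immediately 5' of a gene's
transcription start site; position 1 is the most distal base and position
``length`` abuts the TSS.  Every window of every catalog pattern length is
scored on both strands with the IUPAC mismatch-fraction dissimilarity and
kept when it does not exceed the catalog threshold.  Coordinates are
1-based inclusive on the forward strand.

Because a transcription factor is typically represented by several
near-redundant patterns, raw hits are *collapsed*: overlapping hits of the
same TF class are reduced to a single class-level binding-site record.
Overlapping hits of *different* classes are never merged — a shared E-box
legitimately reports both MITF and USF-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .catalog import MotifCatalog, TFClass, reverse_complement, IUPAC_CODES

__all__ = [
    "UpstreamRegion",
    "BindingSiteHit",
    "scan_region",
    "collapse_hits",
    "write_hit_table",
    "read_hit_table",
    "read_regions_fasta",
    "HIT_COLUMNS",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

HIT_COLUMNS = [
    "region_id",
    "tf_class",
    "start",
    "end",
    "strand",
    "matched_seq",
    "dissimilarity_percent",
    "pattern",
]


class ScanError(ValueError):
    pass


@dataclass(frozen=True)
class UpstreamRegion:
    """One gene's upstream search space."""

    region_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ScanError(f"{self.region_id}: empty sequence")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ScanError(f"{self.region_id}: invalid bases {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class BindingSiteHit:
    """One scored motif match, on forward-strand coordinates."""

    region_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    tf_class: TFClass = field(compare=False)
    strand: str = field(compare=False)
    matched_seq: str = field(compare=False)
    dissimilarity_percent: float = field(compare=False)
    pattern: str = field(compare=False)

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ScanError(f"invalid span [{self.start}, {self.end}]")
        if self.end - self.start + 1 != len(self.pattern):
            raise ScanError("span length does not equal pattern length")
        if self.strand not in "+-":
            raise ScanError(f"invalid strand {self.strand!r}")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def overlaps(self, other: "BindingSiteHit") -> bool:
        return self.start <= other.end and other.start <= self.end


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX[b] for b in seq), dtype=np.int8, count=len(seq))


def _mismatch_counts(codes: np.ndarray, pattern: str) -> np.ndarray:
    """Mismatch count of *pattern* against every window of the coded sequence."""
    m = len(pattern)
    n_win = len(codes) - m + 1
    mism = np.zeros(n_win, dtype=np.int16)
    for j, ch in enumerate(pattern):
        allowed = np.zeros(5, dtype=bool)
        for base in IUPAC_CODES[ch]:
            allowed[_BASE_INDEX[base]] = True
        allowed[4] = False  # N in the sequence never matches
        mism += ~allowed[codes[j : j + n_win]]
    return mism


def scan_region(region: UpstreamRegion, catalog: MotifCatalog) -> list[BindingSiteHit]:
    """All catalog matches in *region* at or under the dissimilarity threshold.

    Both strands are scanned; a span where the same pattern matches on both
    strands (palindromes and near-palindromes) is reported once with strand
    ``+`` so that cluster counts are not doubled.  Hits are sorted by
    (start, end, tf_class).
    """
    codes = _encode(region.sequence)
    thr = catalog.max_dissimilarity_percent
    hits: list[BindingSiteHit] = []
    for motif in catalog:
        m = len(motif)
        if m > region.length:
            continue
        fwd = _mismatch_counts(codes, motif.pattern)
        rev = _mismatch_counts(codes, reverse_complement(motif.pattern))
        fwd_pct = 100.0 * fwd / m
        rev_pct = 100.0 * rev / m
        for s in np.nonzero((fwd_pct <= thr) | (rev_pct <= thr))[0]:
            fp, rp = fwd_pct[s], rev_pct[s]
            strand = "+" if fp <= thr else "-"
            pct = fp if fp <= thr else rp
            hits.append(
                BindingSiteHit(
                    region_id=region.region_id,
                    start=int(s) + 1,
                    end=int(s) + m,
                    tf_class=motif.tf_class,
                    strand=strand,
                    matched_seq=region.sequence[s : s + m],
                    dissimilarity_percent=float(pct),
                    pattern=motif.pattern,
                )
            )
    hits.sort(key=lambda h: (h.start, h.end, h.tf_class.value, h.pattern))
    return hits


def collapse_hits(hits: Sequence[BindingSiteHit]) -> list[BindingSiteHit]:
    """Reduce same-class overlapping hits to one class-level record each.

    Within each TF class, hits are chained into connected components by
    span overlap; each component keeps its best hit (lowest dissimilarity,
    then leftmost, then longest).  Hits of different classes are never
    merged.  Idempotent.
    """
    if not hits:
        return []
    region_ids = {h.region_id for h in hits}
    if len(region_ids) > 1:
        raise ScanError(f"hits from multiple regions: {sorted(region_ids)}")
    kept: list[BindingSiteHit] = []
    for tf in TFClass:
        group = sorted(
            (h for h in hits if h.tf_class is tf), key=lambda h: (h.start, h.end)
        )
        component: list[BindingSiteHit] = []
        comp_end = -1
        for h in group:
            if component and h.start > comp_end:
                kept.append(_best_of(component))
                component = []
                comp_end = -1
            component.append(h)
            comp_end = max(comp_end, h.end)
        if component:
            kept.append(_best_of(component))
    kept.sort(key=lambda h: (h.start, h.end, h.tf_class.value))
    return kept


def _best_of(component: list[BindingSiteHit]) -> BindingSiteHit:
    return min(
        component,
        key=lambda h: (h.dissimilarity_percent, h.start, -(h.end - h.start + 1)),
    )


def write_hit_table(hits: Iterable[BindingSiteHit], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (
                h.region_id,
                h.tf_class.value,
                h.start,
                h.end,
                h.strand,
                h.matched_seq,
                h.dissimilarity_percent,
                h.pattern,
            )
            for h in hits
        ],
        columns=HIT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_hit_table(path: str | Path) -> list[BindingSiteHit]:
    """Parse a hit table, validating each row (extra trailing columns ignored)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ScanError(f"{path}: missing columns {missing}")
    hits = []
    for idx, row in df.iterrows():
        lineno = idx + 2  # header is line 1
        try:
            hits.append(
                BindingSiteHit(
                    region_id=row["region_id"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    tf_class=TFClass(row["tf_class"]),
                    strand=row["strand"],
                    matched_seq=row["matched_seq"],
                    dissimilarity_percent=float(row["dissimilarity_percent"]),
                    pattern=row["pattern"],
                )
            )
        except (ValueError, ScanError) as exc:
            raise ScanError(f"{path}: malformed hit at line {lineno}: {exc}")
    return hits


def read_regions_fasta(path: str | Path) -> list[UpstreamRegion]:
    regions = [
        UpstreamRegion(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not regions:
        raise ScanError(f"{path}: no FASTA records")
    return regions
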