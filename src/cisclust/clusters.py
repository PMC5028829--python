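"""Greedy detection of candidate enhancer modules.

A candidate enhancer module is a compact interval (search window 200 nt)
of an upstream region enriched for binding sites of at least two distinct
transcription factors — the combinatorial-control signature of a
cis-regulatory module.  Detection is greedy: the window holding the most
(collapsed) binding sites is selected first, its hits are removed, and the
search repeats until three modules are found or no window qualifies.
Reported intervals are trimmed to the minimal span covering their member
hits, so printed module widths vary even though the search window is fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .catalog import TFClass
from .scanner import BindingSiteHit

__all__ = [
    "ClusterConfig",
    "EnhancerModule",
    "best_window",
    "find_modules",
    "summarize_modules",
    "StudySummary",
    "write_modules_bed",
    "write_modules_tsv",
]


@dataclass(frozen=True)
class ClusterConfig:
    """Parameters of the module search.

    window_length: fixed sliding-window length in nucleotides.
    clusters_per_region: how many modules to report per region (top-k).
    min_distinct_tfs: distinct TF classes a window must span to qualify.
    trim_to_span: report the minimal interval covering member hits rather
        than the raw search window.
    """

    window_length: int = 200
    clusters_per_region: int = 3
    min_distinct_tfs: int = 2
    trim_to_span: bool = True

    def __post_init__(self) -> None:
        if self.window_length < 1 or self.clusters_per_region < 1:
            raise ValueError("window_length and clusters_per_region must be >= 1")
        if self.min_distinct_tfs < 1:
            raise ValueError("min_distinct_tfs must be >= 1")


@dataclass(frozen=True)
class EnhancerModule:
    """A detected cluster of binding sites within one upstream region."""

    region_id: str
    start: int
    end: int
    member_hits: tuple[BindingSiteHit, ...]
    rank: int

    def __post_init__(self) -> None:
        for h in self.member_hits:
            if not (self.start <= h.start and h.end <= self.end):
                raise ValueError(
                    f"member hit [{h.start},{h.end}] outside module "
                    f"[{self.start},{self.end}]"
                )

    @property
    def n_sites(self) -> int:
        return len(self.member_hits)

    @property
    def distinct_tfs(self) -> frozenset[TFClass]:
        return frozenset(h.tf_class for h in self.member_hits)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def _overlaps_any(hit: BindingSiteHit, intervals: Iterable[tuple[int, int]]) -> bool:
    return any(hit.start <= e and s <= hit.end for s, e in intervals)


def best_window(
    hits: Sequence[BindingSiteHit],
    window_length: int,
    excluded: Iterable[tuple[int, int]] = (),
    min_distinct_tfs: int = 2,
    region_length: int | None = None,
) -> tuple[tuple[int, int], list[BindingSiteHit]] | None:
    """Leftmost maximal-count qualifying window, or None.

    A hit is a member of window [s, s+L-1] iff its full span is contained
    in the window.  Hits overlapping an already-excluded interval are
    ineligible (this is what keeps reported modules non-overlapping after
    trimming).  A window qualifies when its members span at least
    ``min_distinct_tfs`` distinct TF classes; among qualifying windows the
    one with the most members wins, ties broken to the leftmost (most
    distal) offset.
    """
    excluded = list(excluded)
    pool = [h for h in hits if not _overlaps_any(h, excluded)]
    if not pool:
        return None
    pool.sort(key=lambda h: (h.start, h.end))
    if region_length is None:
        region_length = max(h.end for h in pool)
    last_start = max(1, region_length - window_length + 1)

    best: tuple[int, int] | None = None  # (count, -start) comparison
    best_members: list[BindingSiteHit] = []
    for s in range(1, last_start + 1):
        e = s + window_length - 1
        members = [h for h in pool if h.start >= s and h.end <= e]
        if not members:
            continue
        tfs = {h.tf_class for h in members}
        if len(tfs) < min_distinct_tfs:
            continue
        if best is None or len(members) > len(best_members):
            best = (s, e)
            best_members = members
    if best is None:
        return None
    return best, best_members


def find_modules(
    hits: Sequence[BindingSiteHit],
    config: ClusterConfig = ClusterConfig(),
    region_length: int | None = None,
) -> list[EnhancerModule]:
    """Greedy top-k module detection on the collapsed hits of one region."""
    if not hits:
        return []
    region_ids = {h.region_id for h in hits}
    if len(region_ids) > 1:
        raise ValueError(f"hits from multiple regions: {sorted(region_ids)}")
    region_id = region_ids.pop()

    modules: list[EnhancerModule] = []
    excluded: list[tuple[int, int]] = []
    for rank in range(1, config.clusters_per_region + 1):
        found = best_window(
            hits,
            config.window_length,
            excluded,
            config.min_distinct_tfs,
            region_length,
        )
        if found is None:
            break
        (ws, we), members = found
        if config.trim_to_span:
            ws = min(h.start for h in members)
            we = max(h.end for h in members)
        members = tuple(sorted(members, key=lambda h: (h.start, h.end, h.tf_class.value)))
        modules.append(EnhancerModule(region_id, ws, we, members, rank))
        excluded.append((ws, we))
    return modules


@dataclass
class StudySummary:
    """Totals over all regions of a study."""

    total_modules: int
    per_region_counts: dict[str, int]
    rosters: dict[str, list[frozenset[TFClass]]]  # region -> roster per module, by rank

    def region_tf_union(self, region_id: str) -> frozenset[TFClass]:
        rosters = self.rosters.get(region_id, [])
        out: frozenset[TFClass] = frozenset()
        for r in rosters:
            out |= r
        return out


def summarize_modules(
    modules_per_region: dict[str, Sequence[EnhancerModule]],
) -> StudySummary:
    counts = {rid: len(mods) for rid, mods in modules_per_region.items()}
    rosters = {
        rid: [m.distinct_tfs for m in sorted(mods, key=lambda m: m.rank)]
        for rid, mods in modules_per_region.items()
    }
    return StudySummary(sum(counts.values()), counts, rosters)


def write_modules_bed(modules: Iterable[EnhancerModule], path: str | Path) -> None:
    """BED export: 0-based half-open, name = region_id.rank, roster column."""
    with open(path, "w") as fh:
        for m in modules:
            roster = ",".join(sorted(tf.value for tf in m.distinct_tfs))
            fh.write(f"{m.region_id}\t{m.start - 1}\t{m.end}\t{m.region_id}.{m.rank}\t{roster}\n")


def write_modules_tsv(modules: Iterable[EnhancerModule], path: str | Path) -> None:
    """Human-readable module table (region, rank, interval, site count, roster)."""
    with open(path, "w") as fh:
        fh.write("region_id\trank\tstart\tend\tn_sites\tdistinct_tfs\ttf_roster\n")
        for m in modules:
            roster = ",".join(sorted(tf.value for tf in m.distinct_tfs))
            fh.write(
                f"{m.region_id}\t{m.rank}\t{m.start}\t{m.end}\t{m.n_sites}\t"
                f"{len(m.distinct_tfs)}\t{roster}\n"
            )
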