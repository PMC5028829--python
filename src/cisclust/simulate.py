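"""Synthetic upstream regions with planted binding-site clusters.

The generator emulates the statistical structure the pipeline assumes:
1500-nt upstream regions of i.i.d. background sequence carrying three
well-separated ~200-nt windows, each planted with sites for at least two
distinct transcription factors, plus isolated single-factor decoy sites
between the windows.  Background is rejection-resampled until no catalog
match at or under the dissimilarity threshold survives outside the planted
footprints, which makes scanner-output == recorded-truth an invariant
rather than a probability.  Protein families at a controlled substitution
rate (no indels) support identity-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .catalog import (
    MotifCatalog,
    TFClass,
    expand_iupac,
    load_paper_catalog,
)
from .scanner import BindingSiteHit, UpstreamRegion, scan_region, write_hit_table

__all__ = [
    "PlantedSite",
    "PlantedWindow",
    "PlantSpec",
    "SyntheticStudy",
    "generate_region",
    "generate_study",
    "generate_families",
    "mutate_protein",
    "write_study",
    "DEFAULT_REGION_IDS",
    "PLANT_PATTERNS",
    "DECOY_PATTERNS",
]

#: The nine pigmentation target genes whose upstream regions are scanned.
DEFAULT_REGION_IDS = ["AIM1", "DCT", "MC1R", "MITF", "MLANA", "OA1", "PMEL", "RAB27A", "TYR"]

#: One representative plantable pattern per TF class.  MITF/USF-1 share the
#: E-box family, so planting either legitimately induces hits for both.
PLANT_PATTERNS: dict[TFClass, str] = {
    TFClass.CREB: "TGACGTCA",
    TFClass.POU3F2: "ATGCAAAT",
    TFClass.LEF1: "CTTTGAT",
    TFClass.FOXD3: "TGTTTGT",
    TFClass.MITF: "CATGTG",
    TFClass.USF1: "CACGTG",
}

#: Decoy patterns are cross-class-unambiguous so an isolated decoy never
#: spans two distinct TF classes (it must exercise the >=2-distinct-TFs
#: rejection path, not defeat it).
DECOY_PATTERNS: dict[TFClass, str] = {
    TFClass.CREB: "TGACGTCA",
    TFClass.POU3F2: "ATGCAAAT",
    TFClass.LEF1: "CTTTGAT",
}

_BASES = np.array(list("ACGT"))
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class PlantedSite:
    tf_class: TFClass
    pattern: str
    offset: int  # 0-based offset within the window


@dataclass(frozen=True)
class PlantedWindow:
    start: int  # 1-based inclusive, in region coordinates
    end: int
    sites: tuple[PlantedSite, ...]

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DecoySite:
    tf_class: TFClass
    pattern: str
    position: int  # 1-based region coordinate of the site start


@dataclass
class PlantSpec:
    """Full recipe for one synthetic upstream region."""

    region_id: str
    seed: int
    region_length: int = 1500
    background_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    planted_windows: tuple[PlantedWindow, ...] = ()
    decoy_sites: tuple[DecoySite, ...] = ()

    def __post_init__(self) -> None:
        if abs(sum(self.background_freqs) - 1.0) > 1e-9:
            raise SimulationError("background_freqs must sum to 1")
        wins = sorted(self.planted_windows, key=lambda w: w.start)
        for w in wins:
            if not 1 <= w.start <= w.end <= self.region_length:
                raise SimulationError(f"window [{w.start},{w.end}] outside region")
            if len({s.tf_class for s in w.sites}) < 2:
                raise SimulationError("each planted window needs >= 2 distinct TF classes")
            for s in w.sites:
                if s.offset < 0 or w.start + s.offset + len(s.pattern) - 1 > w.end:
                    raise SimulationError(
                        f"site {s.pattern} at offset {s.offset} overflows window"
                    )
        for a, b in zip(wins, wins[1:]):
            gap = b.start - a.end - 1
            if gap <= max(a.length, b.length):
                raise SimulationError(
                    f"windows [{a.start},{a.end}] and [{b.start},{b.end}] separated "
                    f"by {gap} <= window length"
                )
        for d in self.decoy_sites:
            d_end = d.position + len(d.pattern) - 1
            if not 1 <= d.position <= d_end <= self.region_length:
                raise SimulationError("decoy outside region")
            for w in wins:
                if d.position <= w.end and w.start <= d_end:
                    raise SimulationError("decoy overlaps a planted window")


def _footprints(spec: PlantSpec) -> list[tuple[int, int, str, TFClass]]:
    """(start, end, pattern, tf) of every planted/decoy site, 1-based inclusive."""
    out = []
    for w in spec.planted_windows:
        for s in w.sites:
            a = w.start + s.offset
            out.append((a, a + len(s.pattern) - 1, s.pattern, s.tf_class))
    for d in spec.decoy_sites:
        out.append((d.position, d.position + len(d.pattern) - 1, d.pattern, d.tf_class))
    return sorted(out)


def generate_region(
    spec: PlantSpec,
    catalog: MotifCatalog | None = None,
    max_attempts: int = 20,
    max_rounds: int = 200,
) -> tuple[UpstreamRegion, list[BindingSiteHit]]:
    """Draw one region; returns (region, truth hits).

    Truth is the complete catalog annotation of the planted material: every
    scan hit fully contained in a planted/decoy footprint (a planted E-box
    truthfully carries both its MITF and USF-1 identity).  The rejection
    step redraws background under any hit extending outside the footprints,
    so ``scan_region`` on the output equals truth exactly.
    """
    if catalog is None:
        catalog = load_paper_catalog()
    rng = np.random.default_rng(spec.seed)
    prints = _footprints(spec)
    freqs = np.asarray(spec.background_freqs, dtype=float)

    for _ in range(max_attempts):
        seq = rng.choice(_BASES, size=spec.region_length, p=freqs)
        is_planted = np.zeros(spec.region_length, dtype=bool)
        for a, b, pattern, _tf in prints:
            concrete = sorted(expand_iupac(pattern))
            chosen = concrete[int(rng.integers(len(concrete)))]
            seq[a - 1 : b] = list(chosen)
            is_planted[a - 1 : b] = True

        ok = False
        for _round in range(max_rounds):
            region = UpstreamRegion(spec.region_id, "".join(seq))
            hits = scan_region(region, catalog)
            violating = [h for h in hits if not _contained(h, prints)]
            if not violating:
                ok = True
                break
            redraw = np.zeros(spec.region_length, dtype=bool)
            for h in violating:
                redraw[h.start - 1 : h.end] = True
            redraw &= ~is_planted
            if not redraw.any():
                break  # cannot fix without disturbing planted sites; re-attempt
            n = int(redraw.sum())
            seq[redraw] = rng.choice(_BASES, size=n, p=freqs)
        if ok:
            truth = [h for h in hits if _contained(h, prints)]
            return region, truth
    raise SimulationError(
        f"{spec.region_id}: could not reconcile spec after {max_attempts} attempts"
    )


def _contained(hit: BindingSiteHit, prints: Sequence[tuple[int, int, str, TFClass]]) -> bool:
    return any(hit.start >= a and hit.end <= b for a, b, _p, _tf in prints)


@dataclass
class SyntheticStudy:
    """Regions plus ground truth, and optional protein families."""

    regions: list[tuple[UpstreamRegion, list[BindingSiteHit]]]
    specs: list[PlantSpec]
    protein_families: dict[str, dict[str, str]]
    substitution_rates: dict[str, float]
    seed: int

    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r, _ in self.regions]


def _window_anchors(
    region_length: int, k: int, window_length: int
) -> list[tuple[int, int]]:
    """k windows of fixed length, evenly spaced with gaps > window_length."""
    min_gap = window_length + 1
    needed = k * window_length + (k - 1) * min_gap
    if needed > region_length:
        raise SimulationError(
            f"cannot pack {k} windows of {window_length} nt with separation "
            f"> {window_length} into {region_length} nt"
        )
    if k == 1:
        return [(1, window_length)]
    gap = (region_length - k * window_length) // (k - 1)
    anchors = []
    pos = 1
    for _ in range(k):
        anchors.append((pos, pos + window_length - 1))
        pos += window_length + gap
    return anchors


def _spread_offsets(
    rng: np.random.Generator, n: int, window_length: int, site_lens: list[int]
) -> list[int]:
    """Offsets spreading n sites across the window (first near the left edge,
    last ending near the right edge) with a little jitter and no collisions."""
    max_len = max(site_lens)
    span = window_length - max_len
    if n == 1:
        return [int(rng.integers(0, span + 1))]
    targets = [round(j * span / (n - 1)) for j in range(n)]
    offsets = []
    for j, t in enumerate(targets):
        jit = int(rng.integers(-3, 4)) if 0 < j < n - 1 else int(rng.integers(0, 4)) * (1 if j == 0 else -1)
        offsets.append(int(np.clip(t + jit, 0, span)))
    # enforce >= 3 nt gaps between consecutive sites (no straddling matches)
    for j in range(1, n):
        lo = offsets[j - 1] + site_lens[j - 1] + 3
        if offsets[j] < lo:
            offsets[j] = lo
    if offsets[-1] > span:
        raise SimulationError("sites do not fit in window")
    return offsets


def generate_study(
    n_regions: int = 9,
    clusters_per_region: int = 3,
    sites_per_cluster_range: tuple[int, int] = (2, 5),
    seed: int = 42,
    region_length: int = 1500,
    window_length: int = 200,
    decoys_per_region: int = 2,
    with_proteins: bool = True,
    catalog: MotifCatalog | None = None,
) -> SyntheticStudy:
    """Default study: nine 1500-nt regions x three qualifying planted clusters.

    Each cluster carries 2-5 sites for *distinct* TF classes spread across
    its 200-nt window; two single-factor decoys sit centred in the
    inter-window gaps, far enough from the windows that no 200-nt interval
    can contain a decoy together with a planted site.
    """
    lo, hi = sites_per_cluster_range
    if not 2 <= lo <= hi <= len(TFClass):
        raise SimulationError("sites_per_cluster_range must satisfy 2 <= lo <= hi <= 6")
    master = np.random.default_rng(seed)
    region_ids = (DEFAULT_REGION_IDS + [f"SYN{i}" for i in range(10, 10 + max(0, n_regions - 9))])[:n_regions]
    anchors = _window_anchors(region_length, clusters_per_region, window_length) if n_regions else []

    regions: list[tuple[UpstreamRegion, list[BindingSiteHit]]] = []
    specs: list[PlantSpec] = []
    classes = list(TFClass)
    decoy_classes = list(DECOY_PATTERNS)
    for rid in region_ids:
        sub_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        windows = []
        for ws, we in anchors:
            n_sites = int(rng.integers(lo, hi + 1))
            tfs = [classes[i] for i in rng.choice(len(classes), size=n_sites, replace=False)]
            lens = [len(PLANT_PATTERNS[tf]) for tf in tfs]
            offsets = _spread_offsets(rng, n_sites, window_length, lens)
            sites = tuple(
                PlantedSite(tf, PLANT_PATTERNS[tf], off) for tf, off in zip(tfs, offsets)
            )
            windows.append(PlantedWindow(ws, we, sites))
        decoys = []
        for g in range(min(decoys_per_region, len(anchors) - 1)):
            gap_lo, gap_hi = anchors[g][1], anchors[g + 1][0]
            tf = decoy_classes[int(rng.integers(len(decoy_classes)))]
            pat = DECOY_PATTERNS[tf]
            centre = (gap_lo + gap_hi) // 2
            decoys.append(DecoySite(tf, pat, centre - len(pat) // 2))
        spec = PlantSpec(
            region_id=rid,
            seed=sub_seed,
            region_length=region_length,
            planted_windows=tuple(windows),
            decoy_sites=tuple(decoys),
        )
        region, truth = generate_region(spec, catalog=catalog)
        regions.append((region, truth))
        specs.append(spec)

    families: dict[str, dict[str, str]] = {}
    rates: dict[str, float] = {}
    if with_proteins:
        rates = {"hum": 0.30, "mouse": 0.30, "chick": 0.25, "anole": 0.15, "Tham_sirt": 0.08}
        families = generate_families(
            ["TYR", "MITF", "RAB27A"], rates, length=300,
            seed=int(master.integers(0, 2**31 - 1)),
        )
    return SyntheticStudy(regions, specs, families, rates, seed)


def mutate_protein(seq: str, substitution_rate: float, seed: int | np.random.Generator) -> str:
    """Independently substitute each residue with the given probability.

    A substituted residue is drawn uniformly from the 19 *other* standard
    amino acids; no indels are introduced.
    """
    if not 0 <= substitution_rate <= 1:
        raise SimulationError("substitution_rate must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = list(seq)
    flips = rng.random(len(out)) < substitution_rate
    for i in np.nonzero(flips)[0]:
        choices = _AA20.replace(out[i], "") if out[i] in _AA20 else _AA20
        out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def generate_families(
    genes: Sequence[str],
    substitution_rates: dict[str, float],
    length: int = 300,
    seed: int = 0,
    reference_species: str = "pyth",
) -> dict[str, dict[str, str]]:
    """Per-gene ortholog families: a random reference protein per gene plus
    one diverged copy per species at that species' substitution rate."""
    rng = np.random.default_rng(seed)
    families: dict[str, dict[str, str]] = {}
    for gene in genes:
        ref = "".join(_AA20[i] for i in rng.integers(0, len(_AA20), size=length))
        fam = {reference_species: ref}
        for sp, rate in substitution_rates.items():
            fam[sp] = mutate_protein(ref, rate, rng)
        families[gene] = fam
    return families


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Emit regions FASTA, truth hit table, protein FASTA and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "regions.fasta", "w") as fh:
        for region, _truth in study.regions:
            fh.write(f">{region.region_id}\n")
            for i in range(0, region.length, 70):
                fh.write(region.sequence[i : i + 70] + "\n")
    all_truth = [h for _r, truth in study.regions for h in truth]
    write_hit_table(all_truth, outdir / "truth_hits.tsv")
    if study.protein_families:
        with open(outdir / "proteins.fasta", "w") as fh:
            for gene, fam in study.protein_families.items():
                for sp, seq in fam.items():
                    fh.write(f">{gene}|{sp}\n{seq}\n")
    manifest = {
        "seed": study.seed,
        "n_regions": len(study.regions),
        "substitution_rates": study.substitution_rates,
        "regions": [
            {
                "region_id": spec.region_id,
                "seed": spec.seed,
                "region_length": spec.region_length,
                "background_freqs": list(spec.background_freqs),
                "planted_windows": [
                    {
                        "start": w.start,
                        "end": w.end,
                        "sites": [
                            {"tf": s.tf_class.value, "pattern": s.pattern, "offset": s.offset}
                            for s in w.sites
                        ],
                    }
                    for w in spec.planted_windows
                ],
                "decoy_sites": [
                    {"tf": d.tf_class.value, "pattern": d.pattern, "position": d.position}
                    for d in spec.decoy_sites
                ],
            }
            for spec in study.specs
        ],
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
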