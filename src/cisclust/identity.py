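"""Pairwise ortholog percent identity and the gene x species-pair matrix.

Percent identity — identical columns over aligned columns, x100 — between
a reference species' protein and each ortholog summarises how conserved a
coat-color gene is across vertebrates.  The packaged fixture is a
23-gene x 8-species-pair matrix (python vs human, mouse, dog, horse, cow,
chicken, anole lizard and garter snake); two garter-snake orthologs
(RAB38, SLC24A5) were never sequenced and are carried as missing, not 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "PairwiseAlignmentResult",
    "IdentityMatrix",
    "align_identity",
    "build_matrix",
    "range_summary",
    "export_heatmap_table",
    "load_table1",
    "load_domain_annotations",
    "load_pleiotropy_annotations",
    "read_families_fasta",
    "STATED_RANGES",
    "flag_range_discrepancies",
]

_AA = set("ACDEFGHIKLMNPQRSTVWYX")


class IdentityError(ValueError):
    pass


@dataclass(frozen=True)
class PairwiseAlignmentResult:
    identity_percent: float
    aligned_columns: int
    matches: int
    gaps: int


@dataclass
class IdentityMatrix:
    """Gene x species-pair percent identities with a missing-entry mask."""

    values: pd.DataFrame  # float percent, NaN where missing
    reference_species: str = "pyth"

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def species_pairs(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())


def _make_aligner(mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def align_identity(a: str, b: str, mode: str = "global") -> PairwiseAlignmentResult:
    """Percent identity of the optimal pairwise alignment of two proteins.

    BLOSUM62 scoring with affine gaps (open 11, extend 1).  In local mode
    identity is computed over the locally aligned segment only (terminal
    gap columns never enter the count); in global mode every column counts.
    """
    if mode not in ("global", "local"):
        raise IdentityError(f"unknown mode {mode!r}")
    for name, seq in (("first", a), ("second", b)):
        if not seq:
            raise IdentityError(f"{name} sequence is empty")
        bad = set(seq.upper()) - _AA
        if bad:
            raise IdentityError(f"invalid residues {sorted(bad)} in {name} sequence")
    alignment = _make_aligner(mode).align(a.upper(), b.upper())[0]
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return PairwiseAlignmentResult(
        identity_percent=100.0 * counts.identities / columns,
        aligned_columns=columns,
        matches=counts.identities,
        gaps=counts.gaps,
    )


def build_matrix(
    families: Mapping[str, Mapping[str, str]],
    reference_species: str,
    mode: str = "global",
) -> IdentityMatrix:
    """Assemble the gene x species-pair matrix from per-gene ortholog families.

    *families* maps gene -> {species: protein sequence}; the reference
    species must be present in every family.  Cells for species absent
    from a family are marked missing.
    """
    others: list[str] = []
    for gene, fam in families.items():
        if reference_species not in fam:
            raise IdentityError(f"family {gene!r} lacks reference {reference_species!r}")
        for sp in fam:
            if sp != reference_species and sp not in others:
                others.append(sp)
    cols = [f"{reference_species}2{sp}" for sp in others]
    values = pd.DataFrame(np.nan, index=list(families), columns=cols, dtype=float)
    for gene, fam in families.items():
        ref_seq = fam[reference_species]
        for sp in others:
            if sp in fam:
                res = align_identity(ref_seq, fam[sp], mode=mode)
                values.loc[gene, f"{reference_species}2{sp}"] = res.identity_percent
    return IdentityMatrix(values, reference_species)


def range_summary(matrix: IdentityMatrix, gene: str) -> tuple[float, float]:
    """(min, max) percent identity over the gene's non-missing cells."""
    if gene not in matrix.values.index:
        raise IdentityError(f"unknown gene {gene!r}")
    row = matrix.values.loc[gene].dropna()
    if row.empty:
        raise IdentityError(f"gene {gene!r} has no non-missing cells")
    return float(row.min()), float(row.max())


def export_heatmap_table(
    matrix: IdentityMatrix,
    annotations: Mapping[str, str],
    path: str | Path,
) -> None:
    """Tab-delimited heat-map input: row labels "GENE (annotation)", NA for missing."""
    missing_ann = [g for g in matrix.genes if g not in annotations]
    if missing_ann:
        raise IdentityError(f"no annotation for genes {missing_ann}")
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(matrix.species_pairs) + "\n")
        for gene in matrix.genes:
            ann = annotations[gene].strip()
            label = f"{gene} ({ann})" if ann else gene
            cells = []
            for col in matrix.species_pairs:
                v = matrix.values.loc[gene, col]
                cells.append("NA" if pd.isna(v) else f"{v:g}")
            fh.write(label + "\t" + "\t".join(cells) + "\n")


def _data_path(name: str):
    return resources.files("cisclust.data").joinpath(name)


def load_table1() -> IdentityMatrix:
    """The packaged 23 x 8 coat-color identity matrix.

    The two absent garter-snake orthologs are printed as 0 in the source
    table; 0% identity is semantically impossible for a real ortholog pair,
    so zero cells are loaded as missing.
    """
    with resources.as_file(_data_path("table1_identity.tsv")) as p:
        df = pd.read_csv(p, sep="\t", index_col="gene").astype(float)
    df = df.mask(df == 0)
    return IdentityMatrix(df, "pyth")


def load_domain_annotations() -> pd.DataFrame:
    """Static protein-domain annotation table for the six transcription factors."""
    with resources.as_file(_data_path("table3_domains.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_pleiotropy_annotations() -> dict[str, str]:
    """Synthetic per-gene pleiotropy tags (heat-map label formatting only)."""
    with resources.as_file(_data_path("pleiotropy_annotations_synthetic.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#", keep_default_na=False)
    return dict(zip(df["gene"], df["annotation"]))


#: Ranges as stated in the narrative summary of the identity analysis.
#: Those inconsistent with the printed matrix are flagged, not asserted.
STATED_RANGES: dict[str, tuple[float, float]] = {
    "PAX3": (96, 99),
    "RAB27A": (90, 95),
    "MYO5A": (89, 92),
    "OCA2": (83, 93),
    "ASIP": (46, 86),
    "KITLG": (40, 85),
    "EDN3": (42, 78),
    "PMEL": (39, 77),
    "TYR": (71, 87),
    "SLC2A9": (71, 87),
}


def flag_range_discrepancies(matrix: IdentityMatrix) -> dict[str, dict]:
    """Compare computed per-gene ranges against the narrative-stated ones.

    Returns, for every gene with a stated range, the computed range, the
    stated range and whether they agree; disagreements are reported rather
    than silently reconciled.
    """
    report = {}
    for gene, stated in STATED_RANGES.items():
        computed = range_summary(matrix, gene)
        report[gene] = {
            "computed": computed,
            "stated": (float(stated[0]), float(stated[1])),
            "consistent": computed == (float(stated[0]), float(stated[1])),
        }
    return report


def read_families_fasta(path: str | Path) -> dict[str, dict[str, str]]:
    """Protein FASTA with ``gene|species`` record ids -> nested mapping."""
    families: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise IdentityError(f"record id {rec.id!r} is not gene|species")
        gene, species = rec.id.split("|", 1)
        families.setdefault(gene, {})[species] = str(rec.seq)
    if not families:
        raise IdentityError(f"{path}: no FASTA records")
    return families
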