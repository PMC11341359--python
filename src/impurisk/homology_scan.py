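"""Cross-conservation of predicted epitopes with a reference proteome.

A class II 9-mer ligand shows the T-cell receptor positions 2, 3, 5, 7 and 8
while positions 1, 4, 6 and 9 anchor the HLA groove.  An epitope in a drug
peptide that shares its TCR-facing residues with many 9-mers of the host
(human) proteome that bind the same allele is more likely to be tolerated —
the responding T-cell repertoire has been shaped by the self-peptides.  The
homology score of a peptide is the average number of such proteome matches
("depth of cross-conservation") over its hit cells; scores above 2.0 flag
elevated tolerance potential.  Combined with the epitope-density aggregate
score this places a peptide in one of four risk quadrants.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .epitope_scan import FrameHitTable, FrameScore, ScoringMatrixSet, Z_HIT

MHC_POSITIONS = (1, 4, 6, 9)
TCR_POSITIONS = (2, 3, 5, 7, 8)


class HomologyError(ValueError):
    pass


def split_faces(ninemer: str) -> tuple[str, str]:
    """(MHC-facing "1,4,6,9", TCR-facing "2,3,5,7,8") subsequences."""
    if len(ninemer) != 9:
        raise HomologyError(f"expected a 9-mer, got length {len(ninemer)}")
    mhc = "".join(ninemer[p - 1] for p in MHC_POSITIONS)
    tcr = "".join(ninemer[p - 1] for p in TCR_POSITIONS)
    return mhc, tcr


@dataclass
class ReferenceProteome:
    """Named protein sequences indexed by TCR-facing 9-mer pattern."""

    proteins: dict[str, str]
    _index: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._build_index()

    def _build_index(self) -> None:
        index: dict[str, list[tuple[str, int, str]]] = defaultdict(list)
        for name, seq in self.proteins.items():
            for off in range(len(seq) - 8):
                ninemer = seq[off : off + 9]
                _, tcr = split_faces(ninemer)
                index[tcr].append((name, off + 1, ninemer))  # 1-based offset
        self._index = dict(index)

    @classmethod
    def from_fasta(cls, path: Path) -> "ReferenceProteome":
        from Bio import SeqIO

        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def candidates(self, tcr_face: str) -> list[tuple[str, int, str]]:
        return self._index.get(tcr_face, [])

    def n_ninemers(self) -> int:
        return sum(max(0, len(s) - 8) for s in self.proteins.values())


@dataclass(frozen=True)
class CrossConservationRecord:
    """Proteome 9-mers matching one epitope hit's TCR face and HLA restriction."""

    query: str
    allele: str
    matches: tuple[tuple[str, int, str], ...]  # (protein, 1-based offset, ninemer)

    @property
    def depth(self) -> int:
        return len(self.matches)


def find_cross_conserved(
    hit: FrameScore,
    proteome: ReferenceProteome,
    matrices: ScoringMatrixSet,
    z_hit: float = Z_HIT,
) -> CrossConservationRecord:
    """Proteome 9-mers with identical TCR face that are hits for the allele."""
    _, tcr = split_faces(hit.ninemer)
    matches = []
    for protein, offset, ninemer in proteome.candidates(tcr):
        z = float(matrices.z_scores(ninemer, hit.allele)[0])
        if z >= z_hit:
            matches.append((protein, offset, ninemer))
    return CrossConservationRecord(hit.ninemer, hit.allele, tuple(matches))


def cross_conserve_table(
    table: FrameHitTable,
    proteome: ReferenceProteome,
    matrices: ScoringMatrixSet,
    z_hit: float = Z_HIT,
) -> list[CrossConservationRecord]:
    """One record per hit cell of a scanned peptide."""
    records = []
    for fs in table.frame_scores():
        if fs.z >= table.z_hit:
            records.append(find_cross_conserved(fs, proteome, matrices, z_hit=z_hit))
    return records


ELEVATED_TOLERANCE_CUT = 2.0


def homology_score(
    table: FrameHitTable, records: Iterable[CrossConservationRecord]
) -> tuple[float, bool]:
    """Mean cross-conservation depth over hit cells; (score, elevated flag).

    0 when the peptide has no hit cells; the flag is strict (> 2.0).
    """
    records = list(records)
    n_hits = int(table.scores["hit"].sum())
    if n_hits == 0:
        return 0.0, False
    if len(records) != n_hits:
        raise HomologyError(
            f"{n_hits} hit cells but {len(records)} cross-conservation records"
        )
    score = sum(r.depth for r in records) / n_hits
    return score, score > ELEVATED_TOLERANCE_CUT


QUADRANTS = (
    "epitope-dense/less-human",
    "epitope-dense/more-human",
    "epitope-sparse/less-human",
    "epitope-sparse/more-human",
)


@dataclass(frozen=True)
class QuadrantCall:
    epitope_score: float
    homology: float
    quadrant: str


def quadrant_classify(
    epitope_score: float,
    homology: float,
    density_cut: float = 0.0,
    homology_cut: float = ELEVATED_TOLERANCE_CUT,
) -> QuadrantCall:
    """Four-way risk quadrant; points on a cut go to the lower-risk side.

    Epitope-dense requires the aggregate score strictly above its cut;
    less-human requires the homology score strictly below its cut.
    """
    dense = epitope_score > density_cut   # on the cut -> sparse (lower risk)
    less_human = homology < homology_cut  # on the cut -> more-human (lower risk)
    label = (
        f"{'epitope-dense' if dense else 'epitope-sparse'}/"
        f"{'less-human' if less_human else 'more-human'}"
    )
    return QuadrantCall(epitope_score=epitope_score, homology=homology, quadrant=label)


def records_to_csv(records: Iterable[CrossConservationRecord], path: Path) -> None:
    rows = []
    for r in records:
        if not r.matches:
            rows.append((r.query, r.allele, 0, "", ""))
        for protein, offset, ninemer in r.matches:
            rows.append((r.query, r.allele, r.depth, protein, offset))
    pd.DataFrame(
        rows, columns=["query", "allele", "depth", "match_protein", "match_offset"]
    ).to_csv(path, index=False)
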