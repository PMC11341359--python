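"""Class II HLA DR epitope scanning with position-specific scoring matrices.

A peptide is parsed into overlapping 9-mer frames; each frame is scored
against a panel of HLA DR supertype allele matrices (a 9x20 position weight
matrix per allele).  Raw frame scores are standardised against a random
peptide background so that a frame's Z-score places it on the background
score distribution: frames in the top 5% (z >= 1.64) are "hits" — predicted
HLA ligands — and frames in the top 10% (z >= 1.28) are "elevated".  A frame
hit for four or more alleles of the panel is an EpiBar, the signature of a
promiscuous T-cell epitope.  An aggregate immunogenicity score sums hit
Z-scores per 1000 frame-by-allele assessments in excess of the background
expectation, so that a random peptide scores near zero.

The default nine-allele DR supertype panel is DRB1*0101, *0301, *0401,
*0701, *0801, *0901, *1101, *1301 and *1501.  Matrix weights are pluggable
(TSV, one file per allele, 9 rows x 20 residue columns); the shipped default
set is synthetic — seeded random weights that exercise the full procedure
without claiming any allele's true binding preferences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .peptide_model import CANONICAL, ModifiedPeptide

DEFAULT_PANEL = (
    "DRB1*0101", "DRB1*0301", "DRB1*0401", "DRB1*0701", "DRB1*0801",
    "DRB1*0901", "DRB1*1101", "DRB1*1301", "DRB1*1501",
)

Z_HIT = 1.64       # one-sided normal 5% tail
Z_ELEVATED = 1.28  # 10% tail

_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL)}


class ScanError(ValueError):
    pass


def encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_AA_INDEX[a] for a in seq), dtype=np.int64, count=len(seq))
    except KeyError as exc:
        raise ScanError(f"unsupported residue {exc.args[0]!r}") from None


def enumerate_frames(seq: str) -> list[str]:
    """All overlapping 9-mers, 1-based start order; len(seq) - 8 of them."""
    if len(seq) < 9:
        raise ScanError(f"sequence of length {len(seq)} has no 9-mer frame")
    return [seq[i : i + 9] for i in range(len(seq) - 8)]


@dataclass
class ScoringMatrixSet:
    """Per-allele 9x20 weight matrices plus background calibration."""

    matrices: dict[str, np.ndarray]
    calibration_mean: dict[str, float] = field(default_factory=dict)
    calibration_sd: dict[str, float] = field(default_factory=dict)
    background_expectation: Optional[float] = None  # per-assessment hit-z mass

    def __post_init__(self) -> None:
        for allele, m in self.matrices.items():
            m = np.asarray(m, dtype=float)
            if m.shape != (9, 20):
                raise ScanError(f"matrix for {allele} must be 9x20, got {m.shape}")
            self.matrices[allele] = m

    @property
    def alleles(self) -> tuple[str, ...]:
        return tuple(self.matrices)

    @property
    def calibrated(self) -> bool:
        return set(self.calibration_mean) == set(self.matrices) and bool(self.matrices)

    def raw_scores(self, seq: str, allele: str) -> np.ndarray:
        """Raw matrix score for every 9-mer frame of ``seq``."""
        idx = encode(seq)
        frames = np.lib.stride_tricks.sliding_window_view(idx, 9)
        m = self.matrices[allele]
        return m[np.arange(9), frames].sum(axis=1)

    def z_scores(self, seq: str, allele: str) -> np.ndarray:
        if not self.calibrated:
            raise ScanError("matrices are not calibrated; run calibrate() first")
        raw = self.raw_scores(seq, allele)
        return (raw - self.calibration_mean[allele]) / self.calibration_sd[allele]


def default_matrices(
    alleles: Sequence[str] = DEFAULT_PANEL, seed: int = 20240809
) -> ScoringMatrixSet:
    """Synthetic seeded random weight matrices for the default DR panel."""
    rng = np.random.default_rng(seed)
    return ScoringMatrixSet({a: rng.normal(0.0, 1.0, size=(9, 20)) for a in alleles})


def calibrate(
    matrices: ScoringMatrixSet,
    background: Iterable[str],
    z_hit: float = Z_HIT,
) -> ScoringMatrixSet:
    """Standardise raw scores against a random-peptide background.

    Stores per-allele mean and SD of raw frame scores so z = (raw - mean)/SD,
    and the per-assessment expectation of hit-cell z mass used by
    :func:`aggregate_score` so random peptides score near zero.  The
    background must yield enough frames for stable moments (>= 10,000
    recommended).
    """
    background = list(background)
    total_z = 0.0
    n_assessments = 0
    for allele in matrices.alleles:
        raws = np.concatenate([matrices.raw_scores(s, allele) for s in background])
        mean, sd = float(raws.mean()), float(raws.std(ddof=1))
        if sd <= 0 or not np.isfinite(sd):
            raise ScanError(f"degenerate background for {allele}: zero score variance")
        matrices.calibration_mean[allele] = mean
        matrices.calibration_sd[allele] = sd
        z = (raws - mean) / sd
        total_z += float(z[z >= z_hit].sum())
        n_assessments += z.size
    matrices.background_expectation = total_z / n_assessments
    return matrices


@dataclass(frozen=True)
class FrameScore:
    frame_index: int  # 1-based start position
    ninemer: str
    allele: str
    z: float


@dataclass
class FrameHitTable:
    """Full frame-by-allele scoring result for one peptide."""

    peptide: str
    scores: pd.DataFrame  # columns: frame, ninemer, allele, z, hit, elevated
    z_hit: float
    z_elevated: float
    epibar_frames: tuple[int, ...] = ()
    aggregate: Optional[float] = None

    @property
    def n_assessments(self) -> int:
        return len(self.scores)

    @property
    def n_frames(self) -> int:
        return int(self.scores["frame"].nunique())

    @property
    def hit_cells(self) -> pd.DataFrame:
        return self.scores[self.scores["hit"]]

    def frame_scores(self) -> list[FrameScore]:
        return [
            FrameScore(int(r.frame), r.ninemer, r.allele, float(r.z))
            for r in self.scores.itertuples()
        ]

    def to_csv(self, path: Path) -> None:
        df = self.scores.copy()
        df.insert(0, "peptide", self.peptide)
        df["epibar"] = df["frame"].isin(self.epibar_frames)
        df.to_csv(path, index=False)


def scan(
    peptide: ModifiedPeptide | str,
    matrices: ScoringMatrixSet,
    z_hit: float = Z_HIT,
    z_elevated: float = Z_ELEVATED,
    min_epibar_alleles: int = 4,
) -> FrameHitTable:
    """Score every 9-mer frame of a peptide against every panel allele.

    The peptide must already be naturalized (canonical residues only);
    scanning treats the chain as linear — disulfide topology is ignored.
    """
    if z_elevated > z_hit:
        raise ScanError("z_elevated must not exceed z_hit")
    if isinstance(peptide, str):
        name, seq = peptide, peptide
    else:
        if not peptide.is_unmodified:
            raise ScanError(
                f"{peptide.name} carries residue modifications; naturalize() it first"
            )
        name, seq = peptide.name, peptide.sequence
    frames = enumerate_frames(seq)
    rows = []
    for allele in matrices.alleles:
        zs = matrices.z_scores(seq, allele)
        for i, (ninemer, z) in enumerate(zip(frames, zs), start=1):
            rows.append((i, ninemer, allele, float(z)))
    df = pd.DataFrame(rows, columns=["frame", "ninemer", "allele", "z"])
    df["hit"] = df["z"] >= z_hit
    df["elevated"] = df["z"] >= z_elevated
    table = FrameHitTable(
        peptide=name, scores=df, z_hit=z_hit, z_elevated=z_elevated
    )
    table.epibar_frames = detect_epibars(table, min_alleles=min_epibar_alleles)
    table.aggregate = aggregate_score(table, matrices)
    return table


def detect_epibars(table: FrameHitTable, min_alleles: int = 4) -> tuple[int, ...]:
    """Frames called a hit for at least ``min_alleles`` panel alleles."""
    counts = table.scores.groupby("frame")["hit"].sum()
    return tuple(int(f) for f in counts.index[counts >= min_alleles])


def aggregate_score(table: FrameHitTable, matrices: ScoringMatrixSet) -> float:
    """Excess hit-Z mass per 1000 assessments over background expectation.

    S = 1000 * (sum of z over hit cells / N - e_bg) where N is the number of
    frame-by-allele assessments and e_bg the per-assessment expectation of
    the same statistic on the calibration background.  Random peptides score
    about 0; epitope-dense peptides score positive.
    """
    if matrices.background_expectation is None:
        raise ScanError("missing calibration: background expectation unknown")
    hit_mass = float(table.scores.loc[table.scores["hit"], "z"].sum())
    return 1000.0 * (hit_mass / table.n_assessments - matrices.background_expectation)


def frame_score(table: FrameHitTable, frame: int) -> float:
    """Sum of Z over alleles scoring elevated-or-better in one frame."""
    sub = table.scores[table.scores["frame"] == frame]
    if sub.empty:
        raise ScanError(f"frame {frame} not in table for {table.peptide}")
    return float(sub.loc[sub["elevated"], "z"].sum())


# ---------------------------------------------------------------------------
# Matrix TSV / calibration JSON persistence

def write_matrix_tsv(matrices: ScoringMatrixSet, directory: Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for allele, m in matrices.matrices.items():
        fname = allele.replace("*", "_") + ".tsv"
        df = pd.DataFrame(m, columns=list(CANONICAL))
        df.to_csv(directory / fname, sep="\t", index=False)
    if matrices.calibrated:
        sidecar = {
            "mean": matrices.calibration_mean,
            "sd": matrices.calibration_sd,
            "background_expectation": matrices.background_expectation,
        }
        (directory / "calibration.json").write_text(json.dumps(sidecar, indent=1))


def read_matrix_tsv(directory: Path, alleles: Sequence[str]) -> ScoringMatrixSet:
    directory = Path(directory)
    mats = {}
    for allele in alleles:
        fname = allele.replace("*", "_") + ".tsv"
        path = directory / fname
        if not path.exists():
            raise ScanError(f"matrix file not found: {path}")
        df = pd.read_csv(path, sep="\t")
        mats[allele] = df[list(CANONICAL)].to_numpy(dtype=float)
    mset = ScoringMatrixSet(mats)
    sidecar = directory / "calibration.json"
    if sidecar.exists():
        data = json.loads(sidecar.read_text())
        mset.calibration_mean = {a: float(v) for a, v in data["mean"].items()}
        mset.calibration_sd = {a: float(v) for a, v in data["sd"].items()}
        mset.background_expectation = data.get("background_expectation")
    return mset
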