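"""Seeded generators for every input the pipeline consumes.

The wet-lab and database inputs of the risk-assessment pipeline are
replaced by simulators with known ground truth: i.i.d. random peptide
backgrounds for score calibration, reference proteomes with planted
cross-conserved epitopes, four-parameter-logistic inhibition curves with
multiplicative lognormal noise, and over-dispersed (negative binomial)
FluoroSpot donor cohorts with a planted responder structure.  Every
generator is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .binding_assay import InhibitionCurve, four_pl
from .homology_scan import MHC_POSITIONS, TCR_POSITIONS
from .peptide_model import CANONICAL
from .tcell_assay import (
    DEFAULT_CELLS_PER_WELL,
    MEDIUM,
    NEGATIVE_CONTROL,
    POSITIVE_CONTROLS,
    DonorRecord,
    FluoroSpotWell,
)


class SimulationError(ValueError):
    pass


def _freq_vector(freqs: Optional[Sequence[float]]) -> np.ndarray:
    if freqs is None:
        return np.full(20, 0.05)
    f = np.asarray(freqs, dtype=float)
    if f.shape != (20,) or np.any(f < 0) or not np.isclose(f.sum(), 1.0):
        raise SimulationError("frequency vector must be 20 nonnegative values summing to 1")
    return f


def gen_background_peptides(
    n: int,
    length: int,
    freqs: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> list[str]:
    """``n`` i.i.d. random peptides of the given length.

    For score calibration the pool should yield at least 10,000 frames,
    i.e. n * (length - 8) >= 10,000.
    """
    f = _freq_vector(freqs)
    rng = np.random.default_rng(seed)
    letters = np.array(list(CANONICAL))
    draws = rng.choice(letters, size=(n, length), p=f)
    return ["".join(row) for row in draws]


def gen_reference_proteome(
    n_proteins: int,
    length: int,
    planted: Sequence[tuple[str, int, Optional[str]]] = (),
    freqs: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> dict[str, str]:
    """Random proteins with planted 9-mer copies at non-overlapping offsets.

    ``planted`` lists (ninemer, copies, mutate_face) where mutate_face is
    None, "tcr" or "mhc"; a mutated copy has one residue of that face
    flipped to a different letter, so TCR-face mutants must not be matched
    by a TCR-face-identical search.
    """
    rng = np.random.default_rng(seed)
    proteins = {
        f"prot{i:04d}": "".join(p)
        for i, p in enumerate(
            np.random.default_rng(rng.integers(2**31)).choice(
                np.array(list(CANONICAL)), size=(n_proteins, length), p=_freq_vector(freqs)
            )
        )
    }
    insertions = []
    for ninemer, copies, mutate_face in planted:
        if len(ninemer) != 9:
            raise SimulationError("planted sequences must be 9-mers")
        for _ in range(copies):
            insertions.append((ninemer, mutate_face))
    if not insertions:
        return proteins
    names = sorted(proteins)
    slots_per_protein = (length - 9) // 18  # non-overlapping 9-mer slots, spaced
    capacity = n_proteins * max(slots_per_protein, 0)
    if len(insertions) > capacity:
        raise SimulationError(f"{len(insertions)} planted copies exceed capacity {capacity}")
    slots = [
        (name, slot * 18)
        for name in names
        for slot in range(slots_per_protein)
    ]
    chosen = rng.choice(len(slots), size=len(insertions), replace=False)
    for (ninemer, mutate_face), slot_idx in zip(insertions, chosen):
        name, off = slots[slot_idx]
        insert = ninemer
        if mutate_face is not None:
            positions = TCR_POSITIONS if mutate_face == "tcr" else MHC_POSITIONS
            pos = int(rng.choice(positions))
            old = insert[pos - 1]
            new = str(rng.choice([c for c in CANONICAL if c != old]))
            insert = insert[: pos - 1] + new + insert[pos:]
        seq = proteins[name]
        proteins[name] = seq[:off] + insert + seq[off + 9 :]
    return proteins


def write_proteome_fasta(proteome: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(proteome):
            fh.write(f">{name}\n{proteome[name]}\n")


DEFAULT_CONCENTRATIONS = (46.0, 137.0, 412.0, 1_235.0, 3_704.0, 11_111.0, 100_000.0)


def gen_binding_curve(
    peptide: str,
    allele: str,
    true_ic50: float,
    hill: float = 1.0,
    top: float = 100.0,
    bottom: float = 0.0,
    cv: float = 0.10,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
    seed: int = 0,
) -> InhibitionCurve:
    """Triplicate 4PL inhibition readouts with multiplicative lognormal noise.

    The noise multiplies (value - bottom) so the curve floor stays put; its
    coefficient of variation is ``cv``.
    """
    if len(concentrations) != 7:
        raise SimulationError("seven concentrations required")
    if cv < 0 or true_ic50 <= 0 or hill <= 0:
        raise SimulationError("invalid curve parameters")
    rng = np.random.default_rng(seed)
    log_c = np.log10(np.asarray(concentrations, dtype=float))
    ideal = four_pl(log_c, bottom, top, np.log10(true_ic50), hill)
    values = []
    sigma = np.sqrt(np.log1p(cv**2))
    for v in ideal:
        if cv == 0:
            reps = (float(v),) * 3
        else:
            noise = rng.lognormal(-sigma**2 / 2.0, sigma, size=3)
            reps = tuple(float(bottom + (v - bottom) * z) for z in noise)
        values.append(reps)
    return InhibitionCurve(peptide, allele, tuple(float(c) for c in concentrations), tuple(values))


@dataclass
class SimulationConfig:
    """Study conditions for a simulated FluoroSpot cohort.

    Defaults mirror the case-study design: 16-donor cohorts, triplicate
    wells of 1e5 cells, a modestly over-dispersed background (negative
    binomial, mean 5 spots, dispersion 40 — replicate CV about 25% at a
    25-spot response, typical of FluoroSpot triplicates), responders at 5x
    background.
    """

    seed: int = 0
    cohort_size: int = 16
    responder_fraction: float = 7.0 / 16.0
    effect_size: float = 5.0
    background_mean: float = 5.0
    dispersion: float = 40.0  # NB size parameter; larger = closer to Poisson
    n_replicates: int = 3
    cells_per_well: float = DEFAULT_CELLS_PER_WELL
    test_condition: str = "test"
    control_effects: dict = field(
        default_factory=lambda: {"KLH": 20.0, "CEFT": 15.0, "PHA": 60.0, "HSA": 1.0}
    )
    qc_pass_rate: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.responder_fraction <= 1:
            raise SimulationError("responder fraction must be in [0, 1]")
        if self.effect_size < 1:
            raise SimulationError("effect size must be >= 1")
        if self.background_mean <= 0 or self.dispersion <= 0:
            raise SimulationError("background mean and dispersion must be positive")


def _nb_counts(rng: np.random.Generator, mean: float, size_param: float, n: int) -> np.ndarray:
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n)


def gen_fluorospot_cohort(
    config: SimulationConfig,
) -> tuple[list[FluoroSpotWell], list[DonorRecord], dict[str, bool]]:
    """A full cohort of wells plus donor metadata and the planted truth.

    Returns (wells, donor records, {donor: is planted responder}).  The
    first ``round(fraction * cohort_size)`` donors are responders (donor
    order is randomised downstream of the seed, so this is not a bias).
    Control conditions are generated so QC passes at ``qc_pass_rate``.
    """
    rng = np.random.default_rng(config.seed)
    n_resp = int(round(config.responder_fraction * config.cohort_size))
    wells: list[FluoroSpotWell] = []
    donors: list[DonorRecord] = []
    truth: dict[str, bool] = {}
    for i in range(config.cohort_size):
        donor = f"D{i + 1:03d}"
        is_responder = i < n_resp
        truth[donor] = is_responder
        qc_intended = rng.random() < config.qc_pass_rate
        conditions: dict[str, float] = {MEDIUM: config.background_mean}
        conditions[NEGATIVE_CONTROL] = config.background_mean * config.control_effects["HSA"]
        for ctrl in POSITIVE_CONTROLS:
            fold = config.control_effects[ctrl] if qc_intended else 1.0
            conditions[ctrl] = config.background_mean * fold
        test_mean = config.background_mean * (config.effect_size if is_responder else 1.0)
        conditions[config.test_condition] = test_mean
        for cond, mean in conditions.items():
            counts = _nb_counts(rng, mean, config.dispersion, config.n_replicates)
            for c in counts:
                wells.append(
                    FluoroSpotWell(donor, cond, int(c), config.cells_per_well)
                )
        donors.append(
            DonorRecord(
                donor=donor,
                age=int(rng.integers(17, 84)),
                sex="F" if rng.random() < 0.4 else "M",
                drb1_alleles=tuple(
                    str(a)
                    for a in rng.choice(
                        ["DRB1*0301", "DRB1*0401", "DRB1*0701",
                         "DRB1*1101", "DRB1*1301", "DRB1*1501"],
                        size=2, replace=False,
                    )
                ),
            )
        )
    return wells, donors, truth


def wells_to_csv(wells: Sequence[FluoroSpotWell], path: Path) -> None:
    pd.DataFrame(
        [
            {
                "donor": w.donor,
                "condition": w.condition,
                "replicate": i,
                "spots": w.spots,
                "cells_per_well": w.cells_per_well,
            }
            for i, w in enumerate(wells)
        ]
    ).to_csv(path, index=False)


def donors_to_csv(donors: Sequence[DonorRecord], path: Path) -> None:
    pd.DataFrame(
        [
            {
                "donor": d.donor,
                "age": d.age,
                "sex": d.sex,
                "drb1_allele_1": d.drb1_alleles[0] if d.drb1_alleles else "",
                "drb1_allele_2": d.drb1_alleles[1] if len(d.drb1_alleles) > 1 else "",
            }
            for d in donors
        ]
    ).to_csv(path, index=False)
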