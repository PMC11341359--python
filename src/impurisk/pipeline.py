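"""End-to-end orchestration: scan, homology, comparison, risk report.

``run_pipeline`` wires the modules together for one API and its impurities:
calibrate the scoring panel on a random background, scan everything,
cross-conserve hits against a reference proteome, enumerate new epitopes
per impurity, classify the modification face and recommend the follow-up
assay, and emit a JSON risk report plus CSV artifacts.  Deterministic for
fixed seeds and inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .epitope_scan import (
    DEFAULT_PANEL,
    Z_ELEVATED,
    Z_HIT,
    FrameHitTable,
    ScoringMatrixSet,
    calibrate,
    default_matrices,
    read_matrix_tsv,
    scan,
)
from .fixtures import ImpurityDef, api_peptide
from .homology_scan import (
    ReferenceProteome,
    cross_conserve_table,
    homology_score,
    quadrant_classify,
)
from .impurity_compare import classify_modification, new_epitopes, recommend_assay
from .peptide_model import (
    ModifiedPeptide,
    apply_edit,
    molar_concentration,
    naturalize,
)
from .synthetic_data import gen_background_peptides, gen_reference_proteome

log = logging.getLogger("impurisk")


@dataclass
class PipelineConfig:
    seed: int = 0
    alleles: Sequence[str] = DEFAULT_PANEL
    matrix_dir: Optional[Path] = None     # default: synthetic seeded matrices
    proteome_fasta: Optional[Path] = None  # default: synthetic proteome
    z_hit: float = Z_HIT
    z_elevated: float = Z_ELEVATED
    background_n: int = 1200
    background_length: int = 18
    dose_ug_ml: float = 20.0
    out_dir: Optional[Path] = None


def prepare_matrices(config: PipelineConfig) -> ScoringMatrixSet:
    if config.matrix_dir is not None:
        matrices = read_matrix_tsv(Path(config.matrix_dir), config.alleles)
    else:
        matrices = default_matrices(config.alleles, seed=config.seed + 101)
    if not matrices.calibrated:
        background = gen_background_peptides(
            config.background_n, config.background_length, seed=config.seed + 7
        )
        calibrate(matrices, background, z_hit=config.z_hit)
    return matrices


def prepare_proteome(config: PipelineConfig) -> ReferenceProteome:
    if config.proteome_fasta is not None:
        return ReferenceProteome.from_fasta(Path(config.proteome_fasta))
    return ReferenceProteome(
        gen_reference_proteome(60, 120, seed=config.seed + 13)
    )


def peptide_summary(
    peptide: ModifiedPeptide,
    matrices: ScoringMatrixSet,
    proteome: ReferenceProteome,
    config: PipelineConfig,
) -> tuple[dict, FrameHitTable]:
    if peptide.is_unmodified:
        scan_seq = peptide.sequence
        provenance = ()
    else:
        # scan the first natural-analog expansion; provenance reported
        scan_seq, provenance = naturalize(peptide)[0]
    table = scan(scan_seq, matrices, z_hit=config.z_hit, z_elevated=config.z_elevated)
    table.peptide = peptide.name
    records = cross_conserve_table(table, proteome, matrices, z_hit=config.z_hit)
    homology, elevated = homology_score(table, records)
    quad = quadrant_classify(table.aggregate, homology)
    summary = {
        "name": peptide.name,
        "length": len(peptide),
        "sequence": peptide.sequence,
        "naturalized_substitutions": [
            {"position": pos, "modification": tag, "analog": analog}
            for pos, tag, analog in provenance
        ],
        "molar_dose_uM": molar_concentration(config.dose_ug_ml, peptide),
        "hits": int(table.scores["hit"].sum()),
        "epibar_frames": list(table.epibar_frames),
        "aggregate_score": round(table.aggregate, 2),
        "homology_score": round(homology, 2),
        "elevated_tolerance": elevated,
        "quadrant": quad.quadrant,
    }
    return summary, table


def run_pipeline(
    config: PipelineConfig,
    api: Optional[ModifiedPeptide] = None,
    impurities: Sequence[ImpurityDef] = (),
) -> dict:
    """Full risk report for one API and its edit-specified impurities."""
    api = api or api_peptide()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    log.info(
        "impurisk %s: panel=%d alleles, z_hit=%.2f, z_elevated=%.2f, seed=%d",
        __version__, len(config.alleles), config.z_hit, config.z_elevated, config.seed,
    )
    matrices = prepare_matrices(config)
    proteome = prepare_proteome(config)

    api_summary, api_table = peptide_summary(api, matrices, proteome, config)
    if out_dir:
        api_table.to_csv(out_dir / f"scan_{api.name}.csv")

    imp_reports = []
    for spec in impurities:
        pep = apply_edit(api, spec.edit)
        summary, table = peptide_summary(pep, matrices, proteome, config)
        report = new_epitopes(api_table, table)
        classification = classify_modification(spec.edit, api_table)
        summary.update(
            {
                "name": spec.name,
                "abundance_pct": spec.abundance_pct,
                "new_epitopes": report.counts,
                "new_epitope_cells": report.cells.to_dict("records"),
                "modification_face": classification,
                "recommended_assay": recommend_assay(classification),
            }
        )
        if out_dir:
            table.to_csv(out_dir / f"scan_{spec.name}.csv")
        imp_reports.append(summary)

    report = {
        "version": __version__,
        "thresholds": {
            "z_hit": config.z_hit,
            "z_elevated": config.z_elevated,
            "epibar_min_alleles": 4,
            "homology_elevated": 2.0,
        },
        "seed": config.seed,
        "api": api_summary,
        "impurities": imp_reports,
    }
    if out_dir:
        (out_dir / "risk_report.json").write_text(json.dumps(report, indent=1))
        log.info("report written to %s", out_dir / "risk_report.json")
    return report
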