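#!/usr/bin/env python
"""Generate every synthetic input downstream analyses consume.

Writes under results/inputs/: the calibrated allele scoring matrices
(TSV + calibration sidecar), a calibration background, a reference
proteome, simulated inhibition curves with known IC50s, and a simulated
FluoroSpot cohort with a planted 7/16 responder fraction.
"""

from pathlib import Path

import json

from impurisk.epitope_scan import calibrate, default_matrices, write_matrix_tsv
from impurisk.synthetic_data import (
    SimulationConfig,
    donors_to_csv,
    gen_background_peptides,
    gen_binding_curve,
    gen_fluorospot_cohort,
    gen_reference_proteome,
    wells_to_csv,
    write_proteome_fasta,
)

SEED = 1
OUT = Path("results/inputs")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    matrices = default_matrices(seed=SEED + 101)
    background = gen_background_peptides(1200, 18, seed=SEED + 7)
    calibrate(matrices, background)
    write_matrix_tsv(matrices, OUT / "matrices")
    (OUT / "background.fasta").write_text(
        "".join(f">bg{i:05d}\n{p}\n" for i, p in enumerate(background))
    )
    print(f"calibrated {len(matrices.alleles)} allele matrices on "
          f"{sum(len(p) - 8 for p in background)} background frames")

    proteome = gen_reference_proteome(60, 120, seed=SEED + 13)
    write_proteome_fasta(proteome, OUT / "proteome.fasta")
    print(f"reference proteome: {len(proteome)} proteins")

    import pandas as pd

    rows, truth = [], {}
    for i, log_ic50 in enumerate([2.5, 3.0, 3.5, 4.0, 4.5, 5.0]):
        name = f"sim-pep{i}"
        truth[name] = 10 ** log_ic50
        curve = gen_binding_curve(name, "DRB1*0101", 10 ** log_ic50, cv=0.10, seed=SEED + i)
        for c, reps in zip(curve.concentrations_nM, curve.inhibition):
            for j, v in enumerate(reps):
                rows.append((name, "DRB1*0101", c, j, v))
    pd.DataFrame(
        rows, columns=["peptide", "allele", "concentration_nM", "replicate", "percent_inhibition"]
    ).to_csv(OUT / "binding_curves.csv", index=False)
    (OUT / "binding_truth.json").write_text(json.dumps(truth, indent=1))
    print(f"simulated {len(truth)} inhibition curves (true IC50 in truth file)")

    config = SimulationConfig(seed=SEED, cohort_size=16, responder_fraction=7 / 16)
    wells, donors, planted = gen_fluorospot_cohort(config)
    wells_to_csv(wells, OUT / "fluorospot_wells.csv")
    donors_to_csv(donors, OUT / "fluorospot_donors.csv")
    (OUT / "fluorospot_truth.json").write_text(json.dumps(planted, indent=1))
    print(f"FluoroSpot cohort: {config.cohort_size} donors, "
          f"{sum(planted.values())} planted responders")


if __name__ == "__main__":
    main()
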