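#!/usr/bin/env python
"""Fit IC50s to the simulated competition curves; classify published IC50s.

Fits the 4PL model to every simulated inhibition curve, compares the
fitted IC50 to the planted truth, and applies the affinity-bin classifier
to the published case-study IC50 table.  Writes results/binding/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from impurisk.binding_assay import classify_affinity, fit_ic50, read_curves_csv, results_to_csv
from impurisk.fixtures import IC50_TABLE

OUT = Path("results/binding")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    curves = read_curves_csv(Path("results/inputs/binding_curves.csv"))
    truth = json.loads(Path("results/inputs/binding_truth.json").read_text())
    results = [fit_ic50(c) for c in curves]
    results_to_csv(results, OUT / "ic50_fits.csv")
    errors = []
    for r in results:
        true = truth[r.peptide]
        err = abs(np.log10(r.ic50_nM / true)) if r.ic50_nM else float("inf")
        errors.append(err)
        print(f"{r.peptide}: fitted {r.ic50_nM:,.0f} nM vs true {true:,.0f} nM "
              f"({r.affinity_class}, |log10 ratio| {err:.3f})")
    print(f"median |log10 ratio| over {len(errors)} curves: {np.median(errors):.3f}")

    rows = [
        {
            "peptide": rec.peptide,
            "allele": rec.allele,
            "ic50_nM": rec.ic50_nM,
            "published_label": rec.label,
            "classified": classify_affinity(rec.ic50_nM, dose_dependent=True),
        }
        for rec in IC50_TABLE
    ]
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "published_ic50_classification.csv", index=False)
    labelled = df[df["published_label"].notna()]
    agree = int((labelled["published_label"] == labelled["classified"]).sum())
    print(f"published labels reproduced: {agree}/{len(labelled)}")
    cterm = df[df["peptide"] == "API-C-term"]
    print(f"C-terminal API peptide: classifiable binder for {len(cterm)} of 8 alleles")


if __name__ == "__main__":
    main()
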