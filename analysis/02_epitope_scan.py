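#!/usr/bin/env python
"""Scan the salmon calcitonin API and all case-study impurities.

Scores every 9-mer frame against the calibrated DR allele panel, calls
hits and EpiBars, and writes per-peptide frame tables plus a summary of
aggregate scores under results/scan/.
"""

from pathlib import Path

import pandas as pd

from impurisk.epitope_scan import read_matrix_tsv, DEFAULT_PANEL, scan
from impurisk.fixtures import BINDING_IMPURITIES, TCELL_IMPURITIES, api_peptide
from impurisk.peptide_model import apply_edit, naturalize

OUT = Path("results/scan")
MATRICES = Path("results/inputs/matrices")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    matrices = read_matrix_tsv(MATRICES, DEFAULT_PANEL)
    api = api_peptide()
    peptides = [api]
    for spec in TCELL_IMPURITIES + BINDING_IMPURITIES:
        peptides.append(apply_edit(api, spec.edit))

    rows = []
    for pep in peptides:
        seq = pep.sequence if pep.is_unmodified else naturalize(pep)[0][0]
        table = scan(seq, matrices)
        table.peptide = pep.name
        table.to_csv(OUT / f"frames_{pep.name}.csv")
        rows.append(
            {
                "peptide": pep.name,
                "frames": table.n_frames,
                "hits": int(table.scores["hit"].sum()),
                "epibars": ",".join(map(str, table.epibar_frames)),
                "aggregate_score": round(table.aggregate, 2),
            }
        )
        print(f"{pep.name}: {rows[-1]['hits']} hits, "
              f"EpiBars [{rows[-1]['epibars']}], score {rows[-1]['aggregate_score']}")
    pd.DataFrame(rows).to_csv(OUT / "scan_summary.csv", index=False)


if __name__ == "__main__":
    main()
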