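#!/usr/bin/env python
"""Compare each impurity to the API: new epitopes, faces, assay choice.

For every case-study impurity, counts hit cells absent from the API
(split into new-HLA-binding vs altered-TCR-face), classifies which face
of the API's predicted epitopes the modification touches, recommends the
wet-lab follow-up, and designs the short binding-assay peptide for the
C-terminal epitope region.  Writes results/compare/impurity_comparison.csv.
"""

from pathlib import Path

import pandas as pd

from impurisk.epitope_scan import DEFAULT_PANEL, read_matrix_tsv, scan
from impurisk.fixtures import BINDING_IMPURITIES, TCELL_IMPURITIES, api_peptide
from impurisk.impurity_compare import (
    classify_modification,
    design_binding_peptide,
    new_epitopes,
    recommend_assay,
)
from impurisk.peptide_model import apply_edit, naturalize

OUT = Path("results/compare")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    matrices = read_matrix_tsv(Path("results/inputs/matrices"), DEFAULT_PANEL)
    api = api_peptide()
    api_table = scan(api, matrices)

    rows = []
    for spec in TCELL_IMPURITIES + BINDING_IMPURITIES:
        pep = apply_edit(api, spec.edit)
        seq = pep.sequence if pep.is_unmodified else naturalize(pep)[0][0]
        table = scan(seq, matrices)
        table.peptide = spec.name
        report = new_epitopes(api_table, table)
        face = classify_modification(spec.edit, api_table)
        rows.append(
            {
                "impurity": spec.name,
                "modification": spec.note,
                "new_hla_binding": report.counts["new-HLA-binding"],
                "altered_tcr_face": report.counts["altered-TCR-face"],
                "face": face,
                "recommended_assay": recommend_assay(face),
            }
        )
        print(f"{spec.name}: {report.total} new epitope cells "
              f"({face} -> {rows[-1]['recommended_assay']})")
    pd.DataFrame(rows).to_csv(OUT / "impurity_comparison.csv", index=False)

    # assay peptide for the C-terminal promiscuous epitope region (frame 16)
    design = design_binding_peptide(api, 16)
    print(f"binding-assay peptide around frame 16: {design.peptide.sequence} "
          f"(window {design.window}, Cys->Ser at {design.cys_replaced or 'none'})")


if __name__ == "__main__":
    main()
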