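#!/usr/bin/env python
"""Cross-conserve every epitope hit against the reference proteome.

Computes each peptide's homology score (mean depth of TCR-face-identical,
same-allele proteome matches over hit cells) and places it on the
epitope-density x human-homology quadrant plot.  Writes
results/homology/quadrants.csv and a matplotlib quadrant figure.
"""

from pathlib import Path

import pandas as pd

from impurisk.epitope_scan import DEFAULT_PANEL, read_matrix_tsv, scan
from impurisk.fixtures import BINDING_IMPURITIES, TCELL_IMPURITIES, api_peptide
from impurisk.homology_scan import (
    ReferenceProteome,
    cross_conserve_table,
    homology_score,
    quadrant_classify,
    records_to_csv,
)
from impurisk.peptide_model import apply_edit, naturalize

OUT = Path("results/homology")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    matrices = read_matrix_tsv(Path("results/inputs/matrices"), DEFAULT_PANEL)
    proteome = ReferenceProteome.from_fasta(Path("results/inputs/proteome.fasta"))
    api = api_peptide()
    peptides = [api] + [
        apply_edit(api, s.edit) for s in TCELL_IMPURITIES + BINDING_IMPURITIES
    ]
    rows = []
    for pep in peptides:
        seq = pep.sequence if pep.is_unmodified else naturalize(pep)[0][0]
        table = scan(seq, matrices)
        table.peptide = pep.name
        records = cross_conserve_table(table, proteome, matrices)
        homology, elevated = homology_score(table, records)
        quad = quadrant_classify(table.aggregate, homology)
        records_to_csv(records, OUT / f"records_{pep.name}.csv")
        rows.append(
            {
                "peptide": pep.name,
                "epitope_score": round(table.aggregate, 2),
                "homology": round(homology, 2),
                "elevated_tolerance": elevated,
                "quadrant": quad.quadrant,
            }
        )
        print(f"{pep.name}: epitope score {rows[-1]['epitope_score']}, homology {rows[-1]['homology']} -> {quad.quadrant}")
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "quadrants.csv", index=False)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(df["homology"], df["epitope_score"])
    for r in df.itertuples():
        ax.annotate(r.peptide, (r.homology, r.epitope_score), fontsize=7)
    ax.axhline(0.0, color="gray", lw=1)
    ax.axvline(2.0, color="gray", lw=1)
    ax.set_xlabel("homology score (mean cross-conservation depth)")
    ax.set_ylabel("aggregate epitope score (per 1000 assessments)")
    ax.set_title("immunogenicity risk quadrants")
    fig.tight_layout()
    fig.savefig(OUT / "quadrants.png", dpi=120)


if __name__ == "__main__":
    main()
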