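"""Reference data for the salmon calcitonin (SCT) case study.

Salmon calcitonin is a 32-residue therapeutic peptide, C-terminally
amidated, with a disulfide ring between cysteines 1 and 7.  Synthetic
manufacture introduces single-modification impurities — insertions,
deletions, acetylation, deamidation — whose immunogenicity risk relative to
the API these fixtures let the pipeline exercise end to end: the API and
human ortholog sequences, the impurity edit definitions with their observed
relative abundances in a generic product, the short assay-peptide designs
used in HLA competition binding, the published IC50 readouts with their
qualitative affinity labels, and the published cohort responder counts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from .peptide_model import EditOperation, ModifiedPeptide, apply_edit

#: 32-mer API; disulfide C1-C7; C-terminal amide in the drug product.
API_SEQUENCE = "CSNLSTCVLGKLSQELHKLQTYPRTNTGSGTP"

#: Human calcitonin ortholog (32-mer) — 50% positional identity with SCT.
HUMAN_CALCITONIN = "CGNLSTCMLGTYTQDFNKFHTFPQTAIGVGAP"

STANDARD_DOSE_UG_ML = 20.0  # T-cell assay dose for API and impurities


def api_peptide() -> ModifiedPeptide:
    return ModifiedPeptide.from_sequence(
        "SCT",
        API_SEQUENCE,
        c_terminal_amide=True,
        disulfide_pairs=((1, 7),),
    )


@dataclass(frozen=True)
class ImpurityDef:
    name: str
    edit: EditOperation
    abundance_pct: Optional[float]
    note: str


#: Impurities compared to the API in naive T-cell assays (full-length,
#: amidated, disulfide-bridged); abundance = observed % of API in a generic
#: SCT product.
TCELL_IMPURITIES = (
    ImpurityDef(
        "LYS-AC18_SCT", EditOperation("side_chain_mod", 18, "acetyl-K"), 0.24,
        "acetylation of lysine 18",
    ),
    ImpurityDef(
        "Q20E_SCT", EditOperation("substitution", 20, "E"), 0.36,
        "deamidation of glutamine 20 to glutamic acid",
    ),
    ImpurityDef(
        "ENDO-GLY28_SCT", EditOperation("insertion", 28, "G"), 2.62,
        "insertion of glycine at position 28",
    ),
    ImpurityDef(
        "ENDO-THR31_SCT", EditOperation("insertion", 31, "T"), 3.30,
        "insertion of threonine at position 31",
    ),
)

#: Impurities with HLA-anchor modifications, tested in binding assays.
BINDING_IMPURITIES = (
    ImpurityDef(
        "LYS-AC11_SCT", EditOperation("side_chain_mod", 11, "acetyl-K"), None,
        "acetylation of lysine 11",
    ),
    ImpurityDef(
        "DES-THR21_SCT", EditOperation("deletion", 21), None,
        "deletion of threonine 21",
    ),
    ImpurityDef(
        "DES-ASN26_SCT", EditOperation("deletion", 26), None,
        "deletion of asparagine 26",
    ),
)


def tcell_peptides() -> list[ModifiedPeptide]:
    """Full-length API-derived impurity peptides for the T-cell assays."""
    api = api_peptide()
    out = []
    for spec in TCELL_IMPURITIES:
        pep = apply_edit(api, spec.edit)
        out.append(
            replace(pep, name=spec.name, relative_abundance_pct=spec.abundance_pct)
        )
    return out


#: Short peptides synthesized for the HLA competition binding assay.  The
#: free cysteine at API position 7 is replaced by serine to prevent
#: disulfide-linked aggregation.
BINDING_ASSAY_PEPTIDES = {
    "API-N-term": "STSVLGKLSQELHKLQTY",      # API 5-22, C7S
    "API-C-term": "SQELHKLQTYPRTNT",         # API 13-27
    "LYS-AC11_SCT": "STSVLGKLSQELHKL",       # API 5-19, C7S, acetyl-K at 11
    "DES-THR21_SCT": "SQELHKLQYPRTNTGSGT",   # API 13-30 minus T21
    "DES-ASN26_SCT": "HKLQTYPRTTGSGT",       # API 17-30 minus N26
}


@dataclass(frozen=True)
class IC50Record:
    peptide: str
    allele: str
    ic50_nM: float
    label: Optional[str]  # published qualitative bin word, when printed


#: Published competition-assay IC50s.  ``label`` carries the qualitative
#: affinity word printed alongside the value ("weak" maps to the low bin);
#: the two DES-THR21 values were reported without a bin word.
IC50_TABLE = (
    IC50Record("API-N-term", "DRB1*0101", 11_134.0, "low"),
    IC50Record("API-N-term", "DRB1*1101", 104_638.0, "negligible"),
    IC50Record("API-N-term", "DRB1*1501", 95_929.0, "low"),
    IC50Record("API-C-term", "DRB1*0101", 3_348.0, "moderate"),
    IC50Record("API-C-term", "DRB1*0301", 66_416.0, "low"),
    IC50Record("API-C-term", "DRB1*1101", 161_114.0, "negligible"),
    IC50Record("API-C-term", "DRB1*1301", 8_742.0, "moderate"),
    IC50Record("API-C-term", "DRB1*1501", 2_291.0, "moderate"),
    IC50Record("LYS-AC11_SCT", "DRB1*0101", 12_306.0, "low"),
    IC50Record("LYS-AC11_SCT", "DRB1*1501", 12_774.0, "low"),
    IC50Record("DES-THR21_SCT", "DRB1*0101", 14_771.0, None),
    IC50Record("DES-THR21_SCT", "DRB1*1501", 178_709.0, None),
    IC50Record("DES-ASN26_SCT", "DRB1*1101", 308_378.0, "negligible"),
    IC50Record("DES-ASN26_SCT", "DRB1*1501", 9_789.0, "moderate"),
)

#: Eight alleles titrated in the binding assays (*0901 replaces *0801 of
#: the nine-allele in silico panel).
BINDING_ASSAY_ALLELES = (
    "DRB1*0101", "DRB1*0301", "DRB1*0401", "DRB1*0701",
    "DRB1*0901", "DRB1*1101", "DRB1*1301", "DRB1*1501",
)

#: Published naive T-cell cohort responder counts (k positive of N donors).
RESPONSE_COUNTS = {
    "SCT": (7, 16),
    "LYS-AC18_SCT": (9, 16),
    "Q20E_SCT": (9, 16),
    "ENDO-GLY28_SCT": (10, 16),
    "ENDO-THR31_SCT": (11, 16),
}
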