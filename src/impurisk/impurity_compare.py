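"""Impurity-versus-API comparison: new epitopes and assay selection.

An impurity's single modification can (a) create 9-mer frames that bind an
HLA allele where the API did not ("new HLA binding"), or (b) leave binding
intact while changing the residues shown to the T-cell receptor ("altered
TCR face").  Both kinds count as new epitopes that can drive an anti-drug
response.  Whether the modified position sits on the HLA-anchoring face
(frame positions 1, 4, 6, 9) or the TCR face (2, 3, 5, 7, 8) of the API's
predicted epitopes decides which wet-lab follow-up is informative: HLA
competition binding assays for anchor changes, naive T-cell assays for TCR
face changes.  Short assay peptides are designed by centering the binding
region and replacing free cysteines with serine to avoid disulfide-linked
aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .epitope_scan import FrameHitTable
from .homology_scan import MHC_POSITIONS, split_faces
from .peptide_model import EditOperation, ModifiedPeptide, PeptideError, Residue


@dataclass(frozen=True)
class ResidueMapping:
    """Aligned (api_index, impurity_index) pairs, None for a gap; 1-based."""

    pairs: tuple[tuple[Optional[int], Optional[int]], ...]

    def api_to_impurity(self) -> dict[int, int]:
        return {a: b for a, b in self.pairs if a is not None and b is not None}


def align_to_api(
    impurity: ModifiedPeptide | str,
    api: ModifiedPeptide | str,
    edit: Optional[EditOperation] = None,
) -> ResidueMapping:
    """Map API positions onto impurity positions.

    When the impurity is specified as an edit on the API the mapping is exact;
    otherwise a global alignment (match +1, mismatch -1, gap -2, leftmost gap
    on ties) is computed with Bio.Align.
    """
    api_seq = api if isinstance(api, str) else api.sequence
    imp_seq = impurity if isinstance(impurity, str) else impurity.sequence
    if not api_seq or not imp_seq:
        raise PeptideError("empty sequence")
    if edit is not None:
        return _mapping_from_edit(edit, len(api_seq))
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    alignment = aligner.align(api_seq, imp_seq)[0]  # first = leftmost-gap
    pairs: list[tuple[Optional[int], Optional[int]]] = []
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        for k in range(a_end - a_start):
            pairs.append((a_start + k + 1, b_start + k + 1))
    # interleave gap columns in positional order
    full: list[tuple[Optional[int], Optional[int]]] = []
    ai = bi = 1
    for a, b in pairs:
        while ai < a:
            full.append((ai, None))
            ai += 1
        while bi < b:
            full.append((None, bi))
            bi += 1
        full.append((a, b))
        ai, bi = a + 1, b + 1
    while ai <= len(api_seq):
        full.append((ai, None))
        ai += 1
    while bi <= len(imp_seq):
        full.append((None, bi))
        bi += 1
    return ResidueMapping(tuple(full))


def _mapping_from_edit(edit: EditOperation, api_len: int) -> ResidueMapping:
    pairs: list[tuple[Optional[int], Optional[int]]] = []
    if edit.kind == "deletion":
        shift = 0
        for a in range(1, api_len + 1):
            if a == edit.position:
                pairs.append((a, None))
                shift = -1
            else:
                pairs.append((a, a + shift))
    elif edit.kind == "insertion":
        for a in range(1, edit.position):
            pairs.append((a, a))
        pairs.append((None, edit.position))
        for a in range(edit.position, api_len + 1):
            pairs.append((a, a + 1))
    else:  # substitution / side_chain_mod: identity mapping
        pairs = [(a, a) for a in range(1, api_len + 1)]
    return ResidueMapping(tuple(pairs))


@dataclass
class NewEpitopeReport:
    impurity: str
    cells: pd.DataFrame  # columns: frame, allele, ninemer, reason

    @property
    def counts(self) -> dict[str, int]:
        base = {"new-HLA-binding": 0, "altered-TCR-face": 0}
        base.update(self.cells["reason"].value_counts().to_dict())
        return base

    @property
    def total(self) -> int:
        return len(self.cells)


def new_epitopes(
    api_table: FrameHitTable, imp_table: FrameHitTable
) -> NewEpitopeReport:
    """Hit cells of the impurity absent from the API, with a reason each.

    Matching is by 9-mer sequence identity per allele, not frame index, so an
    indel that merely shifts an unchanged epitope does not create a "new"
    one.  A new cell is altered-TCR-face when some API hit for the same
    allele shares its HLA-anchor residues but differs on the TCR face;
    otherwise it is new-HLA-binding.
    """
    if (api_table.z_hit, api_table.z_elevated) != (imp_table.z_hit, imp_table.z_elevated):
        raise ValueError("tables scanned under different thresholds")
    api_hits = api_table.hit_cells
    api_by_allele: dict[str, set[str]] = {
        a: set(g["ninemer"]) for a, g in api_hits.groupby("allele")
    }
    api_anchors: dict[str, set[str]] = {
        a: {split_faces(n)[0] for n in nines} for a, nines in api_by_allele.items()
    }
    rows = []
    for r in imp_table.hit_cells.itertuples():
        known = api_by_allele.get(r.allele, set())
        if r.ninemer in known:
            continue
        mhc_face, _ = split_faces(r.ninemer)
        reason = (
            "altered-TCR-face"
            if mhc_face in api_anchors.get(r.allele, set())
            else "new-HLA-binding"
        )
        rows.append((int(r.frame), r.allele, r.ninemer, reason))
    cells = pd.DataFrame(rows, columns=["frame", "allele", "ninemer", "reason"])
    return NewEpitopeReport(impurity=imp_table.peptide, cells=cells)


def classify_modification(
    edit: EditOperation, api_table: FrameHitTable
) -> str:
    """Which epitope face the edited API position touches.

    Returns "HLA-facing", "TCR-facing", "both" (edit overlaps hit frames on
    both faces) or "outside-epitope".  For indels the edit position itself is
    assessed against every API hit frame covering it.
    """
    hit_frames = sorted(set(int(f) for f in api_table.hit_cells["frame"]))
    faces = set()
    for f in hit_frames:
        if f <= edit.position <= f + 8:
            offset = edit.position - f + 1  # 1..9 within the frame
            faces.add("HLA-facing" if offset in MHC_POSITIONS else "TCR-facing")
    if not faces:
        return "outside-epitope"
    if len(faces) == 2:
        return "both"
    return faces.pop()


def recommend_assay(classification: str) -> str:
    """Map a face classification to the informative wet-lab follow-up."""
    return {
        "HLA-facing": "binding-assay",
        "TCR-facing": "t-cell-assay",
        "both": "both",
        "outside-epitope": "none",
    }[classification]


@dataclass(frozen=True)
class AssayPeptideDesign:
    peptide: ModifiedPeptide
    window: tuple[int, int]  # 1-based inclusive span on the source peptide
    cys_replaced: tuple[int, ...]
    clipped: bool


def design_binding_peptide(
    p: ModifiedPeptide, center_frame: int, length: int = 15
) -> AssayPeptideDesign:
    """A short assay peptide centering a 9-mer binding frame.

    The window (default 15-mer: frame plus three flanking residues each
    side) is clipped and flagged when the frame abuts a terminus.  Free
    cysteines in the window are replaced with serine (recorded) to prevent
    disulfide-linked aggregation in the assay.
    """
    n = len(p)
    if not 1 <= center_frame <= n - 8:
        raise PeptideError(f"frame {center_frame} out of range")
    flank = max(0, (length - 9) // 2)
    start = center_frame - flank
    end = center_frame + 8 + (length - 9 - flank)
    clipped = start < 1 or end > n
    start, end = max(1, start), min(n, end)
    residues = []
    replaced = []
    for pos in range(start, end + 1):
        res = p.residues[pos - 1]
        if res.code == "C":
            residues.append(Residue("S"))
            replaced.append(pos)
        else:
            residues.append(Residue(res.code, res.modification))
    design = ModifiedPeptide(
        name=f"{p.name}[{start}-{end}]",
        residues=tuple(residues),
        c_terminal_amide=False,
        disulfide_pairs=(),
    )
    return AssayPeptideDesign(
        peptide=design, window=(start, end), cys_replaced=tuple(replaced), clipped=clipped
    )
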