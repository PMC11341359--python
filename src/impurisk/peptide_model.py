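"""Peptide sequences with side-chain modifications, masses, and edits.

The active pharmaceutical ingredient (API) of a synthetic peptide drug and
its synthesis/degradation impurities are represented as ordered lists of
residues, each optionally carrying a side-chain or backbone modification
(acetylation, deamidation, oxidation, racemization).  Impurities are most
naturally specified as edits on the API sequence (a deletion, an insertion,
a substitution, or a side-chain modification at a 1-based position); this
module applies such edits, derives the impurity name from the edit, computes
average molecular masses (with corrections for C-terminal amidation and
disulfide bridges), converts mass concentrations to molar ones, and maps
modified residues to natural analogs so that position-specific scoring
matrices defined over the 20 canonical amino acids can be applied.

Positions are 1-based throughout, matching the residue numbering used when
naming impurities (e.g. "deletion of threonine 21" is DES-THR21).
"""

from __future__ import annotations

import csv
import itertools
import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

CANONICAL = "ACDEFGHIKLMNPQRSTVWY"

THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

#: Controlled vocabulary of residue modifications: tag -> (allowed codes, mass delta Da)
MODIFICATIONS = {
    "none": (set(CANONICAL), 0.0),
    "acetyl-K": ({"K"}, 42.0367),
    "deamidated-N": ({"N"}, 0.9847),
    "deamidated-Q": ({"Q"}, 0.9847),
    "D-isomer": (set(CANONICAL), 0.0),
    "oxidized-M": ({"M"}, 15.9994),
}

#: Deamidation converts the residue chemistry into that of a canonical residue.
DEAMIDATION_PRODUCT = {"deamidated-N": "D", "deamidated-Q": "E"}

WATER = 18.0153
AMIDE_DELTA = -0.9847      # C-terminal -OH -> -NH2
DISULFIDE_DELTA = -2.0159  # loss of two hydrogens per S-S bridge


class PeptideError(ValueError):
    """Invalid peptide, edit, or modification."""


def _data_path(name: str) -> Path:
    return Path(str(resources.files("impurisk").joinpath("data", name)))


def load_mass_table(path: Optional[Path] = None) -> dict[str, float]:
    """Average residue masses (Da) from a two-column TSV (code, mass)."""
    path = path or _data_path("average_masses.tsv")
    table: dict[str, float] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            table[row[0]] = float(row[1])
    missing = set(CANONICAL) - set(table)
    if missing:
        raise PeptideError(f"mass table missing residues: {sorted(missing)}")
    return table


_MASS_TABLE: Optional[dict[str, float]] = None


def mass_table() -> dict[str, float]:
    global _MASS_TABLE
    if _MASS_TABLE is None:
        _MASS_TABLE = load_mass_table()
    return _MASS_TABLE


@dataclass(frozen=True)
class Residue:
    code: str
    modification: str = "none"

    def __post_init__(self) -> None:
        if self.code not in CANONICAL:
            raise PeptideError(f"non-canonical residue code {self.code!r}")
        if self.modification not in MODIFICATIONS:
            raise PeptideError(f"unknown modification {self.modification!r}")
        allowed, _ = MODIFICATIONS[self.modification]
        if self.code not in allowed:
            raise PeptideError(
                f"modification {self.modification!r} not valid on {self.code!r}"
            )

    @property
    def mass(self) -> float:
        return mass_table()[self.code] + MODIFICATIONS[self.modification][1]


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide with optional terminal amidation and disulfide topology."""

    name: str
    residues: tuple[Residue, ...]
    c_terminal_amide: bool = False
    disulfide_pairs: tuple[tuple[int, int], ...] = ()
    relative_abundance_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise PeptideError("peptide must have at least one residue")
        seen: set[int] = set()
        for i, j in self.disulfide_pairs:
            for p in (i, j):
                if not 1 <= p <= len(self.residues):
                    raise PeptideError(f"disulfide position {p} out of range")
                if self.residues[p - 1].code != "C":
                    raise PeptideError(f"disulfide position {p} is not a cysteine")
                if p in seen:
                    raise PeptideError(f"position {p} in more than one disulfide")
                seen.add(p)
            if i == j:
                raise PeptideError("disulfide pair positions must be distinct")
        if self.relative_abundance_pct is not None and self.relative_abundance_pct <= 0:
            raise PeptideError("relative abundance must be positive")

    @classmethod
    def from_sequence(
        cls,
        name: str,
        sequence: str,
        *,
        c_terminal_amide: bool = False,
        disulfide_pairs: Sequence[tuple[int, int]] = (),
        relative_abundance_pct: Optional[float] = None,
        modifications: Optional[dict[int, str]] = None,
    ) -> "ModifiedPeptide":
        mods = modifications or {}
        residues = tuple(
            Residue(code, mods.get(pos, "none"))
            for pos, code in enumerate(sequence.upper(), start=1)
        )
        return cls(
            name=name,
            residues=residues,
            c_terminal_amide=c_terminal_amide,
            disulfide_pairs=tuple(tuple(p) for p in disulfide_pairs),
            relative_abundance_pct=relative_abundance_pct,
        )

    @property
    def sequence(self) -> str:
        return "".join(r.code for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_unmodified(self) -> bool:
        return all(r.modification == "none" for r in self.residues)


@dataclass(frozen=True)
class EditOperation:
    """A single difference of an impurity relative to the API.

    kind: deletion | insertion | substitution | side_chain_mod.
    position: 1-based index on the API (insertion allowed at length+1; the
    inserted residue occupies ``position`` and shifts the tail right).
    payload: residue code (insertion/substitution) or modification tag
    (side_chain_mod); deletions carry no payload.
    """

    kind: str
    position: int
    payload: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in {"deletion", "insertion", "substitution", "side_chain_mod"}:
            raise PeptideError(f"unknown edit kind {self.kind!r}")
        if self.kind == "deletion" and self.payload is not None:
            raise PeptideError("deletion carries no payload")
        if self.kind != "deletion" and not self.payload:
            raise PeptideError(f"{self.kind} requires a payload")
        if self.position < 1:
            raise PeptideError("position must be >= 1")


def _edit_name(api: ModifiedPeptide, edit: EditOperation) -> str:
    if edit.kind == "deletion":
        code = api.residues[edit.position - 1].code
        return f"DES-{THREE_LETTER[code]}{edit.position}_{api.name}"
    if edit.kind == "insertion":
        return f"ENDO-{THREE_LETTER[edit.payload]}{edit.position}_{api.name}"
    if edit.kind == "substitution":
        old = api.residues[edit.position - 1].code
        return f"{old}{edit.position}{edit.payload}_{api.name}"
    tag = edit.payload.upper().replace("ACETYL-K", "LYS-AC").replace("OXIDIZED-M", "MET-OX")
    if edit.payload == "acetyl-K":
        return f"LYS-AC{edit.position}_{api.name}"
    return f"{tag}{edit.position}_{api.name}"


def apply_edit(api: ModifiedPeptide, edit: EditOperation) -> ModifiedPeptide:
    """Apply one edit to the API, re-indexing disulfides across indels."""
    n = len(api)
    max_pos = n + 1 if edit.kind == "insertion" else n
    if edit.position > max_pos:
        raise PeptideError(f"position {edit.position} out of range for {edit.kind}")
    residues = list(api.residues)
    pairs = list(api.disulfide_pairs)
    pos = edit.position
    if edit.kind == "deletion":
        pairs = [
            tuple(p - 1 if p > pos else p for p in pair)
            for pair in pairs
            if pos not in pair
        ]
        del residues[pos - 1]
        if not residues:
            raise PeptideError("deletion would leave an empty peptide")
    elif edit.kind == "insertion":
        residues.insert(pos - 1, Residue(edit.payload))
        pairs = [tuple(p + 1 if p >= pos else p for p in pair) for pair in pairs]
    elif edit.kind == "substitution":
        old = residues[pos - 1]
        residues[pos - 1] = Residue(edit.payload)
        if old.code == "C" and edit.payload != "C":
            pairs = [pair for pair in pairs if pos not in pair]
    else:  # side_chain_mod
        old = residues[pos - 1]
        residues[pos - 1] = Residue(old.code, edit.payload)  # validates compatibility
    return ModifiedPeptide(
        name=_edit_name(api, edit),
        residues=tuple(residues),
        c_terminal_amide=api.c_terminal_amide,
        disulfide_pairs=tuple(tuple(p) for p in pairs),
        relative_abundance_pct=api.relative_abundance_pct,
    )


def average_mass(p: ModifiedPeptide) -> float:
    """Average molecular mass in Da, including terminal and bridge corrections."""
    total = sum(r.mass for r in p.residues) + WATER
    if p.c_terminal_amide:
        total += AMIDE_DELTA
    total += DISULFIDE_DELTA * len(p.disulfide_pairs)
    return total


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (5.75 -> 5.8), unlike banker's rounding."""
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def molar_concentration(mass_conc_ug_ml: float, p: ModifiedPeptide) -> float:
    """µM concentration of a mass_conc µg/mL solution, to one decimal."""
    if mass_conc_ug_ml <= 0:
        raise PeptideError("mass concentration must be positive")
    return round_half_away(mass_conc_ug_ml / average_mass(p) * 1000.0, 1)


@dataclass(frozen=True)
class SubstitutionTable:
    """Natural-analog mapping for modified residues, tag -> ordered analogs."""

    mapping: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "acetyl-K": ("Q",),
            "D-isomer": (),   # same letter: resolved per-residue
            "oxidized-M": ("M",),
        }
    )

    def __post_init__(self) -> None:
        for tag, analogs in self.mapping.items():
            if tag not in MODIFICATIONS:
                raise PeptideError(f"unknown modification tag {tag!r}")
            for code in analogs:
                if code not in CANONICAL:
                    raise PeptideError(f"non-canonical analog {code!r} for {tag!r}")

    def analogs(self, residue: Residue) -> tuple[str, ...]:
        tag = residue.modification
        if tag == "none":
            return (residue.code,)
        if tag in DEAMIDATION_PRODUCT:
            return (DEAMIDATION_PRODUCT[tag],)
        if tag == "D-isomer":
            return (residue.code,)
        if tag not in self.mapping or not self.mapping[tag]:
            raise PeptideError(f"no natural analog listed for {tag!r}")
        return self.mapping[tag]

    @classmethod
    def from_tsv(cls, path: Path) -> "SubstitutionTable":
        mapping: dict[str, tuple[str, ...]] = {}
        with open(path) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                mapping[row[0]] = tuple(row[1].split(","))
        return cls(mapping=mapping)


def naturalize(
    p: ModifiedPeptide,
    table: Optional[SubstitutionTable] = None,
    cap: int = 64,
) -> list[tuple[str, tuple[tuple[int, str, str], ...]]]:
    """Expand a modified peptide into natural-residue sequences for scanning.

    Returns one ``(sequence, provenance)`` per combination of analogs, where
    provenance lists ``(position, modification, analog)`` for every
    substituted position.  Unmodified peptides return themselves with empty
    provenance.
    """
    table = table or SubstitutionTable()
    options: list[tuple[str, ...]] = []
    mod_positions: list[int] = []
    for pos, res in enumerate(p.residues, start=1):
        opts = table.analogs(res)
        options.append(opts)
        if res.modification != "none":
            mod_positions.append(pos)
    n_combos = math.prod(len(o) for o in options)
    if n_combos > cap:
        raise PeptideError(f"{n_combos} analog combinations exceed cap {cap}")
    out = []
    for combo in itertools.product(*options):
        seq = "".join(combo)
        prov = tuple(
            (pos, p.residues[pos - 1].modification, combo[pos - 1])
            for pos in mod_positions
        )
        out.append((seq, prov))
    return out


def percent_identity(a: ModifiedPeptide | str, b: ModifiedPeptide | str) -> float:
    """Positional percent identity of two equal-length sequences."""
    sa = a if isinstance(a, str) else a.sequence
    sb = b if isinstance(b, str) else b.sequence
    if not sa or not sb:
        raise PeptideError("empty sequence")
    if len(sa) != len(sb):
        raise PeptideError(
            "sequences differ in length; align them first (see impurity_compare)"
        )
    same = sum(x == y for x, y in zip(sa, sb))
    return 100.0 * same / len(sa)


# ---------------------------------------------------------------------------
# External formats

def read_fasta(path: Path) -> list[ModifiedPeptide]:
    from Bio import SeqIO

    return [
        ModifiedPeptide.from_sequence(rec.id, str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(peptides: Iterable[ModifiedPeptide], path: Path) -> None:
    with open(path, "w") as fh:
        for p in peptides:
            fh.write(f">{p.name}\n{p.sequence}\n")


def load_impurity_spec(path: Path, api: ModifiedPeptide) -> list[ModifiedPeptide]:
    """Impurity JSON dialect: [{name?, edits:[{kind,position,payload?}], abundance_pct?}]."""
    with open(path) as fh:
        entries = json.load(fh)
    out = []
    for entry in entries:
        pep = api
        for e in entry["edits"]:
            pep = apply_edit(pep, EditOperation(e["kind"], e["position"], e.get("payload")))
        name = entry.get("name", pep.name)
        pep = replace(
            pep,
            name=name,
            relative_abundance_pct=entry.get("abundance_pct"),
        )
        out.append(pep)
    return out
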