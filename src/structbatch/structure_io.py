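"""Parse, merge, select from and write PDB-format structures.

The in-memory model is a light hierarchy Structure -> Model -> Chain ->
Residue -> Atom tailored to batch analysis: author residue numbering is kept
verbatim, alternate locations are resolved at parse time (highest occupancy,
ties broken by the lexicographically first alt-loc id) and appended structures
retain their own structure ids so a Selection can address (structure, chain).

Parsing is delegated to gemmi's fixed-column PDB reader; writing is a minimal
v3.3 ATOM/HETATM/MODEL/TER/END formatter so that round-trips preserve
coordinates at the format's 3-decimal precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom", "Residue", "Chain", "Model", "Structure", "Selection",
    "PDBParseError", "parse_pdb", "parse_pdb_file", "write_pdb",
    "append_structures", "extract_sequence", "resolve_selection",
    "THREE_TO_ONE", "ONE_TO_THREE",
]

# Standard 20 amino acids only; everything else (MSE, ligands, ...) -> "X".
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

WATER_NAMES = {"HOH", "WAT", "DOD"}


class PDBParseError(ValueError):
    """Raised when PDB text cannot be interpreted."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coord: np.ndarray
    alt_loc: str = ""
    is_hetero: bool = False
    occupancy: float = 1.0
    b_factor: float = 0.0
    charge: float = 0.0

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coord must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    number: int
    type: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""
    structure_id: str = ""

    @property
    def key(self) -> tuple:
        """Identity within the whole (possibly appended) container."""
        return (self.structure_id, self.chain_id, self.number, self.insertion_code)

    @property
    def label(self) -> str:
        ic = self.insertion_code.strip()
        return f"{self.structure_id}_{self.chain_id}_{self.number}{ic}_{self.type}"

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    @property
    def is_amino(self) -> bool:
        return self.type in THREE_TO_ONE

    @property
    def is_water(self) -> bool:
        return self.type in WATER_NAMES

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.type, "X")


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)
    structure_id: str = ""

    def residue(self, number: int, insertion_code: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.number == number and r.insertion_code.strip() == insertion_code.strip():
                return r
        return None

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Model:
    chains: list[Chain] = field(default_factory=list)

    def chain(self, chain_id: str, structure_id: Optional[str] = None) -> Optional[Chain]:
        for ch in self.chains:
            if ch.id == chain_id and (structure_id is None or ch.structure_id == structure_id):
                return ch
        return None

    def __iter__(self) -> Iterator[Chain]:
        return iter(self.chains)


@dataclass
class Structure:
    id: str
    models: list[Model] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    @property
    def structure_ids(self) -> list[str]:
        seen: list[str] = []
        for ch in self.models[0].chains:
            if ch.structure_id not in seen:
                seen.append(ch.structure_id)
        return seen

    def model(self, index: int = 0) -> Model:
        return self.models[index]

    def chain(self, chain_id: str, structure_id: Optional[str] = None,
              model: int = 0) -> Chain:
        ch = self.models[model].chain(chain_id, structure_id)
        if ch is None:
            avail = ", ".join(sorted({c.id for c in self.models[model].chains}))
            raise KeyError(
                f"chain {chain_id!r} not found in structure {self.id!r}; "
                f"available chains: {avail}")
        return ch

    def residues(self, model: int = 0) -> list[Residue]:
        out: list[Residue] = []
        for ch in self.models[model].chains:
            out.extend(ch.residues)
        return out

    def atoms(self, model: int = 0) -> list[Atom]:
        return [a for r in self.residues(model) for a in r.atoms]

    def copy(self) -> "Structure":
        import copy as _copy
        return _copy.deepcopy(self)


@dataclass
class Selection:
    """Addresses a residue subset; an all-default Selection is empty.

    residue_ranges are inclusive [start, end] author-numbering intervals.
    Stating a chain with no ranges selects the whole chain.
    """
    structure_id: Optional[str] = None
    chain_id: Optional[str] = None
    residue_ranges: Sequence[tuple[int, int]] = ()
    residue_types: Optional[Sequence[str]] = None

    def __post_init__(self):
        norm = []
        for lo, hi in self.residue_ranges:
            if lo > hi:
                lo, hi = hi, lo
            norm.append((int(lo), int(hi)))
        self.residue_ranges = tuple(norm)

    @property
    def is_empty(self) -> bool:
        return (self.structure_id is None and self.chain_id is None
                and not self.residue_ranges and self.residue_types is None)


# ---------------------------------------------------------------------------
# parsing

def _validate_lines(text: str) -> None:
    n_coord = 0
    for i, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            n_coord += 1
            if len(line) < 54:
                raise PDBParseError(f"line {i}: truncated coordinate record")
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except ValueError:
                raise PDBParseError(f"line {i}: malformed coordinate fields") from None
    if n_coord == 0:
        raise PDBParseError("input contains no ATOM or HETATM records")


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one atom per name: highest occupancy, tie -> first alt-loc id."""
    by_name: dict[str, Atom] = {}
    order: list[str] = []
    for a in atoms:
        prev = by_name.get(a.name)
        if prev is None:
            by_name[a.name] = a
            order.append(a.name)
        elif a.occupancy > prev.occupancy or (
                a.occupancy == prev.occupancy
                and (a.alt_loc or "~") < (prev.alt_loc or "~")):
            by_name[a.name] = a
    return [by_name[n] for n in order]


def _convert_gemmi(st: gemmi.Structure, sid: str) -> Structure:
    models: list[Model] = []
    for gm in st:
        chains: dict[str, Chain] = {}
        for gch in gm:
            ch = chains.setdefault(gch.name, Chain(id=gch.name, structure_id=sid))
            for gr in gch:
                atoms = []
                for ga in gr:
                    alt = ga.altloc if ga.altloc not in ("\x00", " ") else ""
                    atoms.append(Atom(
                        serial=ga.serial, name=ga.name,
                        element=ga.element.name or "X",
                        coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        alt_loc=alt, is_hetero=(gr.het_flag == "H"),
                        occupancy=float(ga.occ), b_factor=float(ga.b_iso),
                        charge=float(ga.charge)))
                atoms = _resolve_altlocs(atoms)
                icode = gr.seqid.icode.strip()
                existing = ch.residue(gr.seqid.num, icode)
                if existing is not None and existing.type == gr.name:
                    existing.atoms.extend(atoms)
                else:
                    ch.residues.append(Residue(
                        chain_id=gch.name, number=gr.seqid.num, type=gr.name,
                        atoms=atoms, insertion_code=icode, structure_id=sid))
        models.append(Model(chains=list(chains.values())))
    if not models:
        raise PDBParseError("no models parsed")
    return Structure(id=sid, models=models, provenance=[sid])


def _split_concatenated(text: str) -> list[str]:
    """Split a concatenated multi-entry PDB file on END records."""
    segments, cur = [], []
    for line in text.splitlines():
        if line[:6].strip() == "END":
            if any(l[:6].strip() in ("ATOM", "HETATM") for l in cur):
                segments.append("\n".join(cur) + "\n")
            cur = []
        else:
            cur.append(line)
    if any(l[:6].strip() in ("ATOM", "HETATM") for l in cur):
        segments.append("\n".join(cur) + "\n")
    return segments


def parse_pdb(text: str, id: str = "struct") -> Structure:
    """Parse PDB-format text into a Structure.

    MODEL/ENDMDL records become models; a concatenated file (several entries
    separated by END) becomes a single appended container whose parts are
    addressable as id_1, id_2, ... Highest-occupancy alternate locations are
    retained.
    """
    _validate_lines(text)
    segments = _split_concatenated(text)
    if len(segments) <= 1:
        return _convert_gemmi(gemmi.read_pdb_string(text), id)
    parts = [_convert_gemmi(gemmi.read_pdb_string(seg), f"{id}_{i + 1}")
             for i, seg in enumerate(segments)]
    merged = append_structures(parts)
    merged.id = id
    return merged


def parse_pdb_file(path: str, id: Optional[str] = None) -> Structure:
    import os
    with open(path) as fh:
        text = fh.read()
    if id is None:
        id = os.path.splitext(os.path.basename(path))[0]
    st = parse_pdb(text, id)
    st.provenance = [str(path)]
    return st


# ---------------------------------------------------------------------------
# writing

def _format_atom_line(a: Atom, r: Residue, serial: int) -> str:
    rec = "HETATM" if a.is_hetero else "ATOM  "
    name = a.name
    # standard alignment: element symbols of one letter start in column 14
    if len(name) < 4 and len(a.element) == 1:
        name = " " + name
    name = name.ljust(4)[:4]
    icode = (r.insertion_code or " ")[:1]
    return (f"{rec}{serial:5d} {name}{(a.alt_loc or ' ')[:1]}"
            f"{r.type:>3s} {r.chain_id[:1]}{r.number:4d}{icode}   "
            f"{a.coord[0]:8.3f}{a.coord[1]:8.3f}{a.coord[2]:8.3f}"
            f"{a.occupancy:6.2f}{a.b_factor:6.2f}          "
            f"{a.element:>2s}")


def write_pdb(structure: Structure) -> str:
    """Serialize to fixed-column PDB text (v3.3 subset)."""
    lines: list[str] = []
    multi = len(structure.models) > 1
    for mi, model in enumerate(structure.models, start=1):
        if multi:
            lines.append(f"MODEL     {mi:4d}")
        serial = 0
        for ch in model.chains:
            last_polymer = None
            for r in ch.residues:
                for a in r.atoms:
                    serial += 1
                    lines.append(_format_atom_line(a, r, serial))
                if r.is_amino:
                    last_polymer = r
            if last_polymer is not None:
                serial += 1
                lines.append(f"TER   {serial:5d}      {last_polymer.type:>3s} "
                             f"{ch.id[:1]}{last_polymer.number:4d}")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_pdb_file(structure: Structure, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(write_pdb(structure))


# ---------------------------------------------------------------------------
# merging / selection / sequence

def append_structures(structures: Sequence[Structure]) -> Structure:
    """Merge structures into one container, keeping per-structure identity.

    Coordinates are untouched; chains carry their originating structure id so
    selections can address (structure, chain). Model 1 of each input is used
    for inputs beyond the first; the first input contributes all its models.
    """
    if not structures:
        raise ValueError("append_structures requires at least one structure")
    ids = [s.id for s in structures]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate structure ids in append: {ids}")
    if len(structures) == 1:
        return structures[0].copy()
    first = structures[0].copy()
    out = Structure(id="+".join(ids), models=first.models,
                    provenance=[p for s in structures for p in s.provenance])
    for s in structures[1:]:
        for ch in s.copy().models[0].chains:
            out.models[0].chains.append(ch)
    return out


def extract_sequence(structure: Structure, chain_id: str,
                     structure_id: Optional[str] = None,
                     model: int = 0) -> tuple[str, list[int]]:
    """One-letter sequence of a chain plus the parallel residue-number list.

    Standard amino acids map to their one-letter code, non-standard polymer
    residues to "X"; HETATM-only residues (ligands, waters) are excluded.
    """
    ch = structure.chain(chain_id, structure_id, model)
    seq, numbers = [], []
    for r in ch.residues:
        if r.is_water:
            continue
        if not r.is_amino and all(a.is_hetero for a in r.atoms):
            continue
        seq.append(r.one_letter)
        numbers.append(r.number)
    return "".join(seq), numbers


def resolve_selection(structure: Structure, selection: Selection,
                      model: int = 0) -> list[Residue]:
    """Residues matching every stated criterion, in chain order then residue
    order; an all-default Selection resolves to zero residues."""
    if selection.is_empty:
        return []
    out: list[Residue] = []
    for ch in structure.models[model].chains:
        if selection.structure_id is not None and ch.structure_id != selection.structure_id:
            continue
        if selection.chain_id is not None and ch.id != selection.chain_id:
            continue
        for r in ch.residues:
            if selection.residue_ranges and not any(
                    lo <= r.number <= hi for lo, hi in selection.residue_ranges):
                continue
            if selection.residue_types is not None and r.type not in selection.residue_types:
                continue
            out.append(r)
    return out
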