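"""Residue-level chemical knowledge: radii, charged groups, hydrogen-bond
donors/acceptors, aromatic rings, chi-angle definitions, a compact rotamer
library and ideal side-chain construction.

Ideal internal side-chain geometry (bond lengths, angles, fixed dihedrals) is
derived once per residue type from the chemical-component ideal coordinates
bundled with biotite, converted into a NeRF recipe rooted on the backbone
N/CA/C triad. Chi-angle dihedrals stay free parameters; branch atoms ride on
the nearest chi bond with their ideal offset, so any chi combination can be
realised on any backbone.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np

from ._geom import dihedral, angle_deg, place_atom

__all__ = [
    "VDW_RADII", "vdw_radius", "HBOND_DONORS", "HBOND_ACCEPTORS",
    "cation_atoms", "anion_atoms", "aromatic_rings", "CHI_ATOMS",
    "ROTAMERS", "build_side_chain", "side_chain_atom_names",
]

VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}
DEFAULT_VDW = 1.70


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


# Heavy-atom H-bond chemistry (hydrogens are not modelled; distance-only
# criteria are applied between donor and acceptor heavy atoms).
_SIDE_DONORS = {
    "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"], "CYS": ["SG"],
    "ASN": ["ND2"], "GLN": ["NE2"], "HIS": ["ND1", "NE2"],
    "LYS": ["NZ"], "ARG": ["NE", "NH1", "NH2"], "TRP": ["NE1"],
}
_SIDE_ACCEPTORS = {
    "ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"], "ASN": ["OD1"],
    "GLN": ["OE1"], "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"],
    "HIS": ["ND1", "NE2"], "MET": ["SD"], "CYS": ["SG"],
}

HBOND_DONORS = dict(_SIDE_DONORS)
HBOND_ACCEPTORS = dict(_SIDE_ACCEPTORS)


def donor_atoms(residue) -> list:
    out = []
    for a in residue.heavy_atoms():
        if residue.is_amino and a.name == "N" and residue.type != "PRO":
            out.append(a)
        elif a.name in _SIDE_DONORS.get(residue.type, ()):
            out.append(a)
        elif residue.is_water and a.element == "O":
            out.append(a)
    return out


def acceptor_atoms(residue) -> list:
    out = []
    for a in residue.heavy_atoms():
        if residue.is_amino and a.name in ("O", "OXT"):
            out.append(a)
        elif a.name in _SIDE_ACCEPTORS.get(residue.type, ()):
            out.append(a)
        elif residue.is_water and a.element == "O":
            out.append(a)
    return out


_CATION = {"LYS": ["NZ"], "ARG": ["NE", "NH1", "NH2"]}
_CATION_HIS = {"HIS": ["ND1", "NE2"]}
_ANION = {"ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"]}


def cation_atoms(residue, his_charged: bool = False) -> list:
    names = list(_CATION.get(residue.type, ()))
    if his_charged:
        names += _CATION_HIS.get(residue.type, ())
    return [a for a in residue.heavy_atoms() if a.name in names]


def anion_atoms(residue) -> list:
    names = list(_ANION.get(residue.type, ()))
    if residue.is_amino:
        names.append("OXT")
    return [a for a in residue.heavy_atoms() if a.name in names]


# Aromatic ring definitions; Trp contributes two centroids.
_RINGS = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
    "TRP": [["CG", "CD1", "NE1", "CE2", "CD2"],
            ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]],
}


def aromatic_rings(residue) -> list[tuple[str, np.ndarray]]:
    """(pseudo-atom name, centroid) for each complete aromatic ring."""
    out = []
    for k, names in enumerate(_RINGS.get(residue.type, ())):
        atoms = [residue.atom(n) for n in names]
        if any(a is None for a in atoms):
            continue
        centroid = np.mean([a.coord for a in atoms], axis=0)
        out.append((f"RING{len(names)}", centroid))
    return out


# Standard chi-angle atom quadruplets.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "SER": [("N", "CA", "CB", "OG")],
    "CYS": [("N", "CA", "CB", "SG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
}

# Compact rotamer library: canonical chi combinations with prior weights.
# Weights are rough gas-phase/PDB plausibilities; they enter scoring only as
# a -log(weight) prior, so relative order matters more than exact values.
ROTAMERS: dict[str, list[tuple[tuple[float, ...], float]]] = {
    "SER": [((-65.0,), 0.48), ((178.0,), 0.30), ((64.0,), 0.22)],
    "CYS": [((-65.0,), 0.50), ((180.0,), 0.30), ((60.0,), 0.20)],
    "THR": [((-60.0,), 0.50), ((60.0,), 0.40), ((180.0,), 0.10)],
    "VAL": [((175.0,), 0.60), ((-60.0,), 0.25), ((60.0,), 0.15)],
    "ILE": [((-60.0, 170.0), 0.60), ((-60.0, -60.0), 0.15),
            ((180.0, 165.0), 0.15), ((60.0, 170.0), 0.10)],
    "LEU": [((-65.0, 175.0), 0.60), ((180.0, 65.0), 0.30),
            ((-85.0, 65.0), 0.05), ((180.0, 180.0), 0.05)],
    "MET": [((-65.0, -65.0, -70.0), 0.30), ((-65.0, 180.0, 75.0), 0.20),
            ((180.0, 180.0, 75.0), 0.20), ((180.0, 180.0, 180.0), 0.15),
            ((-65.0, 180.0, 180.0), 0.15)],
    "PHE": [((-65.0, 90.0), 0.50), ((180.0, 80.0), 0.35), ((60.0, 90.0), 0.15)],
    "TYR": [((-65.0, 90.0), 0.50), ((180.0, 80.0), 0.35), ((60.0, 90.0), 0.15)],
    "TRP": [((-65.0, 95.0), 0.30), ((-65.0, -90.0), 0.25),
            ((180.0, -105.0), 0.20), ((180.0, 90.0), 0.15),
            ((60.0, -90.0), 0.10)],
    "HIS": [((-65.0, -70.0), 0.35), ((-65.0, 80.0), 0.25), ((180.0, 60.0), 0.20),
            ((180.0, -70.0), 0.15), ((60.0, -75.0), 0.05)],
    "ASP": [((-70.0, -15.0), 0.50), ((180.0, 15.0), 0.30), ((60.0, 0.0), 0.20)],
    "ASN": [((-65.0, -40.0), 0.40), ((180.0, -75.0), 0.25),
            ((-65.0, 120.0), 0.20), ((60.0, 0.0), 0.15)],
    "GLU": [((-65.0, 180.0, -10.0), 0.35), ((180.0, 180.0, 0.0), 0.30),
            ((-65.0, -65.0, -40.0), 0.20), ((180.0, 65.0, 10.0), 0.15)],
    "GLN": [((-65.0, 180.0, -25.0), 0.35), ((180.0, 180.0, 0.0), 0.30),
            ((-65.0, -65.0, -40.0), 0.20), ((180.0, 65.0, 90.0), 0.15)],
    "LYS": [((-65.0, 180.0, 180.0, 180.0), 0.40),
            ((180.0, 180.0, 180.0, 180.0), 0.30),
            ((-65.0, -65.0, 180.0, 180.0), 0.15),
            ((180.0, 60.0, 180.0, 180.0), 0.10),
            ((60.0, 180.0, 180.0, 180.0), 0.05)],
    "ARG": [((-65.0, 180.0, 180.0, 180.0), 0.35),
            ((180.0, 180.0, 180.0, 180.0), 0.25),
            ((-65.0, -65.0, 180.0, 180.0), 0.15),
            ((180.0, 65.0, 65.0, 85.0), 0.15),
            ((60.0, 180.0, 180.0, 180.0), 0.10)],
    "ALA": [((), 1.0)],
    "GLY": [((), 1.0)],
    "PRO": [((), 1.0)],
}

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class _TemplateAtom:
    name: str
    element: str
    frame: tuple[str, str, str]   # (a, b, c): dihedral a-b-c-self
    bond: float
    theta: float
    dihedral: float               # ideal value, or offset from the chi
    chi_index: Optional[int]      # 0-based chi riding this atom's b-c bond


@lru_cache(maxsize=None)
def _side_chain_template(restype: str) -> tuple[_TemplateAtom, ...]:
    """NeRF recipe for the heavy side-chain atoms of a residue type, derived
    from the chemical component dictionary's ideal coordinates."""
    import biotite.structure.info as bsinfo

    arr = bsinfo.residue(restype)
    names = [str(n) for n in arr.atom_name]
    coords = {n: arr.coord[names.index(n)].astype(float) for n in names}
    heavy = [n for n, e in zip(names, arr.element) if e != "H"]
    adj: dict[str, set[str]] = {n: set() for n in names}
    for i, j, _ in arr.bonds.as_array():
        adj[names[i]].add(names[j])
        adj[names[j]].add(names[i])

    chi_bonds = {}
    for k, (_, b, c, _) in enumerate(CHI_ATOMS.get(restype, ())):
        chi_bonds[(b, c)] = k
    chi_ideal = {k: dihedral(*(coords[x] for x in quad))
                 for k, quad in enumerate(CHI_ATOMS.get(restype, ()))}

    # BFS over the side chain rooted at CA; CB uses the backbone triad frame.
    parent = {"CB": "CA", "CA": None}
    order: list[str] = []
    queue = ["CB"] if "CB" in coords else []
    seen = {"CA", "N", "C", "CB"}
    while queue:
        cur = queue.pop(0)
        order.append(cur)
        for nb in sorted(adj[cur]):
            if nb in seen or nb not in heavy or nb in _BACKBONE:
                continue
            # PRO ring: CD bonds back to N; keep tree acyclic
            seen.add(nb)
            parent[nb] = cur
            queue.append(nb)

    out = []
    elem = {n: str(e) for n, e in zip(names, arr.element)}
    for atom in order:
        c = parent[atom]
        if atom == "CB":
            a, b = "C", "N"
        else:
            b = parent[c]
            a = parent[b] if parent[b] is not None else ("N" if b == "CB" else "C")
            if b == "CB" and c != "CB":
                a = "CA"
            if b == "CA":
                a = "N"
        dih = dihedral(coords[a], coords[b], coords[c], coords[atom])
        chi_index = chi_bonds.get((b, c))
        if chi_index is not None:
            dih = dih - chi_ideal[chi_index]   # offset relative to the chi
        out.append(_TemplateAtom(
            name=atom, element=elem[atom], frame=(a, b, c),
            bond=float(np.linalg.norm(coords[atom] - coords[c])),
            theta=angle_deg(coords[b], coords[c], coords[atom]),
            dihedral=dih, chi_index=chi_index))
    return tuple(out)


def side_chain_atom_names(restype: str) -> list[str]:
    if restype == "GLY":
        return []
    return [t.name for t in _side_chain_template(restype)]


def n_chi(restype: str) -> int:
    return len(CHI_ATOMS.get(restype, ()))


def build_side_chain(n: np.ndarray, ca: np.ndarray, c: np.ndarray,
                     restype: str,
                     chis: Sequence[float] = ()) -> list[tuple[str, str, np.ndarray]]:
    """Build heavy side-chain atoms (incl. CB) on the given backbone triad.

    Returns (atom name, element, coordinate) tuples. `chis` supplies the
    free chi angles in degrees; unspecified chis fall back to the ideal
    template values.
    """
    if restype == "GLY":
        return []
    template = _side_chain_template(restype)
    placed = {"N": np.asarray(n, float), "CA": np.asarray(ca, float),
              "C": np.asarray(c, float)}
    chis = list(chis)
    out = []
    for t in template:
        dih = t.dihedral
        if t.chi_index is not None:
            if t.chi_index < len(chis):
                dih = t.dihedral + chis[t.chi_index]
            else:
                dih = t.dihedral + _ideal_chi(restype, t.chi_index)
        a, b, cc = (placed[x] for x in t.frame)
        pos = place_atom(a, b, cc, t.bond, t.theta, dih)
        placed[t.name] = pos
        out.append((t.name, t.element, pos))
    return out


@lru_cache(maxsize=None)
def _ideal_chi(restype: str, k: int) -> float:
    import biotite.structure.info as bsinfo
    arr = bsinfo.residue(restype)
    names = list(arr.atom_name)
    coords = {nm: arr.coord[names.index(nm)].astype(float) for nm in names}
    return dihedral(*(coords[x] for x in CHI_ATOMS[restype][k]))
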