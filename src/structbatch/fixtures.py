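"""Generators for synthetic structures with exactly known geometry.

Every analysis module in this package is testable offline against structures
built here: ideal helices and strands grown from backbone dihedrals, Cn rings
and helical stacks with exact construction symmetry, two-chain interfaces
engineered so that each requested non-covalent interaction exists at a
distance safely inside its threshold and nothing else does, and seeded
random coils as negative controls.

All builders are deterministic: the seed (where one is accepted) fully
determines the output. Geometry guarantees are stated per builder and are
verified in the test suite by direct distance measurement, independently of
the analysis modules.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from ._geom import place_atom, rotation_about_axis, unit
from .chemistry import build_side_chain, aromatic_rings
from .structure_io import (Atom, Chain, Model, Residue, Structure,
                           ONE_TO_THREE)

__all__ = [
    "build_peptide", "build_helix", "build_strand", "build_coil",
    "build_cn_ring", "build_helical_stack", "build_interface_pair",
    "build_ligand_complex", "build_synthetic_binding_interface",
    "build_synthetic_c2_domain",
]

# ideal backbone internal coordinates (Engh/Huber-like)
_N_CA, _CA_C, _C_N, _C_O = 1.458, 1.525, 1.329, 1.231
_ANG_C_N_CA, _ANG_N_CA_C, _ANG_CA_C_N, _ANG_CA_C_O = 121.7, 111.2, 116.2, 120.8


def _residue(chain_id: str, number: int, rtype: str, atoms, sid: str = "") -> Residue:
    return Residue(chain_id=chain_id, number=number, type=rtype,
                   atoms=atoms, structure_id=sid)


def _mk_atom(serial: int, name: str, element: str, coord,
             hetero: bool = False) -> Atom:
    return Atom(serial=serial, name=name, element=element,
                coord=np.asarray(coord, float), is_hetero=hetero)


def build_peptide(sequence: str, phi_psi: Sequence[tuple[float, float]],
                  chain_id: str = "A", start_number: int = 1,
                  chis: Optional[Sequence[Sequence[float]]] = None,
                  id: str = "peptide", with_oxt: bool = False) -> Structure:
    """Grow a peptide from per-residue (phi, psi) with ideal geometry.

    `sequence` is one-letter; phi of the first residue and psi of the last
    are used only for side-chain-independent placement of O. `chis` optionally
    gives side-chain chi angles per residue (empty -> ideal template chis).
    """
    if len(phi_psi) != len(sequence):
        raise ValueError("phi_psi length must match sequence length")
    n_res = len(sequence)
    residues = []
    serial = 0
    prev_n = prev_ca = prev_c = None
    for i, aa in enumerate(sequence):
        rtype = ONE_TO_THREE.get(aa.upper())
        if rtype is None:
            raise ValueError(f"unknown one-letter residue code {aa!r}")
        phi, psi = phi_psi[i]
        if i == 0:
            n = np.zeros(3)
            ca = np.array([_N_CA, 0.0, 0.0])
            c = place_atom([0.0, 1.0, 0.0], n, ca, _CA_C, _ANG_N_CA_C, 150.0 + phi)
        else:
            psi_prev = phi_psi[i - 1][1]
            n = place_atom(prev_n, prev_ca, prev_c, _C_N, _ANG_CA_C_N, psi_prev)
            ca = place_atom(prev_ca, prev_c, n, _N_CA, _ANG_C_N_CA, 180.0)
            c = place_atom(prev_c, n, ca, _CA_C, _ANG_N_CA_C, phi)
        o = place_atom(n, ca, c, _C_O, _ANG_CA_C_O, psi + 180.0)
        atoms = []
        for nm, el, pos in (("N", "N", n), ("CA", "C", ca), ("C", "C", c),
                            ("O", "O", o)):
            serial += 1
            atoms.append(_mk_atom(serial, nm, el, pos))
        res_chis = () if chis is None else chis[i]
        for nm, el, pos in build_side_chain(n, ca, c, rtype, res_chis):
            serial += 1
            atoms.append(_mk_atom(serial, nm, el, pos))
        if with_oxt and i == n_res - 1:
            serial += 1
            atoms.append(_mk_atom(serial, "OXT", "O",
                                  place_atom(n, ca, c, 1.25, 117.0, psi)))
        residues.append(_residue(chain_id, start_number + i, rtype, atoms, id))
        prev_n, prev_ca, prev_c = n, ca, c
    ch = Chain(id=chain_id, residues=residues, structure_id=id)
    return Structure(id=id, models=[Model(chains=[ch])], provenance=["fixture"])


def build_helix(n: int, chain_id: str = "A", id: str = "helix",
                sequence: Optional[str] = None) -> Structure:
    """Ideal polyalanine alpha-helix (phi=-57, psi=-47), rise ~1.5 A/residue."""
    if n < 4:
        raise ValueError("a helix fixture needs at least 4 residues")
    seq = sequence if sequence is not None else "A" * n
    return build_peptide(seq, [(-57.0, -47.0)] * n, chain_id=chain_id, id=id)


def build_strand(n: int, chain_id: str = "A", id: str = "strand") -> Structure:
    """Extended beta-strand (phi=-120, psi=130) polyalanine."""
    if n < 3:
        raise ValueError("a strand fixture needs at least 3 residues")
    return build_peptide("A" * n, [(-120.0, 130.0)] * n, chain_id=chain_id, id=id)


def build_coil(n: int, seed: int = 0, chain_id: str = "A",
               id: str = "coil") -> Structure:
    """Seeded self-avoiding random coil: dihedrals drawn from broad basins,
    resampled whenever a new residue clashes (< 2.6 A) with earlier ones."""
    rng = np.random.default_rng(seed)
    phi_psi: list[tuple[float, float]] = []
    frames: list[tuple] = []        # (N, CA, C) per accepted residue
    atoms: list[np.ndarray] = []    # 5 heavy atoms per accepted residue
    attempts = 0
    stuck = 0
    clash_cut = 2.6

    def residue_atoms(phi: float, psi: float):
        if not frames:
            nn = np.zeros(3)
            ca = np.array([_N_CA, 0.0, 0.0])
            c = place_atom([0.0, 1.0, 0.0], nn, ca, _CA_C, _ANG_N_CA_C,
                           150.0 + phi)
        else:
            pn, pca, pc = frames[-1]
            psi_prev = phi_psi[-1][1]
            nn = place_atom(pn, pca, pc, _C_N, _ANG_CA_C_N, psi_prev)
            ca = place_atom(pca, pc, nn, _N_CA, _ANG_C_N_CA, 180.0)
            c = place_atom(pc, nn, ca, _CA_C, _ANG_N_CA_C, phi)
        o = place_atom(nn, ca, c, _C_O, _ANG_CA_C_O, psi + 180.0)
        cb = build_side_chain(nn, ca, c, "ALA")[0][2]
        return (nn, ca, c), np.array([nn, ca, c, o, cb])

    while len(phi_psi) < n:
        phi = float(rng.uniform(-160.0, -40.0))
        psi = float(rng.uniform(-180.0, 180.0))
        frame, new = residue_atoms(phi, psi)
        # skip the two preceding (bonded / turn-adjacent) residues
        old = atoms[:-2]
        ok = True
        if old:
            prev = np.concatenate(old)
            d2 = ((prev[:, None, :] - new[None, :, :]) ** 2).sum(axis=-1)
            ok = float(d2.min()) > clash_cut ** 2
        if ok:
            phi_psi.append((phi, psi))
            frames.append(frame)
            atoms.append(new)
            attempts = 0
            stuck = 0
        else:
            attempts += 1
            if attempts > 25 and phi_psi:
                # backtrack instead of accepting a clash; dig deeper each
                # time the same dead end recurs
                stuck += 1
                for _ in range(min(stuck, len(phi_psi))):
                    phi_psi.pop()
                    frames.pop()
                    atoms.pop()
                attempts = 0
    return build_peptide("A" * n, phi_psi, chain_id=chain_id, id=id)


def _min_interchain_distance(structure: Structure) -> float:
    chains = structure.models[0].chains
    best = math.inf
    for i in range(len(chains)):
        ci = np.array([a.coord for r in chains[i] for a in r.atoms])
        for j in range(i + 1, len(chains)):
            cj = np.array([a.coord for r in chains[j] for a in r.atoms])
            d = np.linalg.norm(ci[:, None, :] - cj[None, :, :], axis=-1).min()
            best = min(best, float(d))
    return best


_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _replicate(monomer: Structure, n: int, radius: float, twist: float,
               rise: float, jitter: float, seed: int, id: str) -> Structure:
    if n < 2:
        raise ValueError("need at least 2 subunits")
    if len(monomer.models[0].chains) != 1:
        raise ValueError("monomer must be single-chain")
    rng = np.random.default_rng(seed)
    base = monomer.copy()
    # centre the monomer, stand its principal axis up along z, then move it
    # out to the ring radius along +x so subunits are parallel cylinders
    coords = np.array([a.coord for a in base.atoms()])
    centre = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centre)
    axis = vt[0]
    cross = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(cross) > 1e-9:
        ang = math.degrees(math.atan2(float(np.linalg.norm(cross)),
                                      float(axis[2])))
        align = rotation_about_axis(cross, ang)
    else:
        align = np.eye(3)
    for a in base.atoms():
        a.coord = align @ (a.coord - centre)
    coords = np.array([a.coord for a in base.atoms()])
    shift = np.array([radius, 0.0, 0.0]) - coords.mean(axis=0)
    chains = []
    serial = 0
    for k in range(n):
        rot = rotation_about_axis([0, 0, 1], twist * k)
        dz = np.array([0.0, 0.0, rise * k])
        residues = []
        for r in base.models[0].chains[0].residues:
            atoms = []
            for a in r.atoms:
                serial += 1
                pos = rot @ (a.coord + shift) + dz
                if jitter > 0:
                    pos = pos + rng.normal(0.0, jitter, 3)
                atoms.append(_mk_atom(serial, a.name, a.element, pos))
            residues.append(_residue(_CHAIN_IDS[k], r.number, r.type, atoms, id))
        chains.append(Chain(id=_CHAIN_IDS[k], residues=residues, structure_id=id))
    st = Structure(id=id, models=[Model(chains=chains)], provenance=["fixture"])
    if _min_interchain_distance(st) < 1.5:
        raise ValueError(
            "subunits overlap (inter-subunit atoms closer than 1.5 A); "
            "use a larger radius")
    return st


def build_cn_ring(monomer: Structure, n: int, radius: float = 14.0,
                  jitter: float = 0.0, seed: int = 0,
                  id: str = "cn_ring") -> Structure:
    """n copies of the monomer related by exact 360/n-degree rotations about z.

    `jitter` adds seeded per-atom Gaussian noise (A) after replication, to
    emulate imperfect experimental symmetry.
    """
    return _replicate(monomer, n, radius, 360.0 / n, 0.0, jitter, seed, id)


def build_helical_stack(monomer: Structure, n: int, twist: float = 60.0,
                        rise: float = 5.0, radius: float = 12.0,
                        jitter: float = 0.0, seed: int = 0,
                        id: str = "helical_stack") -> Structure:
    """n copies related by a screw: `twist` degrees about z plus `rise` A
    along z per copy. Not invariant under any pure rotation when rise > 0."""
    if rise <= 0:
        raise ValueError("a helical stack needs rise > 0")
    return _replicate(monomer, n, radius, twist, rise, jitter, seed, id)


# ---------------------------------------------------------------------------
# engineered two-chain interfaces

def _frame_transform(atoms: list[Atom], p_from, u1_from, u2_from,
                     p_to, u1_to, u2_to) -> None:
    """Rigidly move atoms so p_from -> p_to, u1_from -> u1_to, and the
    component of u2 orthogonal to u1 maps correspondingly."""
    def frame(u1, u2):
        e1 = unit(np.asarray(u1, float))
        u2 = np.asarray(u2, float)
        e2 = unit(u2 - np.dot(u2, e1) * e1)
        return np.column_stack([e1, e2, np.cross(e1, e2)])
    rot = frame(u1_to, u2_to) @ frame(u1_from, u2_from).T
    p_from = np.asarray(p_from, float)
    p_to = np.asarray(p_to, float)
    for a in atoms:
        a.coord = rot @ (a.coord - p_from) + p_to


def _single(rtype3: str, chis=()) -> list[Atom]:
    one = {v: k for k, v in ONE_TO_THREE.items()}[rtype3]
    st = build_peptide(one, [(-120.0, 130.0)], chis=[chis])
    return st.models[0].chains[0].residues[0].atoms


def _coord(atoms: list[Atom], name: str) -> np.ndarray:
    for a in atoms:
        if a.name == name:
            return a.coord
    raise KeyError(name)


def _site_salt_bridge(offset):
    """Lys NZ 4.5 A from Asp OD1, side chains head-on; no atom pair of any
    other interaction class within its threshold."""
    la = _single("LYS", (180.0, 180.0, 180.0, 180.0))
    _frame_transform(la, _coord(la, "NZ"), _coord(la, "NZ") - _coord(la, "CE"),
                     [0, 0, 1], offset, [1, 0, 0], [0, 0, 1])
    da = _single("ASP", (180.0, 0.0))
    _frame_transform(da, _coord(da, "OD1"), _coord(da, "OD1") - _coord(da, "CG"),
                     [0, 0, 1], offset + np.array([4.5, 0, 0]), [-1, 0, 0], [0, 0, 1])
    return la, da, "LYS", "ASP"


def _site_hbond(offset):
    """Ser OG donor 3.2 A from Ser OG acceptor."""
    s1 = _single("SER", (180.0,))
    _frame_transform(s1, _coord(s1, "OG"), _coord(s1, "OG") - _coord(s1, "CB"),
                     [0, 0, 1], offset, [1, 0, 0], [0, 0, 1])
    s2 = _single("SER", (180.0,))
    _frame_transform(s2, _coord(s2, "OG"), _coord(s2, "OG") - _coord(s2, "CB"),
                     [0, 0, 1], offset + np.array([3.2, 0, 0]), [-1, 0, 0], [0, 0, 1])
    return s1, s2, "SER", "SER"


def _site_contact(offset):
    """Ala CB 3.8 A from Ala CB: a plain van-der-Waals contact only."""
    a1 = _single("ALA")
    _frame_transform(a1, _coord(a1, "CB"), _coord(a1, "CB") - _coord(a1, "CA"),
                     [0, 0, 1], offset, [1, 0, 0], [0, 0, 1])
    a2 = _single("ALA")
    _frame_transform(a2, _coord(a2, "CB"), _coord(a2, "CB") - _coord(a2, "CA"),
                     [0, 0, 1], offset + np.array([3.8, 0, 0]), [-1, 0, 0], [0, 0, 1])
    return a1, a2, "ALA", "ALA"


def _ring_frame(atoms: list[Atom], rtype: str):
    """Centroid and unit normal of a Phe/Tyr ring; the normal is oriented
    so the residue's CA lies on the positive-normal side."""
    ring_names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
    pts = np.array([_coord(atoms, n) for n in ring_names])
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    normal = vt[2]
    if float(np.dot(_coord(atoms, "CA") - centroid, normal)) < 0:
        normal = -normal
    return centroid, normal


def _site_pi_stacking(offset):
    """Two Phe rings stacked face-to-face, centroids 4.5 A apart; each
    backbone sits on the face turned away from the partner."""
    f1 = _single("PHE", (-65.0, 90.0))
    c1, n1 = _ring_frame(f1, "PHE")
    _frame_transform(f1, c1, n1, _coord(f1, "CA") - c1,
                     offset, [-1, 0, 0], [0, -1, 0])
    f2 = _single("PHE", (-65.0, 90.0))
    c2, n2 = _ring_frame(f2, "PHE")
    _frame_transform(f2, c2, n2, _coord(f2, "CA") - c2,
                     offset + np.array([4.5, 0, 0]), [1, 0, 0], [0, 1, 0])
    return f1, f2, "PHE", "PHE"


def _site_pi_cation(offset):
    """Lys NZ 4.8 A above a Phe ring face; the Phe backbone sits on the
    opposite face."""
    la = _single("LYS", (180.0, 180.0, 180.0, 180.0))
    _frame_transform(la, _coord(la, "NZ"), _coord(la, "NZ") - _coord(la, "CE"),
                     [0, 0, 1], offset, [1, 0, 0], [0, 0, 1])
    f = _single("PHE", (-65.0, 90.0))
    c, nrm = _ring_frame(f, "PHE")
    _frame_transform(f, c, nrm, _coord(f, "CA") - c,
                     offset + np.array([4.8, 0, 0]), [1, 0, 0], [0, 1, 0])
    return la, f, "LYS", "PHE"


def _site_halogen(offset):
    """A chloride-bearing hetero group 3.3 A from a backbone carbonyl O."""
    a1 = _single("ALA")
    _frame_transform(a1, _coord(a1, "O"), _coord(a1, "O") - _coord(a1, "C"),
                     [0, 0, 1], offset, [1, 0, 0], [0, 0, 1])
    lig = [_mk_atom(1, "CL1", "CL", offset + np.array([3.3, 0, 0]), hetero=True),
           _mk_atom(2, "C1", "C", offset + np.array([5.05, 0, 0]), hetero=True)]
    return a1, lig, "ALA", "LIG"


_SITES = {
    "salt bridge": _site_salt_bridge,
    "ionic": _site_salt_bridge,
    "hbond": _site_hbond,
    "contact": _site_contact,
    "pi-stacking": _site_pi_stacking,
    "pi_stacking": _site_pi_stacking,
    "pi-cation": _site_pi_cation,
    "pi_cation": _site_pi_cation,
    "halogen": _site_halogen,
}


def build_interface_pair(interactions_wanted: Sequence[str],
                         id: str = "interface") -> Structure:
    """Two chains (A, B) engineered so each requested interaction type exists
    exactly once, safely inside its threshold, and no unrequested specific
    interaction exists. Requested sites are spaced 25 A apart; with an empty
    request the chains are placed >= 12 A apart with no interactions at all.
    """
    unknown = [t for t in interactions_wanted if t not in _SITES]
    if unknown:
        raise ValueError(f"unknown interaction types: {unknown}; "
                         f"choose from {sorted(set(_SITES))}")
    chains = {"A": [], "B": []}
    serial = 0
    if not interactions_wanted:
        a1 = _single("GLY")
        b1 = _single("GLY")
        _frame_transform(b1, _coord(b1, "CA"), [1, 0, 0], [0, 0, 1],
                         np.array([20.0, 0.0, 0.0]), [1, 0, 0], [0, 0, 1])
        pairs = [(a1, b1, "GLY", "GLY")]
    else:
        pairs = []
        for i, t in enumerate(interactions_wanted):
            offset = np.array([0.0, 25.0 * i, 0.0])
            pairs.append(_SITES[t](offset))
    residues_a, residues_b = [], []
    for i, (atoms_a, atoms_b, type_a, type_b) in enumerate(pairs):
        for a in atoms_a:
            serial += 1
            a.serial = serial
        for a in atoms_b:
            serial += 1
            a.serial = serial
        residues_a.append(_residue("A", i + 1, type_a, atoms_a, id))
        residues_b.append(_residue("B", i + 1, type_b, atoms_b, id))
    ch_a = Chain(id="A", residues=residues_a, structure_id=id)
    ch_b = Chain(id="B", residues=residues_b, structure_id=id)
    return Structure(id=id, models=[Model(chains=[ch_a, ch_b])],
                     provenance=["fixture"])


def build_ligand_complex(near: float = 3.0, far: float = 9.0,
                         id: str = "ligand_complex") -> Structure:
    """Chain A with two Ala residues plus a HETATM ligand ("LIG") whose
    nearest heavy-atom distances to residues 1 and 2 are `near` and `far`."""
    r1 = _single("ALA")
    _frame_transform(r1, _coord(r1, "CB"), _coord(r1, "CB") - _coord(r1, "CA"),
                     [0, 0, 1], np.zeros(3), [1, 0, 0], [0, 0, 1])
    lig_pos = np.array([near, 0.0, 0.0])
    r2 = _single("ALA")
    _frame_transform(r2, _coord(r2, "CB"), _coord(r2, "CB") - _coord(r2, "CA"),
                     [0, 0, 1], lig_pos + np.array([far, 0.0, 0.0]),
                     [-1, 0, 0], [0, 0, 1])
    atoms = r1 + r2
    for i, a in enumerate(atoms):
        a.serial = i + 1
    res1 = _residue("A", 1, "ALA", r1, id)
    res2 = _residue("A", 2, "ALA", r2, id)
    lig = _residue("A", 101, "LIG",
                   [_mk_atom(len(atoms) + 1, "C1", "C", lig_pos, hetero=True)], id)
    ch = Chain(id="A", residues=[res1, res2, lig], structure_id=id)
    return Structure(id=id, models=[Model(chains=[ch])], provenance=["fixture"])


def write_fixture_set(directory: str, seed: int = 0) -> str:
    """Emit a standard fixture set as PDB files plus a JSON manifest that
    records each fixture's ground-truth geometric properties. Returns the
    manifest path."""
    import json
    import os

    from .structure_io import write_pdb_file

    os.makedirs(directory, exist_ok=True)
    monomer = build_coil(16, seed=7)
    entries = {}

    def emit(name, structure, truth):
        path = os.path.join(directory, f"{name}.pdb")
        write_pdb_file(structure, path)
        entries[name] = {"file": f"{name}.pdb", **truth}

    emit("helix12", build_helix(12),
         {"kind": "helix", "n_residues": 12,
          "i_i4_o_n_max_distance": 3.5, "rise_per_residue": 1.5})
    emit("strand8", build_strand(8), {"kind": "strand", "n_residues": 8})
    emit("coil60", build_coil(60, seed=seed),
         {"kind": "coil", "n_residues": 60, "seed": seed, "symmetry": "none"})
    for n in (2, 4):
        emit(f"c{n}_ring", build_cn_ring(monomer, n, radius=16.0),
             {"kind": "cn_ring", "order": n, "rotation_deg": 360.0 / n,
              "axis": [0, 0, 1]})
    emit("helical_stack",
         build_helical_stack(monomer, 6, twist=60.0, rise=5.0),
         {"kind": "helical_stack", "twist_deg": 60.0, "rise_angstrom": 5.0})
    for t, truth in [("salt bridge", {"ionic": 1}),
                     ("hbond", {"hbond": 1}),
                     ("pi-stacking", {"pi_stacking": 1}),
                     ("pi-cation", {"pi_cation": 1}),
                     ("halogen", {"halogen": 1}),
                     ("contact", {"contact": 1})]:
        tag = t.replace(" ", "_").replace("-", "_")
        emit(f"interface_{tag}", build_interface_pair([t], id=tag),
             {"kind": "interface_pair", "planted": t,
              "expected_counts": truth})
    emit("ligand_complex", build_ligand_complex(),
         {"kind": "ligand_complex", "near_distance": 3.0,
          "far_distance": 9.0})
    manifest = os.path.join(directory, "manifest.json")
    with open(manifest, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


# ---------------------------------------------------------------------------
# synthetic stand-ins for literature worked examples (no network access)

def build_synthetic_binding_interface(id: str = "synthetic_complex") -> Structure:
    """SYNTHETIC stand-in for a receptor/binder complex of the kind used in
    published worked examples (a viral binding domain docked on its receptor):
    it is constructed geometry, not deposited coordinates.

    Chain A ("receptor") and chain E ("binder") share an interface with
    exactly two salt bridges (E Lys417 - A Asp30, E Arg403 - A Glu35). Binder
    residue 501 is an Asn placed opposite receptor Tyr41 and Lys353 such that
    the wild type makes no aromatic interaction, while rebuilding residue 501
    as Tyr places a ring that stacks with Tyr41 (centroids ~4.5 A) and sits
    ~5 A from the Lys353 ammonium: the mutation gains exactly one pi-stacking
    and one pi-cation interaction.
    """
    sid = id
    # site 1 + 2: the two salt bridges, 25 A apart
    k417, d30, _, _ = _site_salt_bridge(np.array([0.0, 0.0, 0.0]))
    r403 = _single("ARG", (180.0, 180.0, 180.0, 85.0))
    _frame_transform(r403, _coord(r403, "NH1"),
                     _coord(r403, "NH1") - _coord(r403, "CZ"), [0, 0, 1],
                     np.array([0.0, 25.0, 0.0]), [1, 0, 0], [0, 0, 1])
    e35 = _single("GLU", (180.0, 180.0, 0.0))
    _frame_transform(e35, _coord(e35, "OE1"),
                     _coord(e35, "OE1") - _coord(e35, "CD"), [0, 0, 1],
                     np.array([4.5, 25.0, 0.0]), [-1, 0, 0], [0, 0, 1])

    # site 3: the mutation site. Build the Tyr the mutation engine would
    # build (highest-prior rotamer, chi = (-65, 90)) on a reference backbone
    # to learn where its ring lands, then place the receptor partners
    # relative to that ring; finally keep the Asn wild type on that backbone.
    ref = _single("TYR", (-65.0, 90.0))
    site = np.array([0.0, 50.0, 0.0])
    _frame_transform(ref, _coord(ref, "CA"), _coord(ref, "CB") - _coord(ref, "CA"),
                     [0, 0, 1], site, [1, 0, 0], [0, 0, 1])
    cen, nrm = _ring_frame(ref, "TYR")   # CA of the site on the +nrm side
    backbone = {nm: _coord(ref, nm) for nm in ("N", "CA", "C", "O")}
    lat = backbone["CA"] - cen
    lat = unit(lat - np.dot(lat, nrm) * nrm)   # lateral direction of backbone

    # stacking partner on the face away from the site's backbone
    y41 = _single("TYR", (-65.0, 90.0))
    c41, n41 = _ring_frame(y41, "TYR")
    _frame_transform(y41, c41, n41, _coord(y41, "CA") - c41,
                     cen - 4.5 * nrm, -nrm, -lat)
    # ammonium on the backbone face but tilted away from the backbone
    k353 = _single("LYS", (180.0, 180.0, 180.0, 180.0))
    nz_offset = 4.0 * nrm - 3.0 * lat
    _frame_transform(k353, _coord(k353, "NZ"),
                     _coord(k353, "NZ") - _coord(k353, "CE"), [0, 0, 1],
                     cen + nz_offset, -unit(nz_offset), nrm)

    n501_atoms = [_mk_atom(0, nm, nm[0], backbone[nm]) for nm in ("N", "CA", "C", "O")]
    for nm, el, pos in build_side_chain(backbone["N"], backbone["CA"],
                                        backbone["C"], "ASN", (-65.0, -40.0)):
        n501_atoms.append(_mk_atom(0, nm, el, pos))

    chain_a_res = [
        _residue("A", 30, "ASP", d30, sid),
        _residue("A", 35, "GLU", e35, sid),
        _residue("A", 41, "TYR", y41, sid),
        _residue("A", 353, "LYS", k353, sid),
    ]
    chain_e_res = [
        _residue("E", 403, "ARG", r403, sid),
        _residue("E", 417, "LYS", k417, sid),
        _residue("E", 501, "ASN", n501_atoms, sid),
    ]
    serial = 0
    for r in chain_a_res + chain_e_res:
        for a in r.atoms:
            serial += 1
            a.serial = serial
    ch_a = Chain(id="A", residues=chain_a_res, structure_id=sid)
    ch_e = Chain(id="E", residues=chain_e_res, structure_id=sid)
    return Structure(id=sid, models=[Model(chains=[ch_a, ch_e])],
                     provenance=["synthetic fixture"])


def build_synthetic_c2_domain(seed: int = 0, tail: int = 40,
                              id: str = "synthetic_c2") -> Structure:
    """SYNTHETIC stand-in for a chain whose N-terminal region (residues
    1-178) carries internal C2 symmetry while the full chain does not:
    constructed geometry, not deposited coordinates.

    Residues 1-89 form a seeded compact lobe; residues 90-178 are an exact
    copy rotated 180 degrees about z; residues 179+ are an asymmetric coil
    tail. Selecting residues 1-178 must therefore yield cyclic symmetry of
    order 2; the tail breaks any whole-chain symmetry.
    """
    rng = np.random.default_rng(seed)
    n_lobe = 89
    # mixed helix/turn dihedral pattern, seeded
    phi_psi = []
    i = 0
    while len(phi_psi) < n_lobe:
        run = int(rng.integers(6, 14))
        for _ in range(min(run, n_lobe - len(phi_psi))):
            phi_psi.append((-57.0 + rng.normal(0, 4), -47.0 + rng.normal(0, 4)))
        for _ in range(min(3, n_lobe - len(phi_psi))):
            phi_psi.append((float(rng.uniform(-140, -60)),
                            float(rng.uniform(100, 170))))
    lobe = build_peptide("A" * n_lobe, phi_psi[:n_lobe], id=id)
    coords = np.array([a.coord for a in lobe.atoms()])
    # centre lobe at (r, 0, 0) so a 180-degree z-rotation is clash-free
    extent = float(np.linalg.norm(coords - coords.mean(0), axis=1).max())
    shift = np.array([extent + 6.0, 0.0, 0.0]) - coords.mean(0)
    rot = rotation_about_axis([0, 0, 1], 180.0)

    residues = []
    serial = 0
    for r in lobe.models[0].chains[0].residues:
        atoms = []
        for a in r.atoms:
            serial += 1
            atoms.append(_mk_atom(serial, a.name, a.element, a.coord + shift))
        residues.append(_residue("A", r.number, r.type, atoms, id))
    for r in lobe.models[0].chains[0].residues:
        atoms = []
        for a in r.atoms:
            serial += 1
            atoms.append(_mk_atom(serial, a.name, a.element, rot @ (a.coord + shift)))
        residues.append(_residue("A", r.number + n_lobe, r.type, atoms, id))

    tail_st = build_coil(tail, seed=seed + 1)
    tail_res = tail_st.models[0].chains[0].residues
    # hang the tail off along +z, well away from both lobes
    tail_shift = np.array([0.0, 0.0, extent + 12.0])
    for k, r in enumerate(tail_res):
        atoms = []
        for a in r.atoms:
            serial += 1
            atoms.append(_mk_atom(serial, a.name, a.element, a.coord + tail_shift))
        residues.append(_residue("A", 2 * n_lobe + 1 + k, r.type, atoms, id))
    ch = Chain(id="A", residues=residues, structure_id=id)
    return Structure(id=id, models=[Model(chains=[ch])],
                     provenance=["synthetic fixture"])
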