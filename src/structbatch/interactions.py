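"""Detection of the six typed non-covalent interactions between two residue
sets, with network and tabular export.

Types and default distance thresholds (A): hydrogen bond 3.8, salt bridge /
ionic 6, contact 4, halogen bond 3.8, pi-cation 6, pi-stacking 5.5. All
criteria are heavy-atom distance rules; hydrogens and angular terms are not
used. One interaction per (type, residue pair) is reported, carrying the
closest qualifying atom pair (a ring centroid counts as a pseudo-atom named
RING5/RING6 for the pi types). A residue pair already explained by a specific
type still yields a contact if some atom pair within the contact threshold is
not part of that specific interaction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from . import chemistry as chem
from .structure_io import Residue, Selection, Structure, resolve_selection

__all__ = [
    "InteractionThresholds", "Interaction", "InteractionSet",
    "find_interactions", "interaction_network", "residues_within_radius",
    "INTERACTION_TYPES", "EDGE_COLORS",
]

INTERACTION_TYPES = ("contact", "hbond", "ionic", "halogen",
                     "pi_cation", "pi_stacking")

# 2D-network edge colour convention
EDGE_COLORS = {"hbond": "green", "ionic": "cyan", "contact": "gray",
               "pi_cation": "red", "pi_stacking": "blue", "halogen": "magenta"}

_HALOGENS = {"F", "CL", "BR", "I"}
_HALOGEN_ACCEPTOR_ELEMENTS = {"O", "N", "S"}


@dataclass(frozen=True)
class InteractionThresholds:
    """Distance cutoffs in Angstroms; defaults follow the batch-command
    convention 'threshold 3.8 6 4 3.8 6 5.5' (hbond, salt bridge, contact,
    halogen, pi-cation, pi-stacking)."""
    hbond: float = 3.8
    salt_bridge: float = 6.0
    contact: float = 4.0
    halogen: float = 3.8
    pi_cation: float = 6.0
    pi_stacking: float = 5.5

    def __post_init__(self):
        for k, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"threshold {k} must be positive, got {v}")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "InteractionThresholds":
        valid = set(asdict(cls()).keys())
        unknown = set(mapping) - valid
        if unknown:
            raise KeyError(f"unknown threshold keys: {sorted(unknown)}; "
                           f"valid keys: {sorted(valid)}")
        return cls(**mapping)

    def for_type(self, itype: str) -> float:
        return {"contact": self.contact, "hbond": self.hbond,
                "ionic": self.salt_bridge, "halogen": self.halogen,
                "pi_cation": self.pi_cation,
                "pi_stacking": self.pi_stacking}[itype]


@dataclass(frozen=True)
class Interaction:
    type: str
    residue_a: tuple          # (structure_id, chain_id, number, icode)
    residue_b: tuple
    atom_a: str
    atom_b: str
    distance: float
    label_a: str = ""
    label_b: str = ""

    @property
    def pair_key(self) -> tuple:
        return (self.type, self.residue_a, self.residue_b)


@dataclass
class InteractionSet:
    interactions: list[Interaction] = field(default_factory=list)
    set_a: Optional[Selection] = None
    set_b: Optional[Selection] = None
    thresholds: InteractionThresholds = field(default_factory=InteractionThresholds)

    def by_type(self, itype: str) -> list[Interaction]:
        return [i for i in self.interactions if i.type == itype]

    def counts(self) -> dict[str, int]:
        return {t: len(self.by_type(t)) for t in INTERACTION_TYPES}

    def swapped(self) -> "InteractionSet":
        return InteractionSet(
            interactions=[Interaction(i.type, i.residue_b, i.residue_a,
                                      i.atom_b, i.atom_a, i.distance,
                                      i.label_b, i.label_a)
                          for i in self.interactions],
            set_a=self.set_b, set_b=self.set_a, thresholds=self.thresholds)

    def to_tsv(self) -> str:
        rows = ["type\tchainA\tresA\tatomA\tchainB\tresB\tatomB\tdistance"]
        for i in sorted(self.interactions, key=lambda x: (x.type, x.residue_a,
                                                          x.residue_b)):
            rows.append("\t".join([
                i.type, i.residue_a[1], f"{i.residue_a[2]}{i.residue_a[3]}",
                i.atom_a, i.residue_b[1], f"{i.residue_b[2]}{i.residue_b[3]}",
                i.atom_b, f"{i.distance:.3f}"]))
        return "\n".join(rows) + "\n"

    def to_json(self) -> str:
        return json.dumps({
            "counts": self.counts(),
            "interactions": [
                {"type": i.type, "residue_a": i.label_a or list(i.residue_a),
                 "residue_b": i.label_b or list(i.residue_b),
                 "atom_a": i.atom_a, "atom_b": i.atom_b,
                 "distance": round(i.distance, 3)}
                for i in sorted(self.interactions,
                                key=lambda x: (x.type, x.residue_a, x.residue_b))],
        }, indent=2, sort_keys=True)


def _dist(p, q) -> float:
    return float(np.linalg.norm(np.asarray(p) - np.asarray(q)))


def _pairwise(res_a: Residue, res_b: Residue,
              thresholds: InteractionThresholds,
              his_charged: bool) -> list[Interaction]:
    """All typed interactions between one residue pair."""
    out: list[Interaction] = []
    heavy_a = res_a.heavy_atoms()
    heavy_b = res_b.heavy_atoms()
    if not heavy_a or not heavy_b:
        return out
    ca = np.array([a.coord for a in heavy_a])
    cb = np.array([a.coord for a in heavy_b])
    dmat = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    max_thr = max(thresholds.hbond, thresholds.salt_bridge, thresholds.contact,
                  thresholds.halogen, thresholds.pi_cation,
                  thresholds.pi_stacking)
    if dmat.min() > max_thr + 6.0:   # 6 A covers the centroid offset
        return out

    specific_atom_pairs: set[tuple[str, str]] = set()

    def best_pair(atoms_a, atoms_b, cutoff):
        best = None
        for x in atoms_a:
            for y in atoms_b:
                d = _dist(x.coord, y.coord)
                if d <= cutoff and (best is None or d < best[2]):
                    best = (x, y, d)
        return best

    def add(itype, atoms_a, atoms_b, cutoff, record_all=True):
        hit = best_pair(atoms_a, atoms_b, cutoff)
        if hit is None:
            return
        x, y, d = hit
        out.append(Interaction(itype, res_a.key, res_b.key, x.name, y.name, d,
                               res_a.label, res_b.label))
        if record_all:
            for xx in atoms_a:
                for yy in atoms_b:
                    if _dist(xx.coord, yy.coord) <= cutoff:
                        specific_atom_pairs.add((xx.name, yy.name))

    # hydrogen bonds: donor heavy atom near acceptor heavy atom, either way
    don_a, acc_a = chem.donor_atoms(res_a), chem.acceptor_atoms(res_a)
    don_b, acc_b = chem.donor_atoms(res_b), chem.acceptor_atoms(res_b)
    hb_pairs = [(x, y) for x in don_a for y in acc_b] + \
               [(x, y) for x in acc_a for y in don_b]
    best = None
    for x, y in hb_pairs:
        d = _dist(x.coord, y.coord)
        if d <= thresholds.hbond:
            specific_atom_pairs.add((x.name, y.name))
            if best is None or d < best[2]:
                best = (x, y, d)
    if best is not None:
        out.append(Interaction("hbond", res_a.key, res_b.key, best[0].name,
                               best[1].name, best[2], res_a.label, res_b.label))

    # ionic: cationic group atom near anionic group atom
    cat_a = chem.cation_atoms(res_a, his_charged)
    cat_b = chem.cation_atoms(res_b, his_charged)
    ani_a, ani_b = chem.anion_atoms(res_a), chem.anion_atoms(res_b)
    ion_pairs = [(x, y) for x in cat_a for y in ani_b] + \
                [(x, y) for x in ani_a for y in cat_b]
    best = None
    for x, y in ion_pairs:
        d = _dist(x.coord, y.coord)
        if d <= thresholds.salt_bridge:
            specific_atom_pairs.add((x.name, y.name))
            if best is None or d < best[2]:
                best = (x, y, d)
    if best is not None:
        out.append(Interaction("ionic", res_a.key, res_b.key, best[0].name,
                               best[1].name, best[2], res_a.label, res_b.label))

    # halogen bonds: X (F/Cl/Br/I) near O/N/S
    hal_a = [a for a in heavy_a if a.element.upper() in _HALOGENS]
    hal_b = [a for a in heavy_b if a.element.upper() in _HALOGENS]
    ons_a = [a for a in heavy_a if a.element.upper() in _HALOGEN_ACCEPTOR_ELEMENTS]
    ons_b = [a for a in heavy_b if a.element.upper() in _HALOGEN_ACCEPTOR_ELEMENTS]
    best = None
    for x, y in [(x, y) for x in hal_a for y in ons_b] + \
                [(x, y) for x in ons_a for y in hal_b]:
        d = _dist(x.coord, y.coord)
        if d <= thresholds.halogen:
            specific_atom_pairs.add((x.name, y.name))
            if best is None or d < best[2]:
                best = (x, y, d)
    if best is not None:
        out.append(Interaction("halogen", res_a.key, res_b.key, best[0].name,
                               best[1].name, best[2], res_a.label, res_b.label))

    # pi systems
    rings_a = chem.aromatic_rings(res_a)
    rings_b = chem.aromatic_rings(res_b)
    best = None
    for x in cat_a:
        for name, cen in rings_b:
            d = _dist(x.coord, cen)
            if d <= thresholds.pi_cation and (best is None or d < best[3]):
                best = (x.name, name, "ab", d)
    for y in cat_b:
        for name, cen in rings_a:
            d = _dist(y.coord, cen)
            if d <= thresholds.pi_cation and (best is None or d < best[3]):
                best = (name, y.name, "ab", d)
    if best is not None:
        out.append(Interaction("pi_cation", res_a.key, res_b.key, best[0],
                               best[1], best[3], res_a.label, res_b.label))
    best = None
    for na, cen_a in rings_a:
        for nb, cen_b in rings_b:
            d = _dist(cen_a, cen_b)
            if d <= thresholds.pi_stacking and (best is None or d < best[2]):
                best = (na, nb, d)
    if best is not None:
        out.append(Interaction("pi_stacking", res_a.key, res_b.key, best[0],
                               best[1], best[2], res_a.label, res_b.label))

    # contacts: closest heavy-atom pair not already explaining a specific type
    best = None
    for i, x in enumerate(heavy_a):
        for j, y in enumerate(heavy_b):
            if dmat[i, j] <= thresholds.contact and \
                    (x.name, y.name) not in specific_atom_pairs:
                if best is None or dmat[i, j] < best[2]:
                    best = (x, y, float(dmat[i, j]))
    if best is not None:
        out.append(Interaction("contact", res_a.key, res_b.key, best[0].name,
                               best[1].name, best[2], res_a.label, res_b.label))
    return out


def find_interactions(structure: Structure, set_a: Selection, set_b: Selection,
                      thresholds: Optional[InteractionThresholds] = None,
                      his_charged: bool = False) -> InteractionSet:
    """Typed interactions between every residue pair spanning two disjoint
    selections. His is treated as neutral unless `his_charged` is set."""
    thresholds = thresholds or InteractionThresholds()
    res_a = resolve_selection(structure, set_a)
    res_b = resolve_selection(structure, set_b)
    keys_a = {r.key for r in res_a}
    overlap = keys_a & {r.key for r in res_b}
    if overlap:
        raise ValueError(f"selections overlap on {len(overlap)} residues, "
                         "e.g. " + str(sorted(overlap)[0]))
    out = InteractionSet(set_a=set_a, set_b=set_b, thresholds=thresholds)
    for ra in res_a:
        for rb in res_b:
            out.interactions.extend(_pairwise(ra, rb, thresholds, his_charged))
    return out


def interaction_network(iset: InteractionSet) -> nx.MultiGraph:
    """Residue-level interaction network: nodes are residues taking part in
    at least one interaction, parallel typed edges carry the colour
    convention (green hbond, cyan ionic, gray contact, red pi-cation, blue
    pi-stacking)."""
    g = nx.MultiGraph()
    for i in iset.interactions:
        for key, label in ((i.residue_a, i.label_a), (i.residue_b, i.label_b)):
            node = label or str(key)
            if not g.has_node(node):
                g.add_node(node, structure=key[0], chain=key[1],
                           number=int(key[2]), restype=label.rsplit("_", 1)[-1]
                           if label else "")
        g.add_edge(i.label_a or str(i.residue_a),
                   i.label_b or str(i.residue_b),
                   type=i.type, color=EDGE_COLORS.get(i.type, "black"),
                   distance=round(i.distance, 3))
    return g


def network_to_json(g: nx.MultiGraph) -> str:
    return json.dumps(nx.node_link_data(g, edges="edges"), indent=2,
                      sort_keys=True)


def write_network_graphml(g: nx.MultiGraph, path: str) -> None:
    nx.write_graphml(g, path)


def residues_within_radius(structure: Structure, center: Selection,
                           radius: float) -> list[Residue]:
    """All residues (excluding the center) with at least one heavy atom
    within `radius` A of any center heavy atom."""
    center_res = resolve_selection(structure, center)
    if not center_res:
        raise ValueError("center selection resolves to no residues")
    center_keys = {r.key for r in center_res}
    center_coords = np.array([a.coord for r in center_res
                              for a in r.heavy_atoms()])
    out = []
    for r in structure.residues():
        if r.key in center_keys:
            continue
        coords = [a.coord for a in r.heavy_atoms()]
        if not coords:
            continue
        d = np.linalg.norm(center_coords[:, None, :] -
                           np.asarray(coords)[None, :, :], axis=-1)
        if d.min() <= radius and radius > 0:
            out.append(r)
    return out
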