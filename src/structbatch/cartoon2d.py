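"""2D cartoon layouts at chain, domain and secondary-structure levels.

Secondary structure is assigned from backbone dihedrals alone (no hydrogen
bonds needed): runs of at least 4 residues in the alpha basin become helices,
runs of at least 3 in the beta basin become strands, everything else is coil.

A layout projects the selection through a view rotation, drops the depth
axis, and represents each unit as a glyph: chains and domains become ovals
oriented along the first principal axis of their projected CA coordinates
and sized by the square roots of the principal variances; helices become
solid cylinders and strands hollow ones, spanning their projected first and
last CA, labelled "H"/"S" plus the first residue number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence
from xml.etree import ElementTree as ET

import numpy as np

from ._geom import dihedral
from .structure_io import Residue, Selection, Structure, resolve_selection

__all__ = [
    "SSAssignment", "CartoonNode", "CartoonLayout",
    "assign_secondary_structure", "cartoon_layout", "render_cartoon_svg",
]

HELIX_PHI = (-100.0, -30.0)
HELIX_PSI = (-80.0, -5.0)
STRAND_PHI = (-180.0, -60.0)
STRAND_PSI_A = (60.0, 180.0)
STRAND_PSI_B = (-180.0, -150.0)
MIN_HELIX = 4
MIN_STRAND = 3


@dataclass
class SSAssignment:
    states: dict = field(default_factory=dict)   # residue key -> "H"/"E"/"C"

    def state(self, residue: Residue) -> str:
        return self.states.get(residue.key, "C")

    def to_tsv(self, residues: Sequence[Residue]) -> str:
        rows = ["chain\tnumber\ttype\tstate"]
        for r in residues:
            rows.append(f"{r.chain_id}\t{r.number}\t{r.type}\t{self.state(r)}")
        return "\n".join(rows) + "\n"


def _in(v: float, lo_hi: tuple[float, float]) -> bool:
    return lo_hi[0] <= v <= lo_hi[1]


def assign_secondary_structure(structure: Structure,
                               selection: Selection) -> SSAssignment:
    """Dihedral-basin assignment; residues with missing backbone atoms are
    forced to coil."""
    residues = resolve_selection(structure, selection)
    out = SSAssignment()
    by_chain: dict[tuple, list[Residue]] = {}
    for r in residues:
        if r.is_amino:
            by_chain.setdefault((r.structure_id, r.chain_id), []).append(r)
    for chain_res in by_chain.values():
        raw = []
        for i, r in enumerate(chain_res):
            state = "C"
            prev_r = chain_res[i - 1] if i > 0 else None
            next_r = chain_res[i + 1] if i + 1 < len(chain_res) else None
            atoms = {n: (r.atom(n).coord if r.atom(n) else None)
                     for n in ("N", "CA", "C")}
            if (prev_r is not None and next_r is not None
                    and all(v is not None for v in atoms.values())
                    and prev_r.atom("C") is not None
                    and next_r.atom("N") is not None
                    and prev_r.number == r.number - 1
                    and next_r.number == r.number + 1):
                phi = dihedral(prev_r.atom("C").coord, atoms["N"],
                               atoms["CA"], atoms["C"])
                psi = dihedral(atoms["N"], atoms["CA"], atoms["C"],
                               next_r.atom("N").coord)
                if _in(phi, HELIX_PHI) and _in(psi, HELIX_PSI):
                    state = "H"
                elif _in(phi, STRAND_PHI) and (_in(psi, STRAND_PSI_A)
                                               or _in(psi, STRAND_PSI_B)):
                    state = "E"
            raw.append(state)
        # enforce minimum run lengths
        final = list(raw)
        i = 0
        while i < len(raw):
            j = i
            while j < len(raw) and raw[j] == raw[i]:
                j += 1
            run, state = j - i, raw[i]
            if (state == "H" and run < MIN_HELIX) or \
               (state == "E" and run < MIN_STRAND):
                for k in range(i, j):
                    final[k] = "C"
            i = j
        for r, s in zip(chain_res, final):
            out.states[r.key] = s
    return out


@dataclass
class CartoonNode:
    kind: str                  # chain_oval | domain_oval | helix_cylinder | sheet_cylinder
    label: str
    center_2d: np.ndarray
    axis_2d: np.ndarray        # unit 2-vector
    length: float
    width: float
    members: list = field(default_factory=list)   # residue keys


@dataclass
class CartoonLayout:
    nodes: list[CartoonNode] = field(default_factory=list)
    view_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    level: str = "chain"

    def to_json_obj(self) -> dict:
        return {"level": self.level,
                "nodes": [{"kind": nd.kind, "label": nd.label,
                           "center": [round(float(x), 3) for x in nd.center_2d],
                           "axis": [round(float(x), 6) for x in nd.axis_2d],
                           "length": round(nd.length, 3),
                           "width": round(nd.width, 3),
                           "members": [list(k) for k in nd.members]}
                          for nd in self.nodes]}


def _project(coords: np.ndarray, view_rotation: np.ndarray) -> np.ndarray:
    return (coords @ view_rotation.T)[:, :2]


def _pca_node(kind: str, label: str, residues: list[Residue],
              view_rotation: np.ndarray) -> CartoonNode:
    ca = np.array([r.atom("CA").coord for r in residues
                   if r.atom("CA") is not None])
    pts = _project(ca, view_rotation)
    centre = pts.mean(axis=0)
    centred = pts - centre
    if len(pts) > 1:
        cov = centred.T @ centred / len(pts)
        w, v = np.linalg.eigh(cov)
        axis = v[:, 1]                       # largest eigenvalue last
        length = float(np.sqrt(max(w[1], 0.0)))
        width = float(np.sqrt(max(w[0], 0.0)))
    else:
        axis = np.array([1.0, 0.0])
        length = width = 1.0
    # orient the axis toward increasing residue number
    head = pts[-1] - pts[0]
    if float(np.dot(axis, head)) < 0:
        axis = -axis
    return CartoonNode(kind=kind, label=label, center_2d=centre,
                       axis_2d=axis, length=length, width=width,
                       members=[r.key for r in residues])


def cartoon_layout(structure: Structure, selection: Selection,
                   level: str = "chain",
                   domains: Optional[dict[str, Sequence[tuple[int, int]]]] = None,
                   view_rotation: Optional[np.ndarray] = None,
                   ss: Optional[SSAssignment] = None) -> CartoonLayout:
    """Build the glyph layout for a selection at the requested level."""
    rot = np.eye(3) if view_rotation is None else np.asarray(view_rotation,
                                                             float)
    residues = [r for r in resolve_selection(structure, selection) if r.is_amino]
    if not residues:
        raise ValueError("selection resolves to no amino-acid residues")
    layout = CartoonLayout(view_rotation=rot, level=level)

    if level == "chain":
        by_chain: dict[str, list[Residue]] = {}
        for r in residues:
            by_chain.setdefault(r.chain_id, []).append(r)
        for cid, rs in by_chain.items():
            layout.nodes.append(_pca_node("chain_oval", cid, rs, rot))
        return layout

    if level == "domain":
        if not domains:
            raise ValueError("domain-level cartoon requires domain ranges")
        claimed: set[int] = set()
        for name, ranges in domains.items():
            nums = set()
            for lo, hi in ranges:
                nums.update(range(lo, hi + 1))
            if nums & claimed:
                raise ValueError(f"domain {name!r} overlaps another domain")
            claimed |= nums
            members = [r for r in residues if r.number in nums]
            if members:
                layout.nodes.append(_pca_node("domain_oval", name, members, rot))
        return layout

    if level == "ss":
        if ss is None:
            ss = assign_secondary_structure(structure, selection)
        by_chain2: dict[tuple, list[Residue]] = {}
        for r in residues:
            by_chain2.setdefault((r.structure_id, r.chain_id), []).append(r)
        for chain_res in by_chain2.values():
            i = 0
            while i < len(chain_res):
                state = ss.state(chain_res[i])
                j = i
                while j < len(chain_res) and ss.state(chain_res[j]) == state:
                    j += 1
                if state in ("H", "E"):
                    run = chain_res[i:j]
                    ca = [r.atom("CA") for r in run if r.atom("CA")]
                    pts = _project(np.array([a.coord for a in ca]), rot)
                    start, end = pts[0], pts[-1]
                    axis = end - start
                    norm = float(np.linalg.norm(axis))
                    axis = axis / norm if norm > 1e-9 else np.array([1.0, 0.0])
                    kind = "helix_cylinder" if state == "H" else "sheet_cylinder"
                    label = ("H" if state == "H" else "S") + str(run[0].number)
                    layout.nodes.append(CartoonNode(
                        kind=kind, label=label,
                        center_2d=(start + end) / 2.0, axis_2d=axis,
                        length=norm, width=3.0 if state == "H" else 2.0,
                        members=[r.key for r in run]))
                i = j
        return layout

    raise ValueError(f"unknown cartoon level {level!r}")


def render_cartoon_svg(layout: CartoonLayout, scale: float = 4.0) -> str:
    """One SVG shape per node, labelled; member residues are embedded as a
    data attribute so glyphs remain machine-addressable."""
    nodes = layout.nodes
    if nodes:
        centres = np.array([nd.center_2d for nd in nodes])
        lo = centres.min(axis=0) - 30
        hi = centres.max(axis=0) + 30
    else:
        lo, hi = np.array([0.0, 0.0]), np.array([100.0, 100.0])
    size = (hi - lo) * scale
    svg = ET.Element("svg", xmlns="http://www.w3.org/2000/svg",
                     width=f"{size[0]:.0f}", height=f"{size[1]:.0f}")
    for nd in nodes:
        c = (nd.center_2d - lo) * scale
        ang = float(np.degrees(np.arctan2(nd.axis_2d[1], nd.axis_2d[0])))
        members = ";".join(f"{k[1]}{k[2]}" for k in nd.members)
        common = {"transform": f"rotate({ang:.1f} {c[0]:.1f} {c[1]:.1f})",
                  "data-members": members, "data-kind": nd.kind}
        if nd.kind.endswith("oval"):
            ET.SubElement(svg, "ellipse", cx=f"{c[0]:.1f}", cy=f"{c[1]:.1f}",
                          rx=f"{max(nd.length * scale, 2):.1f}",
                          ry=f"{max(nd.width * scale, 2):.1f}",
                          fill="#9ecae1", stroke="#333", attrib=common)
        else:
            solid = nd.kind == "helix_cylinder"
            w = nd.length * scale
            h = nd.width * scale
            ET.SubElement(svg, "rect",
                          x=f"{c[0] - w / 2:.1f}", y=f"{c[1] - h / 2:.1f}",
                          width=f"{max(w, 2):.1f}", height=f"{max(h, 2):.1f}",
                          rx=f"{h / 3:.1f}",
                          fill="#fb6a4a" if solid else "none",
                          stroke="#333", attrib=common)
        t = ET.SubElement(svg, "text", x=f"{c[0]:.1f}", y=f"{c[1] - 4:.1f}",
                          attrib={"text-anchor": "middle", "font-size": "11"})
        t.text = nd.label
    return ET.tostring(svg, encoding="unicode")
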