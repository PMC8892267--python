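"""Residue-residue contact maps.

A contact map is a symmetric boolean matrix over an ordered residue list:
entry (i, j) is true when the representative atoms of residues i and j are
within the threshold (default 8 A, inclusive). The default representative is
C-beta, with C-alpha standing in for glycine and any other residue lacking a
CB; modes using CA or the closest heavy-atom pair are also available.
Rendering follows the interactive-map convention: at scale 1 the axes carry
per-residue labels, at small scales (e.g. 0.04) labels are suppressed and
only dots remain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional
from xml.etree import ElementTree as ET

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import Residue, Selection, Structure, resolve_selection

__all__ = ["ContactMap", "compute_contact_map", "render_contact_map"]

log = logging.getLogger(__name__)

_CHAIN_COLORS = ["#3366cc", "#dc3912", "#ff9900", "#109618", "#990099",
                 "#0099c6", "#dd4477", "#66aa00"]


@dataclass
class ContactMap:
    residues: list[Residue]
    matrix: np.ndarray             # boolean, n x n, symmetric, diagonal True
    threshold: float = 8.0
    atom_mode: str = "c_beta"
    scale: float = 1.0

    @property
    def n(self) -> int:
        return len(self.residues)

    def to_tsv(self) -> str:
        header = "\t".join(f"{r.chain_id}{r.number}" for r in self.residues)
        lines = ["\t" + header]
        for i, r in enumerate(self.residues):
            row = "\t".join(str(int(x)) for x in self.matrix[i])
            lines.append(f"{r.chain_id}{r.number}\t{row}")
        return "\n".join(lines) + "\n"

    def to_pairs(self, include_diagonal: bool = False) -> list[tuple]:
        out = []
        for i in range(self.n):
            for j in range(i if include_diagonal else i + 1, self.n):
                if self.matrix[i, j]:
                    ra, rb = self.residues[i], self.residues[j]
                    out.append(((ra.chain_id, ra.number), (rb.chain_id, rb.number)))
        return out


def _representative(residue: Residue, mode: str):
    if mode == "c_beta":
        a = residue.atom("CB") or residue.atom("CA")
        return a
    if mode == "c_alpha":
        return residue.atom("CA")
    if mode == "any_heavy":
        return residue.heavy_atoms() or None
    raise ValueError(f"unknown atom_mode {mode!r}")


def compute_contact_map(structure: Structure, selection: Selection,
                        threshold: float = 8.0,
                        atom_mode: str = "c_beta") -> ContactMap:
    """Contact matrix of a selection; comparison is <= threshold (inclusive).

    Residues lacking the representative atom are dropped with a warning.
    Hetero-only residues (ligands/waters) are excluded in c_beta/c_alpha
    modes. Multi-chain selections are ordered chain-major; inter-chain
    contacts are included.
    """
    residues = resolve_selection(structure, selection)
    if not residues:
        raise ValueError("selection resolves to no residues")
    kept, reps = [], []
    for r in residues:
        if atom_mode in ("c_beta", "c_alpha") and not r.is_amino:
            continue
        rep = _representative(r, atom_mode)
        if rep is None:
            log.warning("residue %s lacks a representative atom; dropped",
                        r.label)
            continue
        kept.append(r)
        reps.append(rep)
    if not kept:
        raise ValueError("no residue in the selection has the representative "
                         f"atom for mode {atom_mode!r}")
    if atom_mode == "any_heavy":
        n = len(kept)
        matrix = np.zeros((n, n), dtype=bool)
        coords = [np.array([a.coord for a in rep]) for rep in reps]
        for i in range(n):
            matrix[i, i] = True
            for j in range(i + 1, n):
                d = cdist(coords[i], coords[j]).min()
                matrix[i, j] = matrix[j, i] = d <= threshold
    else:
        pts = np.array([a.coord for a in reps])
        d = cdist(pts, pts)
        matrix = d <= threshold
        np.fill_diagonal(matrix, True)
    return ContactMap(residues=kept, matrix=matrix, threshold=threshold,
                      atom_mode=atom_mode)


def render_contact_map(cmap: ContactMap, scale: float = 1.0) -> str:
    """SVG rendering. At scale 1 each axis shows one label per residue and
    chain-coloured ticks; below a 0.2 scale the labels are suppressed. Each
    plotted cell carries data-resa/data-resb attributes so it stays
    machine-addressable."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    cell = 14.0 * scale
    margin = 42.0 * scale + (30.0 if scale >= 0.2 else 4.0)
    size = margin + cell * cmap.n + 8
    svg = ET.Element("svg", xmlns="http://www.w3.org/2000/svg",
                     width=f"{size:.1f}", height=f"{size:.1f}")
    chains = []
    for r in cmap.residues:
        if r.chain_id not in chains:
            chains.append(r.chain_id)
    color = {c: _CHAIN_COLORS[i % len(_CHAIN_COLORS)]
             for i, c in enumerate(chains)}
    if scale >= 0.2:
        for i, r in enumerate(cmap.residues):
            label = f"{r.type}{r.number}"
            x = margin + cell * (i + 0.5)
            t = ET.SubElement(svg, "text", x=f"{x:.1f}", y=f"{margin - 6:.1f}",
                              fill=color[r.chain_id],
                              attrib={"font-size": f"{max(8 * scale, 6):.1f}",
                                      "text-anchor": "middle",
                                      "class": "axis-label-x"})
            t.text = label
            t = ET.SubElement(svg, "text", x=f"{margin - 6:.1f}", y=f"{x:.1f}",
                              fill=color[r.chain_id],
                              attrib={"font-size": f"{max(8 * scale, 6):.1f}",
                                      "text-anchor": "end",
                                      "class": "axis-label-y"})
            t.text = label
    for i in range(cmap.n):
        for j in range(cmap.n):
            if i == j or not cmap.matrix[i, j]:
                continue
            ra, rb = cmap.residues[i], cmap.residues[j]
            ET.SubElement(svg, "rect",
                          x=f"{margin + cell * j:.2f}",
                          y=f"{margin + cell * i:.2f}",
                          width=f"{max(cell, 0.5):.2f}",
                          height=f"{max(cell, 0.5):.2f}",
                          fill=color[ra.chain_id],
                          attrib={"class": "contact-cell",
                                  "data-resa": f"{ra.chain_id}{ra.number}",
                                  "data-resb": f"{rb.chain_id}{rb.number}"})
    return ET.tostring(svg, encoding="unicode")
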