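"""Internal Cn / helical symmetry detection by circular-permutation
self-alignment.

The selection's CA trace is aligned against itself shifted by every offset k
(cyclically, pairing residue i with residue i+k mod N). Each shift's
correspondence is refined by alternating Kabsch superposition with nearest-CA
re-matching inside a capture radius; the shift's score is the number of
residues whose transformed CA lands within 3 A of its partner. A shift whose
score stands more than 8 robust standard deviations above the score
distribution over all shifts signals symmetry; the winning transform is
decomposed into rotation angle, screw axis and rise. An angle that divides
360 degrees (within tolerance) with negligible rise is a cyclic symmetry of
that order; otherwise the symmetry is helical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .structure_io import Residue, Selection, Structure, resolve_selection
from .superpose import kabsch

__all__ = ["SymmetryScan", "SymmetryResult", "detect_symmetry", "color_mask",
           "MAX_ATOMS", "Z_THRESHOLD"]

MAX_ATOMS = 30_000          # hard cap on the selection size
Z_THRESHOLD = 8.0           # a symmetry is accepted only above this z-score
MIN_SHIFT = 4               # residues; smaller shifts trivially self-align
CAPTURE_RADIUS = 3.5        # A, for correspondence re-derivation
SCORE_RADIUS = 3.0          # A, CA deviation counted as aligned
ANGLE_TOL = 10.0            # degrees, for 360/angle to count as integer
RISE_TOL = 2.0              # A, max |screw translation| for a cyclic call
_MAX_ITER = 10


@dataclass
class SymmetryScan:
    shifts: list[int] = field(default_factory=list)
    scores: list[int] = field(default_factory=list)
    mean: float = 0.0
    sd: float = 0.0


@dataclass
class SymmetryResult:
    kind: str                      # "none" | "cyclic" | "helical"
    z_score: float
    order: int = 0                 # cyclic only
    axis: Optional[np.ndarray] = None
    angle: float = 0.0             # degrees
    rise: float = 0.0              # A along the axis
    shift: int = 0
    aligned_mask: dict = field(default_factory=dict)  # residue key -> "same"/"different"
    scan: Optional[SymmetryScan] = None

    def to_json(self) -> str:
        return json.dumps({
            "kind": self.kind, "order": self.order,
            "axis": None if self.axis is None else [round(float(x), 6)
                                                    for x in self.axis],
            "angle": round(self.angle, 3), "rise": round(self.rise, 3),
            "z_score": round(self.z_score, 3), "shift": self.shift,
        }, indent=2, sort_keys=True)


def _refine_shift(coords: np.ndarray, k: int):
    """Iterated refinement of the cyclic shift-k self-alignment.

    The correspondence always pairs residue i with residue i+k (mod N); what
    the refinement selects is the subset of those pairs that actually
    superposes (deviation within the capture radius). Keeping the pairing
    tied to the sequence shift is what makes distinct shifts distinguishable:
    free closest-point re-pairing would let every shift collapse onto the
    same symmetry transform.

    Returns (score, rotation, translation, pairs).
    """
    n = len(coords)
    partner = np.roll(np.arange(n), -k)       # i -> (i + k) mod n
    dst = coords[partner]
    keep = np.ones(n, dtype=bool)
    rot = np.eye(3)
    trans = np.zeros(3)
    for _ in range(_MAX_ITER):
        res = kabsch(dst[keep], coords[keep])  # sends residue i onto i+k
        rot, trans = res.rotation, res.translation
        dev = np.linalg.norm(coords @ rot.T + trans - dst, axis=1)
        new_keep = dev <= CAPTURE_RADIUS
        if new_keep.sum() < 3 or bool(np.all(new_keep == keep)):
            if new_keep.sum() >= 3:
                keep = new_keep
            break
        keep = new_keep
    dev = np.linalg.norm(coords @ rot.T + trans - dst, axis=1)
    score = int((dev < SCORE_RADIUS).sum())
    pairs = [(int(i), int(partner[i])) for i in np.nonzero(keep)[0]]
    return score, rot, trans, pairs


def _robust_moments(values: np.ndarray) -> tuple[float, float]:
    """Median and MAD-based sigma of the shift scores. A Cn scan has n-1
    high-scoring shifts, so moment estimators would be inflated by the very
    peaks being tested; median/MAD ignores them. The sigma is floored at one
    residue so near-constant score lists cannot produce unbounded z."""
    v = values.astype(float)
    med = float(np.median(v))
    mad = float(np.median(np.abs(v - med)))
    return med, max(1.4826 * mad, 1.0)


def _decompose(rot: np.ndarray, trans: np.ndarray):
    """Rotation angle, unit axis and screw rise of a rigid transform."""
    angle = float(np.degrees(np.arccos(np.clip((np.trace(rot) - 1) / 2.0,
                                               -1.0, 1.0))))
    w, vec = np.linalg.eig(rot)
    idx = int(np.argmin(np.abs(w - 1.0)))
    axis = np.real(vec[:, idx])
    axis = axis / np.linalg.norm(axis)
    # sign convention: make the rotation about +axis positive
    sin_part = np.array([rot[2, 1] - rot[1, 2], rot[0, 2] - rot[2, 0],
                         rot[1, 0] - rot[0, 1]]) / 2.0
    if float(np.dot(sin_part, axis)) < 0:
        axis = -axis
    rise = float(np.dot(trans, axis))
    return angle, axis, rise


def detect_symmetry(structure: Structure, selection: Selection,
                    z_threshold: float = Z_THRESHOLD) -> SymmetryResult:
    """Scan all circular-permutation shifts of the selection's CA trace and
    report the internal symmetry, if any survives the z > 8 rule."""
    residues = [r for r in resolve_selection(structure, selection)
                if r.atom("CA") is not None]
    n_atoms = sum(len(r.atoms) for r in resolve_selection(structure, selection))
    if n_atoms > MAX_ATOMS:
        raise ValueError(f"selection has {n_atoms} atoms, above the "
                         f"{MAX_ATOMS}-atom cap")
    if len(residues) < 8:
        raise ValueError(f"selection resolves to {len(residues)} CA-bearing "
                         "residues; need at least 8")
    coords = np.array([r.atom("CA").coord for r in residues])
    n = len(coords)

    shifts = list(range(MIN_SHIFT, n - MIN_SHIFT + 1))
    results = {}
    scores = []
    for k in shifts:
        score, rot, trans, pairs = _refine_shift(coords, k)
        results[k] = (score, rot, trans, pairs)
        scores.append(score)
    scores_arr = np.array(scores)
    mean, sd = _robust_moments(scores_arr)
    z = (scores_arr - mean) / sd
    scan = SymmetryScan(shifts=shifts, scores=scores, mean=mean, sd=sd)

    best_idx = int(np.argmax(z - 1e-9 * np.array(shifts)))  # ties -> smallest
    best_z = float(z[best_idx])
    if best_z <= z_threshold:
        return SymmetryResult(kind="none", z_score=best_z, scan=scan)

    k = shifts[best_idx]
    score, rot, trans, pairs = results[k]
    angle, axis, rise = _decompose(rot, trans)
    mask = {}
    for i, j in pairs:
        same = residues[i].type == residues[j].type
        mask[residues[i].key] = "same" if same else "different"

    if angle > 1e-6:
        order = int(round(360.0 / angle))
    else:
        order = 0
    is_cyclic = (order >= 2 and abs(360.0 / order - angle) <= ANGLE_TOL
                 and abs(rise) < RISE_TOL)
    if is_cyclic:
        return SymmetryResult(kind="cyclic", order=order, axis=axis,
                              angle=angle, rise=rise, z_score=best_z,
                              shift=k, aligned_mask=mask, scan=scan)
    return SymmetryResult(kind="helical", order=0, axis=axis, angle=angle,
                          rise=rise, z_score=best_z, shift=k,
                          aligned_mask=mask, scan=scan)


def color_mask(result: SymmetryResult, structure: Structure,
               selection: Selection) -> list[dict]:
    """Per-residue annotation for rendering: red for residues aligned onto an
    identical residue type, blue for a different type, unaligned otherwise."""
    if result.kind == "none":
        raise ValueError("no symmetry found; nothing to color")
    rows = []
    for r in resolve_selection(structure, selection):
        state = result.aligned_mask.get(r.key)
        rows.append({
            "chain": r.chain_id, "number": r.number, "type": r.type,
            "state": state if state is not None else "unaligned",
            "color": {"same": "red", "different": "blue",
                      None: "none"}[state],
        })
    return rows


def mask_to_tsv(rows: list[dict]) -> str:
    out = ["chain\tnumber\ttype\tstate\tcolor"]
    for r in rows:
        out.append(f"{r['chain']}\t{r['number']}\t{r['type']}\t{r['state']}\t"
                   f"{r['color']}")
    return "\n".join(out) + "\n"
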