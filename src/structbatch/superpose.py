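"""Rigid-body superposition of chains and structures.

The primitive is the Kabsch algorithm (closed-form least-squares rotation via
SVD, with the determinant sign corrected so a proper rotation is always
returned). On top of it sit three correspondence modes:

* ``align_by_sequence`` — global Needleman-Wunsch alignment (BLOSUM62,
  gap open -11 / extend -1) picks matched residue pairs, optionally
  restricted to a master residue range; their CA atoms are superposed.
* ``align_residue_by_residue`` — the i-th residue of one range pairs with
  the i-th of the other; ranges must resolve to equal CA counts.
* ``align_multiple`` — each mover aligned independently onto a master;
  per-mover failures are collected without aborting the rest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .structure_io import (Chain, Residue, Selection, Structure,
                           extract_sequence, resolve_selection)

__all__ = [
    "SuperpositionResult", "kabsch", "align_by_sequence",
    "align_residue_by_residue", "align_multiple", "apply_transform",
]


@dataclass
class SuperpositionResult:
    rotation: np.ndarray          # 3x3, det +1
    translation: np.ndarray       # 3-vector, A
    rmsd: float
    pairs: list[tuple] = field(default_factory=list)  # (master key, mover key)
    n_aligned: int = 0

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def to_json(self) -> str:
        return json.dumps({
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "rmsd": round(self.rmsd, 6),
            "n_aligned": self.n_aligned,
            "pairs": [[list(a), list(b)] for a, b in self.pairs],
        }, indent=2)


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid transform of point set b onto point set a.

    Returns rotation R and translation t minimising |a - (b R^T + t)|;
    the rmsd is the minimised value. Mirror-degenerate inputs still yield a
    proper rotation (det +1).
    """
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    if a.shape != b.shape:
        raise ValueError(f"point sets differ in shape: {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (b - cb).T @ (a - ca)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = ca - rot @ cb
    moved = b @ rot.T + t
    rmsd = float(np.sqrt(((moved - a) ** 2).sum(axis=1).mean()))
    return SuperpositionResult(rotation=rot, translation=t, rmsd=rmsd,
                               n_aligned=a.shape[0])


def apply_transform(structure: Structure, result: SuperpositionResult) -> Structure:
    """Return a copy of `structure` with the transform applied to all atoms."""
    out = structure.copy()
    for a in out.atoms():
        a.coord = result.rotation @ a.coord + result.translation
    return out


def _ca_residues(chain: Chain) -> list[Residue]:
    return [r for r in chain.residues if r.is_amino and r.atom("CA") is not None]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def align_by_sequence(master_chain: Chain, moving_chain: Chain,
                      master_range: Optional[Selection] = None
                      ) -> SuperpositionResult:
    """Sequence-guided superposition: globally align the two chain sequences,
    then superpose the CA atoms of matched residue pairs. With `master_range`
    the pairing is restricted to master residues inside the selection's
    residue ranges."""
    res_m = _ca_residues(master_chain)
    res_v = _ca_residues(moving_chain)
    if len(res_m) < 3 or len(res_v) < 3:
        raise ValueError("both chains need at least 3 CA-bearing residues")
    seq_m = "".join(r.one_letter for r in res_m)
    seq_v = "".join(r.one_letter for r in res_v)
    aln = _make_aligner().align(seq_m, seq_v)[0]
    keep_numbers = None
    if master_range is not None and master_range.residue_ranges:
        keep_numbers = master_range.residue_ranges
    pairs: list[tuple[Residue, Residue]] = []
    for (ms, me), (vs, ve) in zip(*aln.aligned):
        for k in range(me - ms):
            rm, rv = res_m[ms + k], res_v[vs + k]
            if keep_numbers is not None and not any(
                    lo <= rm.number <= hi for lo, hi in keep_numbers):
                continue
            pairs.append((rm, rv))
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} matched residue pairs; "
                         "need at least 3 for a superposition")
    result = kabsch(np.array([p[0].atom("CA").coord for p in pairs]),
                    np.array([p[1].atom("CA").coord for p in pairs]))
    result.pairs = [(p[0].key, p[1].key) for p in pairs]
    result.n_aligned = len(pairs)
    return result


def align_residue_by_residue(chain_a: Chain, range_a: Sequence[tuple[int, int]],
                             chain_b: Chain, range_b: Sequence[tuple[int, int]]
                             ) -> SuperpositionResult:
    """Pair the i-th CA-bearing residue of range_a with the i-th of range_b
    and superpose; the ranges must contain equally many such residues."""
    def pick(chain, ranges):
        return [r for r in _ca_residues(chain)
                if any(lo <= r.number <= hi for lo, hi in ranges)]
    res_a = pick(chain_a, range_a)
    res_b = pick(chain_b, range_b)
    if len(res_a) != len(res_b):
        raise ValueError(
            f"ranges resolve to different residue counts: {len(res_a)} in "
            f"chain {chain_a.id} vs {len(res_b)} in chain {chain_b.id}")
    if len(res_a) < 3:
        raise ValueError("need at least 3 residues per range")
    result = kabsch(np.array([r.atom("CA").coord for r in res_a]),
                    np.array([r.atom("CA").coord for r in res_b]))
    result.pairs = [(a.key, b.key) for a, b in zip(res_a, res_b)]
    result.n_aligned = len(res_a)
    return result


def align_multiple(master: Chain, others: Sequence[Chain],
                   mode: str = "sequence",
                   master_range: Optional[Selection] = None,
                   ranges: Optional[Sequence[Sequence[tuple[int, int]]]] = None
                   ) -> list[SuperpositionResult | Exception]:
    """Align each chain in `others` independently onto `master`.

    mode "sequence" uses align_by_sequence (optionally with master_range);
    mode "residue" uses align_residue_by_residue with per-mover ranges.
    Failures are returned in place of results, so one bad mover does not
    abort its siblings.
    """
    if not others:
        raise ValueError("need at least one structure to align")
    out: list[SuperpositionResult | Exception] = []
    for i, mover in enumerate(others):
        try:
            if mode == "sequence":
                out.append(align_by_sequence(master, mover, master_range))
            elif mode == "residue":
                if ranges is None:
                    raise ValueError("mode 'residue' needs ranges")
                rng = ranges[i] if len(ranges) > 1 else ranges[0]
                master_rng = (master_range.residue_ranges
                              if master_range is not None else rng)
                out.append(align_residue_by_residue(master, master_rng,
                                                    mover, rng))
            else:
                raise ValueError(f"unknown mode {mode!r}")
        except Exception as exc:   # isolate per-mover failures
            out.append(exc)
    return out
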