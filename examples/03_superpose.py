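"""Superpose structures: Kabsch primitive plus sequence-guided alignment.

Rotates a helix by a known rigid motion and recovers it, then aligns a chain
with an internal deletion onto its full-length master by sequence.
"""

import numpy as np

from structbatch import align_by_sequence, kabsch
from structbatch._geom import rotation_about_axis
from structbatch.fixtures import build_helix, build_peptide

helix = build_helix(12)
ca = np.array([r.atom("CA").coord for r in helix.residues()])
rot = rotation_about_axis([0, 0, 1], 37.0)
moved = ca @ rot  # rotate by -37 degrees
res = kabsch(ca, moved)
print(f"recovered rotation rmsd: {res.rmsd:.2e} A "
      f"(0 means the motion was exactly undone)")

seq = "AKDFGYWLMTSENQRHIVCA"
master = build_peptide(seq, [(-57.0, -47.0)] * 20, id="master")
mover = build_peptide(seq, [(-57.0, -47.0)] * 20, id="mover")
ch = mover.models[0].chains[0]
ch.residues = ch.residues[:8] + ch.residues[13:]   # delete residues 9-13
aligned = align_by_sequence(master.models[0].chains[0], ch)
print(f"sequence-guided: {aligned.n_aligned} residue pairs, "
      f"rmsd {aligned.rmsd:.2e} A (deleted residues are simply skipped)")
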