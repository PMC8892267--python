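"""2D cartoons: secondary-structure assignment and glyph layout.

Assigns H/E/C states from backbone dihedrals, then lays out a
helix-plus-strand peptide at the secondary-structure level (solid cylinder
for the helix, hollow for the strand, labelled by first residue) and a
two-lobe chain at the domain level (PCA-oriented ovals).
"""

from structbatch import (Selection, assign_secondary_structure,
                         cartoon_layout, render_cartoon_svg)
from structbatch.fixtures import build_peptide, build_synthetic_c2_domain

phi_psi = [(-57.0, -47.0)] * 14 + [(-120.0, 130.0)] * 7
pep = build_peptide("A" * 21, phi_psi, id="hs")
sel = Selection(chain_id="A")

ss = assign_secondary_structure(pep, sel)
print("states:", "".join(ss.state(r) for r in pep.residues()))

layout = cartoon_layout(pep, sel, level="ss")
for node in layout.nodes:
    print(f"  {node.label}: {node.kind}, length {node.length:.1f} "
          f"drawing units ({len(node.members)} residues)")

domain = build_synthetic_c2_domain(seed=0)
dl = cartoon_layout(domain, sel, level="domain",
                    domains={"lobe1": [(1, 89)], "lobe2": [(90, 178)]})
print("domain ovals:", [(n.label, round(n.length, 1)) for n in dl.nodes])
print(f"SVG: {len(render_cartoon_svg(layout))} characters")
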