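from xml.etree import ElementTree as ET

import numpy as np
import pytest

from structbatch.cartoon2d import (assign_secondary_structure, cartoon_layout,
                                   render_cartoon_svg)
from structbatch.fixtures import build_helix, build_peptide, build_strand
from structbatch.structure_io import Selection

SEL_A = Selection(chain_id="A")
NS = "{http://www.w3.org/2000/svg}"


def test_ideal_helix_assigned_helical(helix12):
    ss = assign_secondary_structure(helix12, SEL_A)
    states = [ss.state(r) for r in helix12.residues()]
    assert all(s == "H" for s in states[1:-1])     # terminal dihedrals undefined


def test_ideal_strand_assigned_extended():
    st = build_strand(8)
    ss = assign_secondary_structure(st, SEL_A)
    states = [ss.state(r) for r in st.residues()]
    assert all(s == "E" for s in states[1:-1])


def test_short_helical_island_demoted_to_coil():
    # 2 helical residues inside a strand: below the 4-residue minimum
    phi_psi = [(-120.0, 130.0)] * 5 + [(-57.0, -47.0)] * 2 + \
              [(-120.0, 130.0)] * 5
    st = build_peptide("A" * 12, phi_psi, id="island")
    ss = assign_secondary_structure(st, SEL_A)
    states = [ss.state(r) for r in st.residues()]
    assert "H" not in states


def test_missing_backbone_forced_to_coil(helix12):
    broken = helix12.copy()
    r = broken.chain("A").residue(6)
    r.atoms = [a for a in r.atoms if a.name != "C"]
    ss = assign_secondary_structure(broken, SEL_A)
    assert ss.state(broken.chain("A").residue(6)) == "C"


def test_chain_level_single_oval(helix12):
    layout = cartoon_layout(helix12, SEL_A, level="chain")
    assert len(layout.nodes) == 1
    node = layout.nodes[0]
    assert node.kind == "chain_oval" and node.label == "A"
    assert len(node.members) == 12     # partition property


def test_domain_ovals_match_pca_oracle(c2_domain):
    domains = {"lobe1": [(1, 89)], "lobe2": [(90, 178)]}
    layout = cartoon_layout(c2_domain, SEL_A, level="domain", domains=domains)
    assert len(layout.nodes) == 2
    for node, (lo, hi) in zip(layout.nodes, [(1, 89), (90, 178)]):
        ca = np.array([r.atom("CA").coord for r in c2_domain.residues()
                       if lo <= r.number <= hi])
        pts = ca[:, :2]                    # identity view: drop z
        cov = np.cov((pts - pts.mean(0)).T)
        w, v = np.linalg.eigh(cov)
        oracle_axis = v[:, -1]
        cosang = abs(float(np.dot(oracle_axis, node.axis_2d)))
        assert np.degrees(np.arccos(min(cosang, 1.0))) < 5.0


def test_domain_overlap_rejected(c2_domain):
    with pytest.raises(ValueError, match="overlap"):
        cartoon_layout(c2_domain, SEL_A, level="domain",
                       domains={"a": [(1, 100)], "b": [(90, 178)]})


def test_domain_level_requires_ranges(c2_domain):
    with pytest.raises(ValueError, match="requires domain ranges"):
        cartoon_layout(c2_domain, SEL_A, level="domain")


@pytest.fixture(scope="module")
def helix_strand():
    phi_psi = [(-57.0, -47.0)] * 14 + [(-120.0, 130.0)] * 7
    return build_peptide("A" * 21, phi_psi, id="hs")


def test_ss_level_labels_and_kinds(helix_strand):
    layout = cartoon_layout(helix_strand, SEL_A, level="ss")
    kinds = sorted(n.kind for n in layout.nodes)
    assert kinds == ["helix_cylinder", "sheet_cylinder"]
    for node in layout.nodes:
        first = min(k[2] for k in node.members)
        prefix = "H" if node.kind == "helix_cylinder" else "S"
        assert node.label == f"{prefix}{first}"


def test_projection_consistency(helix_strand):
    from scipy.spatial.transform import Rotation
    r1 = Rotation.from_euler("xyz", [20, -35, 60], degrees=True).as_matrix()
    r2 = Rotation.from_euler("zxy", [10, 45, -30], degrees=True).as_matrix()
    a = cartoon_layout(helix_strand, SEL_A, level="chain",
                       view_rotation=r2 @ r1)
    b = cartoon_layout(helix_strand, SEL_A, level="chain", view_rotation=r1)
    # laying out under r1 then rotating the view by r2 equals composing
    c = cartoon_layout(helix_strand, SEL_A, level="chain",
                       view_rotation=r2 @ r1)
    assert np.allclose(a.nodes[0].center_2d, c.nodes[0].center_2d, atol=1e-6)
    assert not np.allclose(a.nodes[0].center_2d, b.nodes[0].center_2d)


def test_render_counts(c2_domain, helix_strand):
    layout = cartoon_layout(c2_domain, SEL_A, level="domain",
                            domains={"lobe1": [(1, 89)], "lobe2": [(90, 178)]})
    root = ET.fromstring(render_cartoon_svg(layout))
    assert len(root.findall(f"{NS}ellipse")) == 2
    assert len(root.findall(f"{NS}text")) == 2

    ss = cartoon_layout(helix_strand, SEL_A, level="ss")
    root = ET.fromstring(render_cartoon_svg(ss))
    rects = root.findall(f"{NS}rect")
    fills = {r.get("data-kind"): r.get("fill") for r in rects}
    assert fills["helix_cylinder"] != "none"     # solid
    assert fills["sheet_cylinder"] == "none"     # hollow

    from structbatch.cartoon2d import CartoonLayout
    empty = ET.fromstring(render_cartoon_svg(CartoonLayout()))
    assert len(list(empty)) == 0
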