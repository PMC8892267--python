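import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from structbatch._geom import rotation_about_axis
from structbatch.fixtures import build_helix, build_peptide
from structbatch.structure_io import Selection
from structbatch.superpose import (align_by_sequence, align_multiple,
                                   align_residue_by_residue, apply_transform,
                                   kabsch)

SEQ = "AKDFGYWLMTSENQRHIVCA"   # varied 20-residue sequence
PHIPSI = [(-57.0, -47.0)] * len(SEQ)


@pytest.fixture(scope="module")
def varied_chain():
    return build_peptide(SEQ, PHIPSI, id="master").models[0].chains[0]


def _points(seed, n=12):
    return np.random.default_rng(seed).normal(size=(n, 3)) * 4.0


def test_kabsch_identity():
    a = _points(0)
    res = kabsch(a, a)
    assert np.allclose(res.rotation, np.eye(3), atol=1e-12)
    assert np.allclose(res.translation, 0.0, atol=1e-12)
    assert res.rmsd == pytest.approx(0.0, abs=1e-12)


def test_kabsch_recovers_constructed_transform():
    a = _points(1)
    rot = rotation_about_axis([0, 0, 1], 37.0)
    t = np.array([1.0, -2.0, 3.0])
    b = (a - t) @ rot       # b such that rot @ b + t... construct directly:
    b = (rot.T @ (a - t).T).T
    res = kabsch(a, b)
    assert res.rmsd < 1e-8
    assert np.allclose(res.rotation, rot, atol=1e-8)
    assert np.allclose(res.translation, t, atol=1e-8)


def test_kabsch_mirror_still_proper_rotation():
    a = _points(2)
    b = a.copy()
    b[:, 0] *= -1.0           # mirror image
    res = kabsch(a, b)
    assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
    assert res.rmsd > 0.1


def test_kabsch_contracts():
    with pytest.raises(ValueError):
        kabsch(_points(0, 5), _points(0, 6))
    with pytest.raises(ValueError):
        kabsch(_points(0, 2), _points(0, 2))


def test_kabsch_agrees_with_scipy_align_vectors():
    a, b = _points(3), _points(4)
    res = kabsch(a, b)
    rot_sp, rssd = Rotation.align_vectors(a - a.mean(0), b - b.mean(0))
    assert np.allclose(res.rotation, rot_sp.as_matrix(), atol=1e-8)
    assert res.rmsd == pytest.approx(rssd / np.sqrt(len(a)), abs=1e-8)


def test_kabsch_local_optimality_spot_check():
    a, b = _points(5), _points(6)
    best = kabsch(a, b).rmsd
    rng = np.random.default_rng(7)
    for _ in range(50):
        rot = Rotation.random(random_state=rng).as_matrix()
        moved = b @ rot.T
        moved += (a.mean(0) - moved.mean(0))
        rmsd = np.sqrt(((moved - a) ** 2).sum(axis=1).mean())
        assert rmsd >= best - 1e-12


def test_sequence_alignment_full_copy(varied_chain):
    copy = build_peptide(SEQ, PHIPSI, id="copy").models[0].chains[0]
    res = align_by_sequence(varied_chain, copy)
    assert res.n_aligned == len(SEQ)
    assert res.rmsd == pytest.approx(0.0, abs=1e-9)


def test_sequence_alignment_with_deletion(varied_chain):
    deleted = SEQ[:8] + SEQ[13:]           # drop residues 9-13
    mover_st = build_peptide(SEQ, PHIPSI, id="m2")
    ch = mover_st.models[0].chains[0]
    ch.residues = [r for i, r in enumerate(ch.residues) if not 8 <= i < 13]
    res = align_by_sequence(varied_chain, ch)
    mover_numbers = {p[1][2] for p in res.pairs}
    assert not mover_numbers & {9, 10, 11, 12, 13}
    assert res.rmsd == pytest.approx(0.0, abs=1e-9)
    assert res.n_aligned == len(SEQ) - 5


def test_sequence_alignment_master_range(varied_chain):
    copy = build_peptide(SEQ, PHIPSI, id="c2").models[0].chains[0]
    res = align_by_sequence(varied_chain, copy,
                            Selection(residue_ranges=[(5, 15)]))
    assert all(5 <= p[0][2] <= 15 for p in res.pairs)
    assert res.n_aligned == 11


def test_residue_by_residue(varied_chain):
    res = align_residue_by_residue(varied_chain, [(1, 20)],
                                   varied_chain, [(1, 20)])
    assert res.rmsd == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError, match="counts"):
        align_residue_by_residue(varied_chain, [(1, 20)],
                                 varied_chain, [(1, 19)])


def test_residue_by_residue_recovers_rigid_motion(helix12):
    moved = helix12.copy()
    rot = rotation_about_axis([1, 1, 0], 25.0)
    t = np.array([4.0, 0.0, -2.0])
    for a in moved.atoms():
        a.coord = rot @ a.coord + t
    res = align_residue_by_residue(helix12.models[0].chains[0], [(1, 12)],
                                   moved.models[0].chains[0], [(1, 12)])
    assert res.rmsd < 1e-8
    back = apply_transform(moved, res)
    orig = np.array([a.coord for a in helix12.atoms()])
    got = np.array([a.coord for a in back.atoms()])
    assert np.allclose(orig, got, atol=1e-7)


def test_mutual_inverse_transforms(helix12):
    moved = helix12.copy()
    rot = rotation_about_axis([0, 1, 0], 40.0)
    for a in moved.atoms():
        a.coord = rot @ a.coord + np.array([1.0, 2.0, 3.0])
    ch_a = helix12.models[0].chains[0]
    ch_b = moved.models[0].chains[0]
    fwd = align_residue_by_residue(ch_a, [(1, 12)], ch_b, [(1, 12)])
    bwd = align_residue_by_residue(ch_b, [(1, 12)], ch_a, [(1, 12)])
    assert np.allclose(fwd.rotation @ bwd.rotation, np.eye(3), atol=1e-6)
    assert np.allclose(fwd.rotation @ bwd.translation + fwd.translation,
                       0.0, atol=1e-6)


def test_mode_agreement_on_identical_sequences(varied_chain):
    copy = build_peptide(SEQ, PHIPSI, id="c3").models[0].chains[0]
    seq_res = align_by_sequence(varied_chain, copy)
    rbr_res = align_residue_by_residue(varied_chain, [(1, 20)], copy, [(1, 20)])
    assert abs(seq_res.rmsd - rbr_res.rmsd) < 1e-9


def test_align_multiple_isolated_failures(varied_chain):
    good = build_peptide(SEQ, PHIPSI, id="g").models[0].chains[0]
    tiny = build_peptide("AG", [(-57, -47)] * 2, id="t").models[0].chains[0]
    results = align_multiple(varied_chain, [good, tiny], mode="sequence")
    assert results[0].rmsd == pytest.approx(0.0, abs=1e-9)
    assert isinstance(results[1], Exception)


def test_align_multiple_recovers_transforms(helix12):
    movers = []
    rots = []
    for i, ang in enumerate((15.0, 75.0, 140.0)):
        rot = rotation_about_axis([0, 0, 1], ang)
        rots.append(rot)
        m = helix12.copy()
        for a in m.atoms():
            a.coord = rot @ a.coord
        movers.append(m.models[0].chains[0])
    results = align_multiple(helix12.models[0].chains[0], movers,
                             mode="residue", ranges=[[(1, 12)]])
    for rot, res in zip(rots, results):
        assert np.allclose(res.rotation, rot.T, atol=1e-7)
        assert res.rmsd < 1e-8
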