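import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from structbatch.structure_io import (PDBParseError, Selection,
                                      append_structures, extract_sequence,
                                      parse_pdb, resolve_selection, write_pdb)
from structbatch.fixtures import build_helix, build_peptide

MINIMAL = ("ATOM      1  CA  ALA A   1      11.104   6.134  -6.504"
           "  1.00  0.00           C\n")


def test_minimal_atom_record():
    s = parse_pdb(MINIMAL, "mini")
    assert len(s.models) == 1
    chains = s.models[0].chains
    assert len(chains) == 1 and chains[0].id == "A"
    assert len(chains[0].residues) == 1
    assert chains[0].residues[0].atoms[0].name == "CA"


def test_multi_model_nmr_style():
    text = "MODEL        1\n" + MINIMAL + "ENDMDL\n" \
           "MODEL        2\n" + MINIMAL + "ENDMDL\nEND\n"
    s = parse_pdb(text, "nmr")
    assert len(s.models) == 2
    # analyses default to model 1
    assert len(s.residues(model=0)) == 1


def test_write_parse_round_trip_bit_exact():
    helix = build_helix(12)
    text = write_pdb(helix)
    back = parse_pdb(text, "helix")
    a0 = helix.atoms()
    a1 = back.atoms()
    assert len(a0) == len(a1)
    for x, y in zip(a0, a1):
        assert x.name == y.name
        # PDB precision is 3 decimals; a re-write must be identical
        assert np.allclose(np.round(x.coord, 3), y.coord, atol=0.0)
    assert write_pdb(back) == write_pdb(parse_pdb(write_pdb(back), "helix"))


def test_altloc_highest_occupancy_then_lexicographic():
    text = (
        "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C\n"
        "ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.60  0.00           C\n"
        "ATOM      3  CB AALA A   1       2.000   0.000   0.000  0.50  0.00           C\n"
        "ATOM      4  CB BALA A   1       3.000   0.000   0.000  0.50  0.00           C\n")
    r = parse_pdb(text, "alt").residues()[0]
    assert r.atom("CA").coord[0] == pytest.approx(1.0)   # occupancy 0.6 wins
    assert r.atom("CB").coord[0] == pytest.approx(2.0)   # tie -> altloc A


def test_parse_errors():
    with pytest.raises(PDBParseError, match="no ATOM"):
        parse_pdb("HEADER    NOTHING\nEND\n", "empty")
    bad = MINIMAL + "ATOM      2  CB  ALA A   1      xx.x\n"
    with pytest.raises(PDBParseError, match="line 2"):
        parse_pdb(bad, "bad")


def test_append_identity_and_conservation(helix12):
    single = append_structures([helix12])
    assert len(single.residues()) == len(helix12.residues())
    other = build_helix(8, id="helix8")
    both = append_structures([helix12, other])
    assert set(both.structure_ids) == {"helix", "helix8"}
    assert len(both.residues()) == 20
    with pytest.raises(ValueError, match="duplicate"):
        append_structures([helix12, helix12])


def test_append_does_not_mutate_inputs(helix12):
    before = np.array([a.coord for a in helix12.atoms()]).copy()
    append_structures([helix12, build_helix(8, id="b")])
    after = np.array([a.coord for a in helix12.atoms()])
    assert np.array_equal(before, after)


def test_append_translated_copy_rmsd_equals_displacement(helix12):
    moved = helix12.copy()
    moved.id = "moved"
    shift = np.array([3.0, 4.0, 0.0])      # |shift| = 5
    for a in moved.atoms():
        a.coord = a.coord + shift
        a.coord = np.asarray(a.coord)
    for ch in moved.models[0].chains:
        ch.structure_id = "moved"
        for r in ch.residues:
            r.structure_id = "moved"
    both = append_structures([helix12, moved])
    ca = np.array([a.coord for r in both.residues() for a in r.atoms
                   if r.structure_id == "helix"])
    cb = np.array([a.coord for r in both.residues() for a in r.atoms
                   if r.structure_id == "moved"])
    rmsd = float(np.sqrt(((ca - cb) ** 2).sum(axis=1).mean()))
    assert rmsd == pytest.approx(5.0, abs=1e-9)


def test_extract_sequence_mapping_and_gap():
    pep = build_peptide("AGY", [(-57, -47)] * 3)
    seq, nums = extract_sequence(pep, "A")
    assert seq == "AGY" and nums == [1, 2, 3]
    gap = build_peptide("AG", [(-57, -47)] * 2, start_number=10)
    gap.models[0].chains[0].residues[1].number = 15
    seq, nums = extract_sequence(gap, "A")
    assert seq == "AG" and nums == [10, 15]


def test_extract_sequence_nonstandard_and_het():
    text = (MINIMAL.replace("ALA A   1", "MSE A   2") + MINIMAL +
            "HETATM    9  O   HOH A  99      10.000   1.000   1.000  1.00  0.00           O\n")
    s = parse_pdb(text, "mix")
    seq, nums = extract_sequence(s, "A")
    assert seq == "XA"      # MSE -> X; water excluded
    with pytest.raises(KeyError, match="available chains"):
        extract_sequence(s, "Z")


def test_resolve_selection_semantics(helix12):
    # empty ranges + chain stated -> whole chain
    assert len(resolve_selection(helix12, Selection(chain_id="A"))) == 12
    # all-default selection -> nothing
    assert resolve_selection(helix12, Selection()) == []
    got = resolve_selection(helix12, Selection(chain_id="A",
                                               residue_ranges=[(1, 10), (5, 12)]))
    brute = {r.number for r in helix12.residues()
             if 1 <= r.number <= 10 or 5 <= r.number <= 12}
    assert [r.number for r in got] == sorted(brute)


@settings(max_examples=25, deadline=None)
@given(st.lists(st.tuples(st.integers(1, 12), st.integers(1, 12)),
                min_size=1, max_size=4))
def test_resolve_selection_order_independent_and_idempotent(ranges):
    helix = build_helix(12)
    sel_fwd = Selection(chain_id="A", residue_ranges=ranges)
    sel_rev = Selection(chain_id="A", residue_ranges=list(reversed(ranges)))
    a = [r.number for r in resolve_selection(helix, sel_fwd)]
    b = [r.number for r in resolve_selection(helix, sel_rev)]
    assert a == b
    assert a == sorted(set(a))
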