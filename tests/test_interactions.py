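import itertools

import numpy as np
import pytest

from structbatch import chemistry as chem
from structbatch.fixtures import build_interface_pair, build_ligand_complex
from structbatch.interactions import (INTERACTION_TYPES, InteractionThresholds,
                                      find_interactions, interaction_network,
                                      network_to_json, residues_within_radius)
from structbatch.structure_io import Selection

SEL_A = Selection(chain_id="A")
SEL_B = Selection(chain_id="B")

ALL_TYPES = ["salt bridge", "hbond", "contact", "pi-stacking", "pi-cation",
             "halogen"]
CANONICAL = {"salt bridge": "ionic", "hbond": "hbond", "contact": "contact",
             "pi-stacking": "pi_stacking", "pi-cation": "pi_cation",
             "halogen": "halogen"}


@pytest.mark.parametrize("wanted", ALL_TYPES)
def test_each_type_detected_exactly_once_no_false_positives(wanted):
    st = build_interface_pair([wanted])
    counts = find_interactions(st, SEL_A, SEL_B).counts()
    assert counts[CANONICAL[wanted]] == 1
    for t in INTERACTION_TYPES:
        if t != CANONICAL[wanted]:
            assert counts[t] == 0, f"false positive {t} for planted {wanted}"


def test_all_six_together():
    st = build_interface_pair(ALL_TYPES)
    counts = find_interactions(st, SEL_A, SEL_B).counts()
    for t in ALL_TYPES:
        assert counts[CANONICAL[t]] == 1


def test_far_apart_residues_no_interactions():
    st = build_interface_pair([])
    assert find_interactions(st, SEL_A, SEL_B).interactions == []


def test_overlapping_sets_rejected():
    st = build_interface_pair(["contact"])
    with pytest.raises(ValueError, match="overlap"):
        find_interactions(st, SEL_A, SEL_A)


def test_unknown_threshold_key_rejected():
    with pytest.raises(KeyError, match="unknown threshold"):
        InteractionThresholds.from_mapping({"hbonds": 3.8})


def test_swap_symmetry():
    st = build_interface_pair(ALL_TYPES)
    ab = find_interactions(st, SEL_A, SEL_B)
    ba = find_interactions(st, SEL_B, SEL_A)
    assert {i.pair_key for i in ab.interactions} == \
        {(t, b, a) for t, a, b in (i.pair_key for i in ba.interactions)}


def test_threshold_monotonicity():
    st = build_interface_pair(ALL_TYPES)
    small = find_interactions(st, SEL_A, SEL_B, InteractionThresholds())
    big = find_interactions(st, SEL_A, SEL_B, InteractionThresholds(
        hbond=4.5, salt_bridge=7.0, contact=5.0, halogen=4.5,
        pi_cation=7.0, pi_stacking=6.5))
    small_keys = {i.pair_key for i in small.interactions}
    big_keys = {i.pair_key for i in big.interactions}
    # enlarging thresholds never removes a specific interaction
    for key in small_keys:
        if key[0] != "contact":     # contacts may be re-explained
            assert key in big_keys


def brute_force_scan(structure, thresholds):
    """Independent all-pairs re-implementation of the distance rules."""
    chains = structure.models[0].chains
    res_a = chains[0].residues
    res_b = chains[1].residues
    found = set()
    for ra, rb in itertools.product(res_a, res_b):
        specific = set()
        for x in chem.donor_atoms(ra):
            for y in chem.acceptor_atoms(rb):
                if np.linalg.norm(x.coord - y.coord) <= thresholds.hbond:
                    found.add(("hbond", ra.key, rb.key))
                    specific.add((x.name, y.name))
        for x in chem.acceptor_atoms(ra):
            for y in chem.donor_atoms(rb):
                if np.linalg.norm(x.coord - y.coord) <= thresholds.hbond:
                    found.add(("hbond", ra.key, rb.key))
                    specific.add((x.name, y.name))
        for x in chem.cation_atoms(ra) + chem.anion_atoms(ra):
            for y in chem.cation_atoms(rb) + chem.anion_atoms(rb):
                opposite = ({x.name} <= {"NZ", "NE", "NH1", "NH2"}) != \
                           ({y.name} <= {"NZ", "NE", "NH1", "NH2"})
                if opposite and np.linalg.norm(x.coord - y.coord) <= \
                        thresholds.salt_bridge:
                    found.add(("ionic", ra.key, rb.key))
                    specific.add((x.name, y.name))
        for x in ra.heavy_atoms():
            for y in rb.heavy_atoms():
                hx = x.element.upper() in ("F", "CL", "BR", "I")
                hy = y.element.upper() in ("F", "CL", "BR", "I")
                ax = x.element.upper() in ("O", "N", "S")
                ay = y.element.upper() in ("O", "N", "S")
                if ((hx and ay) or (hy and ax)) and \
                        np.linalg.norm(x.coord - y.coord) <= thresholds.halogen:
                    found.add(("halogen", ra.key, rb.key))
                    specific.add((x.name, y.name))
        for x in chem.cation_atoms(ra):
            for _, cen in chem.aromatic_rings(rb):
                if np.linalg.norm(x.coord - cen) <= thresholds.pi_cation:
                    found.add(("pi_cation", ra.key, rb.key))
        for _, cen in chem.aromatic_rings(ra):
            for y in chem.cation_atoms(rb):
                if np.linalg.norm(cen - y.coord) <= thresholds.pi_cation:
                    found.add(("pi_cation", ra.key, rb.key))
        for _, ca in chem.aromatic_rings(ra):
            for _, cb in chem.aromatic_rings(rb):
                if np.linalg.norm(ca - cb) <= thresholds.pi_stacking:
                    found.add(("pi_stacking", ra.key, rb.key))
        for x in ra.heavy_atoms():
            for y in rb.heavy_atoms():
                if np.linalg.norm(x.coord - y.coord) <= thresholds.contact \
                        and (x.name, y.name) not in specific:
                    found.add(("contact", ra.key, rb.key))
    return found


@pytest.mark.parametrize("wanted", [["salt bridge"], ["hbond"],
                                    ["pi-stacking"], ALL_TYPES])
def test_brute_force_oracle_equivalence(wanted):
    st = build_interface_pair(wanted)
    thresholds = InteractionThresholds()
    iset = find_interactions(st, SEL_A, SEL_B, thresholds)
    assert {i.pair_key for i in iset.interactions} == \
        brute_force_scan(st, thresholds)


def test_his_neutral_by_default():
    st = build_interface_pair(["salt bridge"])
    # replace the Lys label by His semantics: a His at the same spot is not
    # cationic unless the flag is set
    lys = st.models[0].chains[0].residues[0]
    assert chem.cation_atoms(lys) != []
    lys.type = "HIS"
    assert chem.cation_atoms(lys) == []
    assert chem.cation_atoms(lys, his_charged=True) == []   # no ND1/NE2 atoms


def test_network_document():
    st = build_interface_pair(["salt bridge"])
    iset = find_interactions(st, SEL_A, SEL_B)
    g = interaction_network(iset)
    assert g.number_of_nodes() == 2 and g.number_of_edges() == 1
    (_, _, data), = g.edges(data=True)
    assert data["type"] == "ionic" and data["color"] == "cyan"
    empty = interaction_network(find_interactions(
        build_interface_pair([]), SEL_A, SEL_B))
    assert empty.number_of_nodes() == 0 and empty.number_of_edges() == 0
    assert "nodes" in network_to_json(g)


def test_parallel_edges_for_coexisting_types():
    st = build_interface_pair(["salt bridge"])
    # widen the hbond cutoff so the same Lys NZ / Asp OD1 pair also counts
    # as donor/acceptor: two typed parallel edges between two nodes
    iset = find_interactions(st, SEL_A, SEL_B,
                             InteractionThresholds(hbond=5.0))
    assert iset.counts()["ionic"] == 1 and iset.counts()["hbond"] == 1
    g = interaction_network(iset)
    assert g.number_of_nodes() == 2 and g.number_of_edges() == 2


def test_residues_within_radius():
    st = build_ligand_complex(near=3.0, far=9.0)
    centre = Selection(chain_id="A", residue_types=["LIG"])
    near = residues_within_radius(st, centre, 4.0)
    assert [r.number for r in near] == [1]
    assert residues_within_radius(st, centre, 0.0) == []
    everything = residues_within_radius(st, centre, 1e6)
    assert [r.number for r in everything] == [1, 2]
    with pytest.raises(ValueError, match="no residues"):
        residues_within_radius(st, Selection(chain_id="Z"), 4.0)
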