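"""Molecular graph engine: formula, mass, DBE, rings, CIP, SMILES."""

import warnings

import pytest

from pkstereo.cip import CIPIncompleteError, assign_cip, rank_substituents
from pkstereo.molgraph import (
    IMPLICIT_H,
    GraphError,
    MolecularGraph,
    ValenceError,
    count_double_bonds,
    degrees_of_unsaturation,
    macrocycle_size,
    molecular_formula,
    monoisotopic_mass,
    perceive_rings,
)
from pkstereo.smiles import write_smiles
from pkstereo.synth import make_random_molecule


def _chain(n):
    g = MolecularGraph()
    atoms = [g.add_atom("C") for _ in range(n)]
    for a, b in zip(atoms, atoms[1:]):
        g.add_bond(a, b)
    return g, atoms


# -- formula / mass / DBE -------------------------------------------------


def test_methane_formula():
    g = MolecularGraph()
    g.add_atom("C")
    assert molecular_formula(g) == "CH4"


def test_valence_violation_names_the_atom():
    g = MolecularGraph()
    c = g.add_atom("C")
    for _ in range(3):
        o = g.add_atom("O")
        g.add_bond(c, o, 2)
    with pytest.raises(ValenceError, match="atom 0"):
        molecular_formula(g)


@pytest.mark.parametrize(
    "formula,adduct,mass",
    [
        ("H2O", "none", 18.0106),
        ("C41H70O11", "Na", 761.4816),
        ("", "none", 0.0),
    ],
)
def test_monoisotopic_masses(formula, adduct, mass):
    assert monoisotopic_mass(formula, adduct) == pytest.approx(mass, abs=1e-4)


def test_mass_is_additive():
    assert monoisotopic_mass("C6H12O6") == pytest.approx(
        monoisotopic_mass("C3H6O3") + monoisotopic_mass("C3H6O3"), abs=1e-9
    )


def test_unknown_element_raises():
    with pytest.raises(ValueError, match="unknown element"):
        monoisotopic_mass("C2U3")


@pytest.mark.parametrize(
    "formula,dbe", [("C41H70O11", 7), ("CH4", 0), ("C6H6", 4), ("C5H5N", 4)]
)
def test_degrees_of_unsaturation(formula, dbe):
    assert degrees_of_unsaturation(formula) == dbe


def test_dbe_scope_is_chno():
    with pytest.raises(ValueError, match="outside C/H/N/O"):
        degrees_of_unsaturation("CH4S")


# -- rings ----------------------------------------------------------------


def test_cyclohexane_has_one_six_ring():
    g, atoms = _chain(6)
    g.add_bond(atoms[-1], atoms[0])
    rings = perceive_rings(g)
    assert [len(r) for r in rings] == [6]


def test_acyclic_chain_has_no_rings():
    g, _ = _chain(5)
    assert perceive_rings(g) == []


def test_toy_lactone_macrocycle_size():
    # 6-membered lactone: ring O + 5 C, exocyclic carbonyl O
    g, atoms = _chain(5)
    o_ring = g.add_atom("O")
    g.add_bond(atoms[-1], o_ring)
    g.add_bond(o_ring, atoms[0])
    o_carbonyl = g.add_atom("O")
    g.add_bond(atoms[0], o_carbonyl, 2)
    assert macrocycle_size(g, (atoms[0], o_ring)) == 6


def test_macrocycle_requires_a_cyclic_bond():
    g, atoms = _chain(4)
    with pytest.raises(GraphError, match="not in any cycle"):
        macrocycle_size(g, (atoms[0], atoms[1]))


# -- CIP ------------------------------------------------------------------


def test_textbook_forced_s_center():
    """Bromochlorofluoromethane: Br>Cl>F>H counterclockwise from lowest = S."""
    g = MolecularGraph()
    c = g.add_atom("C")
    br, cl, f = g.add_atom("Br"), g.add_atom("Cl"), g.add_atom("F")
    for x in (br, cl, f):
        g.add_bond(c, x)
    g.set_stereocenter(c, (br, cl, f, IMPLICIT_H), -1)
    assert assign_cip(g) == {c: "S"}
    g.set_stereocenter(c, (br, cl, f, IMPLICIT_H), +1)
    assert assign_cip(g) == {c: "R"}


def test_cip_incomplete_on_identical_branches():
    # 2-propanol: the two methyls are indistinguishable
    g = MolecularGraph()
    c = g.add_atom("C")
    m1, m2, o = g.add_atom("C"), g.add_atom("C"), g.add_atom("O")
    for x in (m1, m2, o):
        g.add_bond(c, x)
    with pytest.raises(CIPIncompleteError):
        rank_substituents(g, c, (m1, m2, o, IMPLICIT_H))


def test_cip_invariant_under_atom_index_permutation():
    """Relabeling atoms must never change a CIP label."""
    import numpy as np

    base = make_random_molecule(16)
    assert base is not None and base.stereocenters
    ref = assign_cip(base)
    rng = np.random.default_rng(1)
    for _ in range(50):
        perm = {
            i: int(p) for i, p in zip(sorted(base.atoms), rng.permutation(len(base.atoms)))
        }
        g = MolecularGraph()
        g._next = len(base.atoms)
        for i, a in base.atoms.items():
            g.atoms[perm[i]] = type(a)(a.element, perm[i], a.label)
            g._adj[perm[i]] = {}
        for i, j, o in base.bonds():
            g._adj[perm[i]][perm[j]] = o
            g._adj[perm[j]][perm[i]] = o
        for i, sc in base.stereocenters.items():
            order = tuple(perm[n] if n != IMPLICIT_H else n for n in sc.order)
            g.set_stereocenter(perm[i], order, sc.parity, sc.provenance)
        labels = assign_cip(g)
        assert {i: labels[perm[i]] for i in ref} == ref


def test_cip_agrees_with_rdkit_on_random_molecules():
    """Spot agreement with an independent toolkit (full sweep in acceptance)."""
    rdkit = pytest.importorskip("rdkit")
    from rdkit import Chem
    from rdkit.Chem import rdCIPLabeler

    checked = 0
    for seed in range(80):
        g = make_random_molecule(seed)
        if g is None:
            continue
        mine = assign_cip(g)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            smi = write_smiles(g, atom_maps=True)
        m = Chem.MolFromSmiles(smi)
        assert m is not None, smi
        rdCIPLabeler.AssignCIPLabels(m)
        ref = {
            a.GetAtomMapNum(): a.GetProp("_CIPCode")
            for a in m.GetAtoms()
            if a.HasProp("_CIPCode")
        }
        for i, lab in mine.items():
            if i in ref:
                assert ref[i] == lab, f"seed {seed} atom {i}: {smi}"
                checked += 1
    assert checked >= 50


# -- SMILES ---------------------------------------------------------------


def test_ethanol_smiles():
    g = MolecularGraph()
    c1, c2, o = g.add_atom("C"), g.add_atom("C"), g.add_atom("O")
    g.add_bond(c1, c2)
    g.add_bond(c2, o)
    assert write_smiles(g) == "CCO"


def test_e_butene_round_trips_as_e():
    rdkit = pytest.importorskip("rdkit")
    from rdkit import Chem

    g = MolecularGraph()
    a = [g.add_atom("C") for _ in range(4)]
    g.add_bond(a[0], a[1])
    g.add_bond(a[1], a[2], 2)
    g.add_bond(a[2], a[3])
    g.set_double_bond_geometry(a[1], a[2], a[0], a[3], "trans")
    m = Chem.MolFromSmiles(write_smiles(g))
    stereo = [b.GetStereo() for b in m.GetBonds() if b.GetStereo() != Chem.BondStereo.STEREONONE]
    assert stereo == [Chem.BondStereo.STEREOE]


def test_unassigned_stereocenter_warns_and_omits_the_mark():
    g = MolecularGraph()
    c = g.add_atom("C")
    br, cl, f = g.add_atom("Br"), g.add_atom("Cl"), g.add_atom("F")
    for x in (br, cl, f):
        g.add_bond(c, x)
    g.set_stereocenter(c, (br, cl, f, IMPLICIT_H), None)
    with pytest.warns(UserWarning, match="unassigned"):
        smi = write_smiles(g)
    assert "@" not in smi


def test_smiles_round_trip_is_lossless_on_marinolides(marinolide_a, marinolide_b_experimental):
    rdkit = pytest.importorskip("rdkit")
    from rdkit import Chem

    for rep, g, _ in (marinolide_a, marinolide_b_experimental):
        m = Chem.MolFromSmiles(rep.smiles)
        assert m is not None
        from rdkit.Chem import rdMolDescriptors

        assert rdMolDescriptors.CalcMolFormula(m) == "C41H70O11"
        centers = Chem.FindMolChiralCenters(m, includeUnassigned=True, useLegacyImplementation=False)
        assert len(centers) == 16


def test_dbe_equals_rings_plus_double_bonds_across_representations(marinolide_a):
    _, g, _ = marinolide_a
    formula = molecular_formula(g)
    assert degrees_of_unsaturation(formula) == len(perceive_rings(g)) + count_double_bonds(g)


def test_dbe_ring_identity_on_random_molecules():
    for seed in range(40):
        g = make_random_molecule(seed)
        if g is None:
            continue
        formula = molecular_formula(g)
        assert degrees_of_unsaturation(formula) == len(perceive_rings(g)) + count_double_bonds(g)
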