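"""Molecular graph engine for CHO(N) natural products.

The graph is deliberately small in scope: elements C/H/O (plus N and Na for
formula arithmetic), bond orders 1 and 2, implicit hydrogens completed from
standard valences, tetrahedral stereocenters stored as neighbor-order
parities, and double-bond geometry stored as a cis/trans relation between
one reference substituent on each end.

Parity convention
-----------------
A stereocenter stores an ordered tuple of its four neighbors (atom indices,
with ``IMPLICIT_H`` standing for the implicit hydrogen) plus ``parity``:

* ``parity = +1`` — viewed from the *last* neighbor in the stored order
  toward the center, the first three neighbors appear counterclockwise.

With the stored order equal to the CIP priority order (highest first) this
makes ``+1`` an *R* center and ``-1`` an *S* center, which is how
:func:`pkstereo.cip.assign_cip` decodes it.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Optional

import networkx as nx

IMPLICIT_H = -1

STANDARD_VALENCE = {"C": 4, "O": 2, "N": 3, "F": 1, "Cl": 1, "Br": 1}

ATOMIC_NUMBER = {"H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "Na": 11, "Cl": 17, "Br": 35}


class ValenceError(ValueError):
    """An atom's bond orders exceed its standard valence."""


class GraphError(ValueError):
    """Structural problem in a molecular graph or an edit on it."""


def _load_masses() -> dict:
    with resources.files("pkstereo.data").joinpath("atomic_masses.json").open() as fh:
        return json.load(fh)


_MASSES: Optional[dict] = None


def atomic_masses() -> dict:
    """Monoisotopic masses pinned in the bundled data file."""
    global _MASSES
    if _MASSES is None:
        _MASSES = _load_masses()
    return _MASSES


@dataclass
class Atom:
    element: str
    index: int
    label: Optional[str] = None  # backbone label such as "C-17"


@dataclass
class StereoCenter:
    order: tuple  # 4 neighbor ids, IMPLICIT_H allowed once
    parity: Optional[int]  # +1 / -1, or None when unassigned
    provenance: str = "unassigned"  # bioinformatic | experimental | unassigned
    descriptor: Optional[str] = None  # cached CIP label once assigned


@dataclass
class DoubleBondGeometry:
    ref_i: int  # substituent of atom i used as the reference
    ref_j: int  # substituent of atom j
    relation: str  # "cis" | "trans" (same side / opposite sides)


class MolecularGraph:
    """Mutable molecular graph with implicit hydrogens."""

    def __init__(self) -> None:
        self.atoms: dict[int, Atom] = {}
        self._adj: dict[int, dict[int, int]] = {}
        self.stereocenters: dict[int, StereoCenter] = {}
        self.double_bond_geometry: dict[tuple, DoubleBondGeometry] = {}
        self._next = 0

    # -- construction -------------------------------------------------
    def add_atom(self, element: str, label: Optional[str] = None) -> int:
        if element not in STANDARD_VALENCE:
            raise GraphError(f"unsupported element {element!r}")
        idx = self._next
        self._next += 1
        self.atoms[idx] = Atom(element, idx, label)
        self._adj[idx] = {}
        return idx

    def add_bond(self, i: int, j: int, order: int = 1) -> None:
        if i == j:
            raise GraphError("self-bond")
        if j in self._adj[i]:
            raise GraphError(f"bond {i}-{j} already present")
        if order not in (1, 2):
            raise GraphError(f"bond order {order} unsupported")
        self._adj[i][j] = order
        self._adj[j][i] = order

    def set_bond_order(self, i: int, j: int, order: int) -> None:
        if j not in self._adj[i]:
            raise GraphError(f"no bond {i}-{j}")
        self._adj[i][j] = order
        self._adj[j][i] = order
        if order != 2:
            self.double_bond_geometry.pop(self._bkey(i, j), None)

    def remove_atom(self, i: int) -> None:
        for j in list(self._adj[i]):
            del self._adj[j][i]
        del self._adj[i]
        del self.atoms[i]
        self.stereocenters.pop(i, None)
        for key in [k for k in self.double_bond_geometry if i in k]:
            del self.double_bond_geometry[key]

    def remove_bond(self, i: int, j: int) -> None:
        if j not in self._adj[i]:
            raise GraphError(f"no bond {i}-{j}")
        del self._adj[i][j]
        del self._adj[j][i]
        self.double_bond_geometry.pop(self._bkey(i, j), None)

    @staticmethod
    def _bkey(i: int, j: int) -> tuple:
        return (i, j) if i < j else (j, i)

    # -- queries ------------------------------------------------------
    def neighbors(self, i: int) -> Iterator[tuple]:
        return iter(sorted(self._adj[i].items()))

    def bond_order(self, i: int, j: int) -> int:
        return self._adj[i].get(j, 0)

    def bonds(self) -> Iterator[tuple]:
        seen = set()
        for i, nbrs in sorted(self._adj.items()):
            for j, order in sorted(nbrs.items()):
                if (j, i) not in seen:
                    seen.add((i, j))
                    yield i, j, order

    def implicit_h(self, i: int) -> int:
        atom = self.atoms[i]
        used = sum(self._adj[i].values())
        h = STANDARD_VALENCE[atom.element] - used
        if h < 0:
            raise ValenceError(
                f"atom {i} ({atom.element}{'/' + atom.label if atom.label else ''}) "
                f"exceeds valence: {used} bond orders"
            )
        return h

    def degree(self, i: int) -> int:
        return len(self._adj[i])

    def validate(self) -> None:
        """Raise on valence violations or a disconnected graph."""
        for i in self.atoms:
            self.implicit_h(i)
        if self.atoms and not nx.is_connected(self.to_networkx()):
            raise GraphError("graph is not connected")

    def atom_by_label(self, label: str) -> int:
        for i, atom in self.atoms.items():
            if atom.label == label:
                return i
        raise KeyError(label)

    # -- stereo -------------------------------------------------------
    def set_stereocenter(
        self,
        i: int,
        order: tuple,
        parity: Optional[int],
        provenance: str = "unassigned",
    ) -> None:
        order = tuple(order)
        if len(order) != 4:
            raise GraphError("stereocenter needs 4 ordered neighbors")
        explicit = [n for n in order if n != IMPLICIT_H]
        if len(set(explicit)) != len(explicit):
            raise GraphError("duplicate stereocenter neighbor")
        for n in explicit:
            if n not in self._adj[i]:
                raise GraphError(f"stereocenter neighbor {n} not bonded to {i}")
        if order.count(IMPLICIT_H) != (1 if len(explicit) == 3 else 0):
            raise GraphError("stereocenter needs 4 neighbors (3 + implicit H allowed)")
        if order.count(IMPLICIT_H) == 1 and self.implicit_h(i) != 1:
            raise GraphError(f"atom {i} has no single implicit H for stereo")
        self.stereocenters[i] = StereoCenter(order, parity, provenance)

    def set_double_bond_geometry(
        self, i: int, j: int, ref_i: int, ref_j: int, relation: str
    ) -> None:
        if self.bond_order(i, j) != 2:
            raise GraphError(f"bond {i}-{j} is not a double bond")
        if relation not in ("cis", "trans"):
            raise GraphError(f"bad relation {relation!r}")
        if ref_i not in self._adj[i] or ref_j not in self._adj[j]:
            raise GraphError("geometry references must be bonded substituents")
        key = self._bkey(i, j)
        if key != (i, j):
            i, j, ref_i, ref_j = j, i, ref_j, ref_i
        self.double_bond_geometry[key] = DoubleBondGeometry(ref_i, ref_j, relation)

    # -- derived ------------------------------------------------------
    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(self.atoms)
        G.add_edges_from((i, j, {"order": o}) for i, j, o in self.bonds())
        return G

    def copy(self) -> "MolecularGraph":
        g = MolecularGraph()
        g._next = self._next
        g.atoms = {i: Atom(a.element, a.index, a.label) for i, a in self.atoms.items()}
        g._adj = {i: dict(nbrs) for i, nbrs in self._adj.items()}
        g.stereocenters = {
            i: StereoCenter(s.order, s.parity, s.provenance, s.descriptor)
            for i, s in self.stereocenters.items()
        }
        g.double_bond_geometry = {
            k: DoubleBondGeometry(v.ref_i, v.ref_j, v.relation)
            for k, v in self.double_bond_geometry.items()
        }
        return g

    def formula_counts(self) -> dict:
        counts: dict = {}
        h = 0
        for i, atom in self.atoms.items():
            counts[atom.element] = counts.get(atom.element, 0) + 1
            h += self.implicit_h(i)
        if h:
            counts["H"] = counts.get("H", 0) + h
        return counts


# ---------------------------------------------------------------------------
# formula / mass arithmetic
# ---------------------------------------------------------------------------

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict:
    counts: dict = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def hill_formula(counts: dict) -> str:
    parts = []
    for el in ["C", "H"] + sorted(e for e in counts if e not in ("C", "H")):
        n = counts.get(el, 0)
        if n:
            parts.append(el + (str(n) if n > 1 else ""))
    return "".join(parts)


def molecular_formula(g: MolecularGraph) -> str:
    """Hill-notation molecular formula, implicit hydrogens included."""
    g.validate()
    return hill_formula(g.formula_counts())


def monoisotopic_mass(formula: str, adduct: str = "none") -> float:
    """Monoisotopic mass in Da; ``adduct='Na'`` adds one sodium atom.

    Reported to 4 decimals (round-half-up), matching the convention used for
    "calcd." values in HR-MS work, which ignores the electron mass.
    """
    counts = parse_formula(formula) if formula else {}
    if adduct == "Na":
        counts["Na"] = counts.get("Na", 0) + 1
    elif adduct != "none":
        raise ValueError(f"unsupported adduct {adduct!r}")
    masses = atomic_masses()
    total = 0.0
    for el, n in counts.items():
        if el not in masses:
            raise ValueError(f"unknown element {el!r}")
        total += masses[el] * n
    # round half-up at the 4th decimal
    import math

    return math.floor(total * 1e4 + 0.5) / 1e4


def degrees_of_unsaturation(formula: str) -> int:
    """Ring-plus-double-bond equivalents for a C/H/N/O formula."""
    counts = parse_formula(formula)
    for el in counts:
        if el not in ("C", "H", "N", "O"):
            raise ValueError(f"element {el!r} outside C/H/N/O scope")
    dbe = counts.get("C", 0) - counts.get("H", 0) / 2 + 1 + counts.get("N", 0) / 2
    if dbe != int(dbe):
        raise ValueError(f"non-integer DBE for {formula!r}")
    return int(dbe)


# ---------------------------------------------------------------------------
# ring perception
# ---------------------------------------------------------------------------


def perceive_rings(g: MolecularGraph) -> list:
    """A smallest-set-of-smallest-rings basis as sorted atom-index lists.

    Output ordering is deterministic: rings are sorted by (size, member
    indices), so identical graphs always produce identical output.
    """
    basis = nx.minimum_cycle_basis(g.to_networkx())
    rings = sorted(sorted(c) for c in basis)
    rings.sort(key=lambda c: (len(c), c))
    return rings


def ring_count(g: MolecularGraph) -> int:
    return len(perceive_rings(g))


def macrocycle_size(g: MolecularGraph, bond: tuple) -> int:
    """Size of the smallest cycle containing ``bond`` (i, j)."""
    i, j = bond
    if g.bond_order(i, j) == 0:
        raise GraphError(f"no bond {i}-{j}")
    G = g.to_networkx()
    G.remove_edge(i, j)
    try:
        path = nx.shortest_path(G, i, j)
    except nx.NetworkXNoPath:
        raise GraphError(f"bond {i}-{j} is not in any cycle")
    return len(path)


def count_double_bonds(g: MolecularGraph) -> int:
    return sum(1 for _, _, o in g.bonds() if o == 2)


@dataclass
class FormulaReport:
    formula: str
    monoisotopic_mass: float
    adduct_mass: dict  # adduct -> Da
    dbe: int
    ring_count: int
    ring_sizes: list
    macrocycle_size: Optional[int] = None


def formula_report(g: MolecularGraph, ester_bond: Optional[tuple] = None) -> FormulaReport:
    """Formula, masses, DBE and ring metrics for one molecular graph."""
    formula = molecular_formula(g)
    rings = perceive_rings(g)
    return FormulaReport(
        formula=formula,
        monoisotopic_mass=monoisotopic_mass(formula),
        adduct_mass={"Na": monoisotopic_mass(formula, "Na")},
        dbe=degrees_of_unsaturation(formula),
        ring_count=len(rings),
        ring_sizes=[len(r) for r in rings],
        macrocycle_size=macrocycle_size(g, ester_bond) if ester_bond else None,
    )


def graph_to_dict(g: MolecularGraph) -> dict:
    """JSON-serializable dump of the graph (documented schema, version 1)."""
    return {
        "schema": "pkstereo-graph-1",
        "atoms": [
            {
                "index": i,
                "element": a.element,
                "label": a.label,
                "implicit_h": g.implicit_h(i),
            }
            for i, a in sorted(g.atoms.items())
        ],
        "bonds": [[i, j, o] for i, j, o in g.bonds()],
        "stereocenters": {
            str(i): {
                "order": list(sc.order),
                "parity": sc.parity,
                "provenance": sc.provenance,
                "descriptor": sc.descriptor,
            }
            for i, sc in sorted(g.stereocenters.items())
        },
        "double_bond_geometry": {
            f"{i}-{j}": {"ref_i": geo.ref_i, "ref_j": geo.ref_j, "relation": geo.relation}
            for (i, j), geo in sorted(g.double_bond_geometry.items())
        },
    }
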