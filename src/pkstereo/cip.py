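"""Native Cahn-Ingold-Prelog R/S assignment (Sequence Rules 1a, 1b, 2).

The implementation builds the hierarchical digraph for each substituent
branch of a stereocenter (duplicate atoms for multiple bonds and ring
closures, no children on duplicates) and compares branches *sphere by
sphere* (breadth-first).  The breadth-first order matters: a depth-first
subtree comparison can rank two branches differently from CIP whenever a
sphere decides before a deeper, heavier atom is reached, and such cases
occur in real polyketide backbones.

Covered: Rule 1a (atomic number, explored in spheres), Rule 1b (duplicate
nodes rank below real nodes of the same atomic number; among duplicates,
the one whose original atom is closer to the root ranks higher), Rule 2
(mass — vacuous here because no isotopes are representable).  Rules 3-5 are
out of scope; if two branches remain indistinguishable the engine raises
:class:`CIPIncompleteError` rather than guessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cmp_to_key
from typing import Optional

from .molgraph import ATOMIC_NUMBER, IMPLICIT_H, MolecularGraph


class CIPIncompleteError(ValueError):
    """Two branches cannot be discriminated by the implemented rules."""

    def __init__(self, center: int, message: Optional[str] = None):
        self.center = center
        super().__init__(message or f"CIP-incomplete: cannot rank branches at atom {center}")


@dataclass
class _Node:
    z: int
    dup: bool = False
    dup_sphere: int = 0  # sphere of the duplicated original (Rule 1b)
    children: list = field(default_factory=list)


def _h_node() -> _Node:
    return _Node(z=1)


def _build_branch(g: MolecularGraph, center: int, first: int) -> _Node:
    """Hierarchical digraph branch rooted at neighbor ``first`` of ``center``."""
    if first == IMPLICIT_H:
        return _h_node()

    def expand(atom: int, parent: int, path: dict, sphere: int) -> _Node:
        node = _Node(z=ATOMIC_NUMBER[g.atoms[atom].element])
        kids = []
        path = dict(path)
        path[atom] = sphere
        for nb, order in g.neighbors(atom):
            if nb == parent:
                # pi bond(s) back to the parent contribute duplicate nodes
                for _ in range(order - 1):
                    kids.append(
                        _Node(
                            z=ATOMIC_NUMBER[g.atoms[nb].element],
                            dup=True,
                            dup_sphere=sphere - 1,
                        )
                    )
                continue
            if nb in path:
                # ring closure: duplicate of the ancestor, plus pi duplicates
                for _ in range(order):
                    kids.append(
                        _Node(
                            z=ATOMIC_NUMBER[g.atoms[nb].element],
                            dup=True,
                            dup_sphere=path[nb],
                        )
                    )
                continue
            kids.append(expand(nb, atom, path, sphere + 1))
            for _ in range(order - 1):
                kids.append(
                    _Node(
                        z=ATOMIC_NUMBER[g.atoms[nb].element],
                        dup=True,
                        dup_sphere=sphere + 1,
                    )
                )
        for _ in range(g.implicit_h(atom)):
            kids.append(_h_node())
        node.children = kids
        return node

    # the double bond center-first, if any, adds a pi duplicate inside the branch
    return expand(first, center, {center: 0}, 1)


def _key_1a(n: _Node) -> tuple:
    return (n.z,)


def _key_1b(n: _Node) -> tuple:
    # real atoms outrank duplicates of equal z; nearer originals outrank
    # farther ones (encoded so that a *larger* key means higher priority)
    return (n.z, 0 if not n.dup else -1, -n.dup_sphere if n.dup else 0)


def _compare(a: _Node, b: _Node, key, memo: dict) -> int:
    mk = (id(a), id(b), key)
    if mk in memo:
        return memo[mk]
    result = _compare_impl(a, b, key, memo)
    memo[mk] = result
    memo[(id(b), id(a), key)] = -result
    return result


def _compare_impl(a: _Node, b: _Node, key, memo: dict) -> int:
    ka, kb = key(a), key(b)
    if ka != kb:
        return 1 if ka > kb else -1
    level_a, level_b = [a], [b]
    child_cmp = cmp_to_key(lambda x, y: _compare(x, y, key, memo))
    pad = (0,) + (0,) * (len(ka) - 1)
    while level_a or level_b:
        next_a: list = []
        next_b: list = []
        seq_a: list = []
        seq_b: list = []
        for pa, pb in zip(level_a, level_b):
            ca = sorted(pa.children, key=child_cmp, reverse=True)
            cb = sorted(pb.children, key=child_cmp, reverse=True)
            width = max(len(ca), len(cb))
            seq_a.extend([key(c) for c in ca] + [pad] * (width - len(ca)))
            seq_b.extend([key(c) for c in cb] + [pad] * (width - len(cb)))
            next_a.extend(ca)
            next_b.extend(cb)
        if seq_a != seq_b:
            return 1 if seq_a > seq_b else -1
        level_a, level_b = next_a, next_b
    return 0


def compare_branches(g: MolecularGraph, center: int, n1: int, n2: int) -> int:
    """CIP order of two substituents of ``center``: 1 if n1 > n2, -1, or 0."""
    a = _build_branch(g, center, n1)
    b = _build_branch(g, center, n2)
    memo: dict = {}
    result = _compare(a, b, _key_1a, memo)
    if result == 0:
        result = _compare(a, b, _key_1b, {})
    return result


def rank_substituents(g: MolecularGraph, center: int, neighbors: tuple) -> list:
    """Neighbors sorted by descending CIP priority; raises on any tie."""
    branches = {n: _build_branch(g, center, n) for n in neighbors}
    memo: dict = {}

    def cmp(n1: int, n2: int) -> int:
        r = _compare(branches[n1], branches[n2], _key_1a, memo)
        if r == 0:
            r = _compare(branches[n1], branches[n2], _key_1b, memo)
        return r

    ordered = sorted(neighbors, key=cmp_to_key(cmp), reverse=True)
    for x, y in zip(ordered, ordered[1:]):
        if cmp(x, y) == 0:
            raise CIPIncompleteError(center)
    return ordered


def _perm_sign(src: tuple, dst: tuple) -> int:
    perm = [src.index(x) for x in dst]
    sign = 1
    for i in range(len(perm)):
        for j in range(i + 1, len(perm)):
            if perm[i] > perm[j]:
                sign = -sign
    return sign


def label_stereocenter(g: MolecularGraph, center: int) -> str:
    """CIP label (R/S) for one stereocenter with a defined parity."""
    sc = g.stereocenters[center]
    if sc.parity is None:
        raise ValueError(f"stereocenter {center} has no defined parity")
    priority = tuple(rank_substituents(g, center, sc.order))
    parity_on_priority = sc.parity * _perm_sign(sc.order, priority)
    return "R" if parity_on_priority > 0 else "S"


def assign_cip(g: MolecularGraph) -> dict:
    """R/S labels for every stereocenter with a defined parity.

    Unassigned centers (parity ``None``) are skipped; their descriptor stays
    ``None``.  Raises :class:`CIPIncompleteError` when the implemented rules
    cannot discriminate two branches at some center.
    """
    labels: dict = {}
    for i, sc in sorted(g.stereocenters.items()):
        if sc.parity is None:
            sc.descriptor = None
            continue
        labels[i] = label_stereocenter(g, i)
        sc.descriptor = labels[i]
    return labels
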