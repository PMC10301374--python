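"""Deterministic stereo-SMILES writer.

Atom ordering follows a Morgan-style canonical ranking (initial invariants
refined by neighbor-rank multisets, ties broken by lowest atom index, then
re-refined), so identical graphs always serialize identically.  Tetrahedral
parities are emitted as ``@``/``@@`` and double-bond geometry as ``/``/``\\``
directional bonds, including on ring-closure digits when the spanning tree
cuts a geometry-bearing bond.

There is intentionally no SMILES reader here; round-trip tests parse the
output with an independent cheminformatics toolkit.
"""

from __future__ import annotations

import warnings
from collections import defaultdict

from .cip import _perm_sign
from .molgraph import ATOMIC_NUMBER, IMPLICIT_H, GraphError, MolecularGraph


def canonical_ranks(g: MolecularGraph) -> dict:
    """Dense canonical ranks (0..n-1, unique) for every atom."""
    atoms = sorted(g.atoms)

    def dense(keys: dict) -> dict:
        uniq = sorted(set(keys.values()))
        pos = {k: r for r, k in enumerate(uniq)}
        return {i: pos[keys[i]] for i in atoms}

    keys = {
        i: (
            ATOMIC_NUMBER[g.atoms[i].element],
            g.degree(i),
            g.implicit_h(i),
            sum(o for _, o in g.neighbors(i)),
        )
        for i in atoms
    }
    ranks = dense(keys)

    def refine(ranks: dict) -> dict:
        while True:
            keys = {
                i: (ranks[i], tuple(sorted((o, ranks[j]) for j, o in g.neighbors(i))))
                for i in atoms
            }
            new = dense(keys)
            if new == ranks:
                return ranks
            ranks = new

    ranks = refine(ranks)
    while len(set(ranks.values())) < len(atoms):
        # break the lowest-ranked remaining tie at the lowest atom index
        by_rank = defaultdict(list)
        for i in atoms:
            by_rank[ranks[i]].append(i)
        rank, members = min((r, m) for r, m in by_rank.items() if len(m) > 1)
        chosen = min(members)
        keys = {i: (ranks[i], 0 if i == chosen else 1) for i in atoms}
        ranks = refine(dense(keys))
    return ranks


def _build_dirmap(g: MolecularGraph) -> dict:
    """Directed bond -> '/' or '\\' tokens realizing all stored geometries."""
    dirmap: dict = {}
    for (i, j), geo in sorted(g.double_bond_geometry.items()):
        placed = False
        for flip in (False, True):
            updown: dict = {}
            side_ref_i = 1 if flip else -1
            updown[(i, geo.ref_i)] = side_ref_i
            for n, o in g.neighbors(i):
                if n not in (j, geo.ref_i) and o == 1:
                    updown[(i, n)] = -side_ref_i
            side_ref_j = -side_ref_i if geo.relation == "trans" else side_ref_i
            updown[(j, geo.ref_j)] = side_ref_j
            for n, o in g.neighbors(j):
                if n not in (i, geo.ref_j) and o == 1:
                    updown[(j, n)] = -side_ref_j
            trial: dict = {}
            for (d, s), sd in updown.items():
                trial[(s, d)] = "/" if sd == -1 else "\\"
                trial[(d, s)] = "/" if sd == 1 else "\\"
            if all(dirmap.get(k, v) == v for k, v in trial.items()):
                dirmap.update(trial)
                placed = True
                break
        if not placed:
            raise GraphError(f"conflicting double-bond geometry at bond {i}-{j}")
    return dirmap


def write_smiles(g: MolecularGraph, atom_maps: bool = False) -> str:
    """Serialize the graph; warns (and omits the mark) on unassigned stereo.

    With ``atom_maps=True`` every atom is written as a bracket atom carrying
    its graph index as the SMILES atom-map number (explicit H counts
    included), which lets an external parser recover the index mapping.
    """
    g.validate()
    if not g.atoms:
        return ""
    ranks = canonical_ranks(g)
    start = min(g.atoms, key=lambda i: ranks[i])

    parent: dict = {start: None}
    children: dict = defaultdict(list)
    ring_partners: dict = defaultdict(list)  # emission order per atom
    visit_pos: dict = {}
    ring_bonds: set = set()

    def dfs(u: int) -> None:
        visit_pos[u] = len(visit_pos)
        for v, _ in sorted(g.neighbors(u), key=lambda t: ranks[t[0]]):
            if v == parent.get(u):
                continue
            if v in visit_pos:
                key = (v, u) if visit_pos[v] < visit_pos[u] else (u, v)
                if key not in ring_bonds:
                    ring_bonds.add(key)
                continue
            parent[v] = u
            children[u].append(v)
            dfs(v)

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 4 * len(g.atoms) + 100))
    try:
        dfs(start)
    finally:
        sys.setrecursionlimit(old_limit)

    for a, b in sorted(ring_bonds, key=lambda ab: (visit_pos[ab[1]], visit_pos[ab[0]])):
        ring_partners[a].append(b)
        ring_partners[b].append(a)

    dirmap = _build_dirmap(g)

    # ring digit allocation
    digit_of: dict = {}
    free: list = []
    next_digit = [1]

    def open_digit(key: tuple) -> int:
        d = free.pop(0) if free else next_digit[0]
        if d == next_digit[0]:
            next_digit[0] += 1
        digit_of[key] = d
        return d

    def close_digit(key: tuple) -> int:
        d = digit_of.pop(key)
        free.append(d)
        free.sort()
        return d

    def digit_str(d: int) -> str:
        return str(d) if d < 10 else f"%{d:02d}"

    def written_order(u: int) -> list:
        order = []
        if parent.get(u) is not None:
            order.append(parent[u])
        if g.implicit_h(u) == 1:
            order.append(IMPLICIT_H)
        order.extend(ring_partners[u])
        order.extend(children[u])
        return order

    def atom_token(u: int) -> str:
        el = g.atoms[u].element
        sc = g.stereocenters.get(u)
        sym = ""
        if sc is None or sc.parity is None:
            if sc is not None:
                warnings.warn(
                    f"stereocenter at atom {u} is unassigned; emitted without a mark",
                    stacklevel=2,
                )
        else:
            w = written_order(u)
            if len(w) != 4:
                raise GraphError(f"stereo atom {u} does not have 4 writable neighbors")
            parity_w = sc.parity * _perm_sign(sc.order, tuple(w))
            sym = "@" if parity_w == -1 else "@@"
        if not sym and not atom_maps:
            return el
        nh = g.implicit_h(u)
        h = "" if nh == 0 else ("H" if nh == 1 else f"H{nh}")
        mapno = f":{u}" if atom_maps else ""
        return f"[{el}{sym}{h}{mapno}]"

    def bond_prefix(frm: int, to: int) -> str:
        if g.bond_order(frm, to) == 2:
            return "="
        return dirmap.get((frm, to), "")

    def emit(u: int) -> str:
        out = [atom_token(u)]
        for v in ring_partners[u]:
            key = (u, v) if (u, v) in ring_bonds else (v, u)
            if key in digit_of:
                out.append(dirmap.get((u, v), "") + digit_str(close_digit(key)))
            else:
                prefix = "=" if g.bond_order(u, v) == 2 else dirmap.get((u, v), "")
                out.append(prefix + digit_str(open_digit(key)))
        kids = children[u]
        for idx, v in enumerate(kids):
            sub = bond_prefix(u, v) + emit(v)
            out.append(f"({sub})" if idx < len(kids) - 1 else sub)
        return "".join(out)

    sys.setrecursionlimit(max(old_limit, 4 * len(g.atoms) + 100))
    try:
        return emit(start)
    finally:
        sys.setrecursionlimit(old_limit)
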