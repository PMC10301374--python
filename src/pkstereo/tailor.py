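"""Post-PKS tailoring: macrolactonization, hemiketal pyran, epoxidation.

The three edits are applied to the molecular graph of the released linear
chain.  Chemically the pyran is thought to form while the chain is still
carrier-bound and the epoxide after release, but the edits commute on this
scaffold, so they are applied in a fixed order (lactonize, hemiketal,
epoxidize) for determinism.

Stereocenters born during tailoring (the hemiketal carbon and the two
epoxide carbons) carry provenance ``unassigned`` unless experimental
configurations are supplied.  Epoxidation of an E-olefin is suprafacial:
the two epoxide centers are constrained to the trans (unlike) relative
configuration, so only the two face-consistent descriptor pairs are
accepted from experiment; a cis pair is rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .build import LinearPolyketide, linear_graph
from .cip import label_stereocenter
from .molgraph import IMPLICIT_H, GraphError, MolecularGraph


class TailoringError(ValueError):
    pass


@dataclass
class TailoringPlan:
    lactonization_site: int
    hemiketal_pair: Optional[tuple] = None  # (ketone position, hydroxyl position)
    epoxidation_bond: Optional[tuple] = None  # (position, position)
    experimental_configs: dict = field(default_factory=dict)  # position -> "R"/"S"

    def to_json(self) -> str:
        return json.dumps(
            {
                "lactonization_site": self.lactonization_site,
                "hemiketal_pair": list(self.hemiketal_pair) if self.hemiketal_pair else None,
                "epoxidation_bond": list(self.epoxidation_bond) if self.epoxidation_bond else None,
                "experimental_configs": {str(k): v for k, v in self.experimental_configs.items()},
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "TailoringPlan":
        d = json.loads(text)
        return cls(
            lactonization_site=d["lactonization_site"],
            hemiketal_pair=tuple(d["hemiketal_pair"]) if d.get("hemiketal_pair") else None,
            epoxidation_bond=tuple(d["epoxidation_bond"]) if d.get("epoxidation_bond") else None,
            experimental_configs={int(k): v for k, v in (d.get("experimental_configs") or {}).items()},
        )


def _backbone(g: MolecularGraph, pos: int) -> int:
    try:
        return g.atom_by_label(f"C-{pos}")
    except KeyError:
        raise TailoringError(f"no backbone carbon C-{pos}")


def _hydroxyl_oxygen(g: MolecularGraph, c: int) -> Optional[int]:
    for n, order in g.neighbors(c):
        if g.atoms[n].element == "O" and order == 1 and g.degree(n) == 1:
            return n
    return None


def _ketone_oxygen(g: MolecularGraph, c: int) -> Optional[int]:
    for n, order in g.neighbors(c):
        if g.atoms[n].element == "O" and order == 2:
            return n
    return None


def hydroxyl_sites(g: MolecularGraph) -> list:
    """Backbone positions currently bearing a free hydroxyl."""
    out = []
    for i, atom in g.atoms.items():
        if atom.label and atom.label.startswith("C-") and _hydroxyl_oxygen(g, i) is not None:
            pos = int(atom.label[2:])
            if pos != 1:  # the carboxyl OH is not a lactonization nucleophile
                out.append(pos)
    return sorted(out)


def macrolactonize(g: MolecularGraph, site: int) -> None:
    """Ester bond between the C-1 carbonyl and the hydroxyl at ``site``.

    Removes the carboxyl OH (water leaves, net -H2O versus acid + alcohol).
    """
    c1 = _backbone(g, 1)
    acid_oh = _hydroxyl_oxygen(g, c1)
    if acid_oh is None:
        raise TailoringError("C-1 carries no free carboxyl hydroxyl (already released?)")
    site_c = _backbone(g, site)
    site_o = _hydroxyl_oxygen(g, site_c)
    if site_o is None:
        raise TailoringError(
            f"C-{site} bears no hydroxyl; valid lactonization sites: "
            + ", ".join(f"C-{p}" for p in hydroxyl_sites(g))
        )
    g.remove_atom(acid_oh)
    g.add_bond(site_o, c1)


def form_hemiketal(g: MolecularGraph, ketone: int, hydroxyl: int) -> int:
    """Intramolecular hemiketal: hydroxyl oxygen adds to the ketone carbon.

    Only the 6-membered (tetrahydropyran) ring is supported; the pair must
    be separated by four backbone bonds.  Returns the new stereocenter (the
    former ketone carbon), registered as ``unassigned``.
    """
    ring_size = abs(ketone - hydroxyl) + 2
    if ring_size != 6:
        raise TailoringError(
            f"hemiketal pair C-{ketone}/C-{hydroxyl} would close a "
            f"{ring_size}-membered ring; only 6-membered pyran hemiketals supported"
        )
    ck = _backbone(g, ketone)
    ko = _ketone_oxygen(g, ck)
    if ko is None:
        raise TailoringError(f"C-{ketone} is not a ketone")
    ch = _backbone(g, hydroxyl)
    ho = _hydroxyl_oxygen(g, ch)
    if ho is None:
        raise TailoringError(f"C-{hydroxyl} bears no hydroxyl")
    g.set_bond_order(ck, ko, 1)
    g.add_bond(ho, ck)
    prev_c = _backbone(g, ketone - 1)
    next_c = _backbone(g, ketone + 1)
    g.set_stereocenter(ck, (ko, ho, prev_c, next_c), None, provenance="unassigned")
    return ck


def _parity_from_coords(center: np.ndarray, pts: list) -> int:
    """Parity under the stored-order convention from 3D positions.

    With neighbors listed in CIP priority order an R center gives a negative
    determinant, hence parity ``-sign(det)``.
    """
    v = [np.asarray(p, dtype=float) - np.asarray(center, dtype=float) for p in pts]
    det = np.linalg.det(np.array([v[0] - v[3], v[1] - v[3], v[2] - v[3]]))
    return -1 if det > 0 else 1


def _epoxide_face_parities(relation: str) -> list:
    """Parity pairs (at the two carbons) for the two oxygenation faces.

    Neighbor orders are fixed as ``[O, other olefin C, geometry reference,
    remaining substituent]`` on each carbon; the olefin geometry constrains
    the relative configuration, leaving exactly two consistent completions.
    """
    a = np.array([0.0, 0.0, 0.0])
    b = np.array([1.5, 0.0, 0.0])
    ref_a = np.array([-0.75, 1.3, 0.0])
    other_a = np.array([-0.75, -1.3, 0.0])
    sign = -1.0 if relation == "trans" else 1.0
    ref_b = np.array([2.25, sign * 1.3, 0.0])
    other_b = np.array([2.25, -sign * 1.3, 0.0])
    faces = []
    for z in (1.2, -1.2):
        o = np.array([0.75, 0.0, z])
        pa = _parity_from_coords(a, [o, b, ref_a, other_a])
        pb = _parity_from_coords(b, [o, a, ref_b, other_b])
        faces.append((pa, pb))
    return faces


def epoxidize(g: MolecularGraph, bond: tuple) -> dict:
    """Oxirane across an E-olefin; both new centers start ``unassigned``.

    Returns ``{"centers": (atom_a, atom_b), "faces": [(parity_a, parity_b),
    (parity_a, parity_b)]}`` — the two geometry-consistent parity
    completions, used to vet experimental configurations.
    """
    a_pos, b_pos = sorted(bond)
    ca, cb = _backbone(g, a_pos), _backbone(g, b_pos)
    if g.bond_order(ca, cb) != 2:
        raise TailoringError(f"C-{a_pos}=C-{b_pos} is not a double bond")
    key = MolecularGraph._bkey(ca, cb)
    geo = g.double_bond_geometry.get(key)
    if geo is None:
        raise TailoringError(f"C-{a_pos}=C-{b_pos} has no recorded geometry")
    lo, hi = key
    ref_a, ref_b = (geo.ref_i, geo.ref_j) if lo == ca else (geo.ref_j, geo.ref_i)
    relation = geo.relation

    g.set_bond_order(ca, cb, 1)
    o = g.add_atom("O")
    g.add_bond(o, ca)
    g.add_bond(o, cb)

    def order_for(c: int, other_c: int, ref: int) -> tuple:
        rest = [n for n, _ in g.neighbors(c) if n not in (o, other_c, ref)]
        if rest:
            fourth = rest[0]
        elif g.implicit_h(c) == 1:
            fourth = IMPLICIT_H
        else:
            raise TailoringError(f"cannot determine fourth substituent at atom {c}")
        return (o, other_c, ref, fourth)

    g.set_stereocenter(ca, order_for(ca, cb, ref_a), None, provenance="unassigned")
    g.set_stereocenter(cb, order_for(cb, ca, ref_b), None, provenance="unassigned")
    return {"centers": (ca, cb), "faces": _epoxide_face_parities(relation)}


def apply_plan(
    linear: LinearPolyketide,
    plan: TailoringPlan,
    findings: Optional[list] = None,
) -> MolecularGraph:
    """Run all tailoring edits and resolve experimental configurations.

    Experimental configurations for tailoring-born centers set their parity
    (provenance ``experimental``); for backbone centers already predicted
    bioinformatically they are cross-checks only — a disagreement is
    reported as a finding, never an override.  An epoxide descriptor pair
    inconsistent with the E-olefin (a cis pair) raises.
    """
    from .cluster import Finding

    g = linear_graph(linear)
    macrolactonize(g, plan.lactonization_site)
    hemiketal_center = None
    if plan.hemiketal_pair:
        hemiketal_center = form_hemiketal(g, *plan.hemiketal_pair)
    epoxide = None
    if plan.epoxidation_bond:
        epoxide = epoxidize(g, plan.epoxidation_bond)

    exp = dict(plan.experimental_configs or {})

    if hemiketal_center is not None and plan.hemiketal_pair[0] in exp:
        want = exp[plan.hemiketal_pair[0]]
        sc = g.stereocenters[hemiketal_center]
        for parity in (1, -1):
            sc.parity = parity
            if label_stereocenter(g, hemiketal_center) == want:
                break
        else:
            raise TailoringError(
                f"cannot realize descriptor {want} at C-{plan.hemiketal_pair[0]}"
            )
        sc.provenance = "experimental"

    if epoxide is not None:
        a_pos, b_pos = sorted(plan.epoxidation_bond)
        in_exp = [p for p in (a_pos, b_pos) if p in exp]
        if len(in_exp) == 1:
            raise TailoringError(
                f"experimental configuration given for only one epoxide carbon "
                f"(C-{in_exp[0]}); need both C-{a_pos} and C-{b_pos} or neither"
            )
        if len(in_exp) == 2:
            ca, cb = epoxide["centers"]
            sa, sb = g.stereocenters[ca], g.stereocenters[cb]
            want = (exp[a_pos], exp[b_pos])
            for pa, pb in epoxide["faces"]:
                sa.parity, sb.parity = pa, pb
                got = (label_stereocenter(g, ca), label_stereocenter(g, cb))
                if got == want:
                    sa.provenance = sb.provenance = "experimental"
                    break
            else:
                sa.parity = sb.parity = None
                faces = []
                for pa, pb in epoxide["faces"]:
                    sa.parity, sb.parity = pa, pb
                    faces.append(
                        (label_stereocenter(g, ca), label_stereocenter(g, cb))
                    )
                sa.parity = sb.parity = None
                raise TailoringError(
                    f"descriptor pair C-{a_pos}={want[0]}, C-{b_pos}={want[1]} is "
                    f"inconsistent with suprafacial epoxidation of the E-olefin; "
                    f"allowed pairs: {faces[0]} or {faces[1]}"
                )

    # cross-check experimental configs against bioinformatic predictions
    if findings is not None:
        for i, sc in sorted(g.stereocenters.items()):
            label = g.atoms[i].label
            if not label or sc.provenance != "bioinformatic":
                continue
            pos = int(label[2:])
            if pos in exp:
                predicted = label_stereocenter(g, i)
                if predicted != exp[pos]:
                    findings.append(
                        Finding(
                            "warning",
                            "stereo-disagreement",
                            f"C-{pos}: bioinformatic prediction {predicted} vs "
                            f"experimental {exp[pos]}",
                        )
                    )

    g.validate()
    return g
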