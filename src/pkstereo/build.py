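"""Linear polyketide backbone construction from a classified assembly line.

Collinearity: with E extension modules, extension module ``m`` contributes
backbone carbons ``C(2(E-m)+1)`` (acyl) and ``C(2(E-m)+2)`` (alpha); the
carbon its reductive loop acts on (the beta-keto carbon delivered by the
upstream module) is ``C(2(E-m)+3)``.  The loading module contributes
``C(2E+1)`` and ``C(2E+2)``; ``C-1`` is the thioester carbon, modeled as a
free carboxyl until chain release.

Stereodescriptors produced here are assembly-line-local acyl labels
(3S/3R for beta-hydroxyls, 2S/2R for alpha-methyls), *not* final CIP
labels: priorities in the finished molecule can differ from the generic
acyl intermediate, so R/S comes only from the CIP engine on the completed
graph.  The local labels are converted to neighbor-order parities using the
fixed generic-intermediate priority (thioester side > distal chain side).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .cluster import AssemblyLine, ModuleSpec
from .molgraph import IMPLICIT_H, MolecularGraph


class BuildError(ValueError):
    pass


# (beta_state, beta_descriptor, alpha_descriptor_if_methyl) per KR subtype,
# for a module whose DH is absent or inactive
KR_RULES = {
    "A1": ("hydroxyl", "3S", "2R"),
    "A2": ("hydroxyl", "3S", "2S"),
    "B1": ("hydroxyl", "3R", "2R"),
    "B2": ("hydroxyl", "3R", "2S"),
    "C1": ("ketone", "none", "2R"),
    "C2": ("ketone", "none", "2S"),
}

ENOYL_GEOMETRY = "E"  # DH-derived 2-enoyl intermediates are E-configured


@dataclass
class StereoRuleTable:
    """Subtype -> outcome rules; defaults encode the standard conventions."""

    kr: dict = field(default_factory=lambda: dict(KR_RULES))
    enoyl_geometry: str = ENOYL_GEOMETRY
    # alpha descriptor installed by an active ER on a methylmalonyl unit,
    # keyed by the residue at ER reference position 44
    er_alpha: dict = field(default_factory=lambda: {"Y": "2S", "default": "2R"})

    def er_descriptor(self, residue_44: str) -> str:
        return self.er_alpha.get(residue_44, self.er_alpha["default"])


DEFAULT_RULES = StereoRuleTable()


@dataclass
class KetideUnit:
    module_index: int
    carbons: tuple  # (acyl position, alpha position)
    alpha_substituent: str  # "H" | "methyl"
    alpha_descriptor: str  # "2R" | "2S" | "none"
    beta_position: Optional[int]
    beta_state: Optional[str]  # ketone|hydroxyl|enoyl|methylene|carboxyl-thioester
    beta_descriptor: Optional[str]  # "3R"|"3S"|"E"|"Z"|"none"


@dataclass
class LinearPolyketide:
    units: list
    n_backbone_carbons: int
    methyl_positions: list
    carbon_states: dict  # backbone position -> state dict

    @property
    def total_carbons(self) -> int:
        return self.n_backbone_carbons + len(self.methyl_positions)

    def hydroxyl_positions(self) -> list:
        return sorted(
            p for p, st in self.carbon_states.items() if st["state"] == "hydroxyl"
        )

    def ketone_positions(self) -> list:
        return sorted(
            p for p, st in self.carbon_states.items() if st["state"] == "ketone"
        )

    def enoyl_bonds(self) -> list:
        return sorted(
            (p - 1, p) for p, st in self.carbon_states.items() if st["state"] == "enoyl"
        )

    def to_table(self) -> list:
        """Per-carbon table (list of dicts), JSON-serializable."""
        out = []
        for p in sorted(self.carbon_states):
            row = {"position": p}
            row.update(self.carbon_states[p])
            out.append(row)
        return out


def map_backbone(line: AssemblyLine) -> dict:
    """Module index -> {'carbons': (acyl, alpha), 'beta': beta position}."""
    E = line.n_extensions
    out = {}
    for m in line.modules:
        if m.index == 0:
            out[0] = {"carbons": (2 * E + 1, 2 * E + 2), "beta": None}
        else:
            base = 2 * (E - m.index)
            out[m.index] = {"carbons": (base + 1, base + 2), "beta": base + 3}
    return out


def apply_reductive_loop(
    module: ModuleSpec, rules: StereoRuleTable = DEFAULT_RULES
) -> tuple:
    """(beta_state, beta_descriptor, alpha_descriptor) for one module.

    The alpha descriptor applies only when the module loads methylmalonyl;
    an unreduced alpha-methyl defaults to 2R (the condensation product)
    unless an epimerizing KR subtype or the ER rule overrides it.
    """
    if module.at_call is None:
        raise BuildError(f"module {module.index} has no AT call")
    methyl = module.at_call.specificity == "methylmalonyl"
    kr = module.kr_call
    dh_active = module.dh_call is not None and module.dh_call.active
    er = module.er_call
    er_active = er is not None and er.active

    if kr is None:
        if dh_active:
            raise BuildError(
                f"module {module.index}: active DH without KR is chemically impossible"
            )
        return ("ketone", "none", "2R" if methyl else "none")

    beta_state, beta_desc, alpha = rules.kr[kr.subtype]
    if not methyl:
        alpha = "none"

    if not kr.redox_active or not dh_active:
        # KR alone (or redox-inactive KR); inactive DH is treated as absent
        return (beta_state, beta_desc, alpha)

    if not er_active:
        return ("enoyl", rules.enoyl_geometry, "none")

    alpha = rules.er_descriptor(er.residue_44) if methyl else "none"
    if er.alpha_descriptor_if_methyl == "not_applicable" and methyl:
        alpha = "none"
    return ("methylene", "none", alpha)


def build_linear(
    line: AssemblyLine, rules: StereoRuleTable = DEFAULT_RULES
) -> LinearPolyketide:
    """Full per-carbon state table for the released (free-acid) chain."""
    blocked = [
        m.index
        for m in line.modules
        if m.at_call is None or m.at_call.specificity == "unknown"
    ]
    if blocked:
        raise BuildError(
            "carbon accounting blocked: AT specificity unknown for module(s) "
            + ", ".join(str(i) for i in sorted(blocked))
        )
    E = line.n_extensions
    n_backbone = 2 * (E + 1)
    positions = map_backbone(line)

    states = {
        p: {"state": "methylene", "substituent": "H", "descriptor": "none",
            "provenance": "none"}
        for p in range(1, n_backbone + 1)
    }
    states[1] = {
        "state": "carboxyl",
        "substituent": "H",
        "descriptor": "none",
        "provenance": "none",
    }
    # loading unit: acetyl starter; its acyl carbon is module 1's beta target
    states[n_backbone]["state"] = "methyl-terminus"

    units = []
    methyl_positions = []
    for m in line.modules:
        acyl, alpha_pos = positions[m.index]["carbons"]
        if m.index == 0:
            units.append(
                KetideUnit(0, (acyl, alpha_pos), "H", "none", None, None, None)
            )
            continue
        beta = positions[m.index]["beta"]
        beta_state, beta_desc, alpha_desc = apply_reductive_loop(m, rules)
        methyl = m.at_call.specificity == "methylmalonyl"
        if methyl:
            methyl_positions.append(alpha_pos)
            states[alpha_pos]["substituent"] = "methyl"

        bst = states[beta]
        bst["state"] = beta_state if beta_state != "ketone" else "ketone"
        if beta_state == "hydroxyl":
            bst["descriptor"] = beta_desc
            bst["provenance"] = "bioinformatic"
        elif beta_state == "enoyl":
            bst["state"] = "enoyl"
            bst["descriptor"] = beta_desc  # E geometry on bond (beta-1, beta)
            bst["provenance"] = "bioinformatic"
            states[beta - 1]["state"] = "enoyl-alpha"
        if beta_state == "enoyl":
            alpha_desc = "none"
        ast = states[alpha_pos]
        if methyl and alpha_desc != "none" and ast["state"] != "enoyl-alpha":
            ast["descriptor"] = alpha_desc
            ast["provenance"] = "bioinformatic"
        units.append(
            KetideUnit(
                m.index,
                (acyl, alpha_pos),
                "methyl" if methyl else "H",
                alpha_desc if methyl else "none",
                beta,
                beta_state,
                beta_desc,
            )
        )

    lp = LinearPolyketide(units, n_backbone, sorted(methyl_positions), states)
    assert lp.total_carbons == n_backbone + len(methyl_positions)
    return lp


# ---------------------------------------------------------------------------
# molecular graph of the linear product
# ---------------------------------------------------------------------------


def linear_graph(lp: LinearPolyketide) -> MolecularGraph:
    """Molecular graph of the free-acid linear chain with local parities.

    Local acyl descriptors are converted to parities with the fixed
    generic-intermediate priority order: beta-hydroxyl carbons
    ``[OH, C(p-1), C(p+1), H]`` (3S -> -1, 3R -> +1); alpha-methyl carbons
    ``[C(p-1), C(p+1), CH3, H]`` (2S -> -1, 2R -> +1).  ``C(p-1)`` is the
    thioester-proximal side.
    """
    g = MolecularGraph()
    n = lp.n_backbone_carbons
    backbone = {}
    for p in range(1, n + 1):
        backbone[p] = g.add_atom("C", label=f"C-{p}")
    for p in range(1, n):
        g.add_bond(backbone[p], backbone[p + 1])

    # carboxyl at C-1
    o_carbonyl = g.add_atom("O")
    g.add_bond(backbone[1], o_carbonyl, 2)
    o_hydroxyl = g.add_atom("O")
    g.add_bond(backbone[1], o_hydroxyl, 1)

    # methyl branches, numbered C-(n+1).. in backbone order
    methyl_atom = {}
    next_label = n + 1
    for p in lp.methyl_positions:
        c = g.add_atom("C", label=f"C-{next_label}")
        next_label += 1
        g.add_bond(backbone[p], c)
        methyl_atom[p] = c

    for p, st in sorted(lp.carbon_states.items()):
        state = st["state"]
        if state == "hydroxyl":
            o = g.add_atom("O")
            g.add_bond(backbone[p], o)
            desc = st["descriptor"]
            if desc in ("3S", "3R"):
                g.set_stereocenter(
                    backbone[p],
                    (o, backbone[p - 1], backbone[p + 1], IMPLICIT_H),
                    -1 if desc == "3S" else +1,
                    provenance=st["provenance"] if st["provenance"] != "none" else "bioinformatic",
                )
        elif state == "ketone":
            o = g.add_atom("O")
            g.add_bond(backbone[p], o, 2)
        elif state == "enoyl":
            # double bond between alpha (p-1) and beta (p), E-configured:
            # chain substituents (p-2 side and p+1 side) are trans
            g.set_bond_order(backbone[p - 1], backbone[p], 2)
            ref_alpha = backbone[p - 2] if p - 2 >= 1 else o_carbonyl
            g.set_double_bond_geometry(
                backbone[p - 1], backbone[p], ref_alpha, backbone[p + 1], "trans"
            )

    for p, st in sorted(lp.carbon_states.items()):
        if st["substituent"] == "methyl" and st["descriptor"] in ("2R", "2S"):
            g.set_stereocenter(
                backbone[p],
                (backbone[p - 1], backbone[p + 1], methyl_atom[p], IMPLICIT_H),
                +1 if st["descriptor"] == "2R" else -1,
                provenance="bioinformatic",
            )

    g.validate()
    return g
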