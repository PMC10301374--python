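"""Seeded synthetic data: domain sequences, whole clusters, the mld fixture.

Domain generator
----------------
Synthetic domains emulate homologous family members of the bundled
reference consensus: the scaffold is the reference sequence with seeded
random substitutions (uniform over the 20 canonical residues) at a default
20% divergence, never touching the protected diagnostic windows
(diagnostic positions plus a 3-residue flank).  Diagnostic residues are
then written according to the requested call, so the classifier's expected
evidence sits at known alignment positions inside a randomized context.
An extra ``mutation_rate`` can be layered on top for robustness tests.

All randomness flows through :class:`numpy.random.Generator` seeded with
PCG64 (the algorithm is fixed here, not the platform default), so the same
seed gives byte-identical output on every platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

from .classify import diagnostic, diagnostic_positions, reference_sequences
from .cluster import (
    AssemblyLine,
    ATCall,
    DHCall,
    DomainRef,
    ERCall,
    KRCall,
    ModuleSpec,
    ValidationError,
    read_module_table,
    validate_architecture,
)
from .tailor import TailoringPlan

AA20 = list("ACDEFGHIKLMNPQRSTVWY")
DEFAULT_DIVERGENCE = 0.2
PROTECT_FLANK = 3


@dataclass
class GeneratorSpec:
    seed: int
    divergence: float = DEFAULT_DIVERGENCE
    mutation_rate: float = 0.0

    def rng(self) -> np.random.Generator:
        return np.random.Generator(np.random.PCG64(self.seed))


def _protected(kind: str) -> set:
    out = set()
    for p in diagnostic_positions(kind):
        out.update(range(p - PROTECT_FLANK, p + PROTECT_FLANK + 1))
    return out


def _write(seq: list, start_1based: int, residues: str) -> None:
    for k, r in enumerate(residues):
        seq[start_1based - 1 + k] = r


def make_domain(
    kind: str,
    call,
    seed: int,
    mutation_rate: float = 0.0,
    divergence: float = DEFAULT_DIVERGENCE,
) -> tuple:
    """One synthetic domain sequence plus its truth row.

    ``call`` is the expected classification: AT specificity string, KR
    subtype string, DH ``True``/``False`` activity, or the ER residue-44
    letter.  Identical inputs give identical output.
    """
    spec = GeneratorSpec(seed, divergence, mutation_rate)
    rng = spec.rng()
    ref = reference_sequences()[kind]
    protected = _protected(kind)
    seq = list(ref)
    total_rate = min(1.0, divergence + mutation_rate)
    for i in range(len(seq)):
        if (i + 1) in protected:
            continue
        if rng.random() < total_rate:
            seq[i] = AA20[int(rng.integers(20))]

    truth = {"kind": kind, "call": call, "seed": seed}
    if kind == "AT":
        d = diagnostic("at-motif-malonyl")
        motif = {"malonyl": "HAFH", "methylmalonyl": "YASH"}.get(call, "AAAA")
        _write(seq, d.start, motif)
    elif kind == "KR":
        subtype = call
        if subtype[0] == "C":
            _write(seq, diagnostic("kr-triad-ser").start, "A")
            _write(seq, diagnostic("kr-triad-tyr").start, "F")
            _write(seq, diagnostic("kr-triad-asn").start, "A")
        else:
            _write(seq, diagnostic("kr-triad-ser").start, "S")
            _write(seq, diagnostic("kr-triad-tyr").start, "Y")
            _write(seq, diagnostic("kr-triad-asn").start, "N")
        if subtype[0] == "B":
            _write(seq, diagnostic("kr-b-fingerprint").start, "LDD")
            _write(seq, diagnostic("kr-a-fingerprint").start, "F")
        elif subtype[0] == "A":
            _write(seq, diagnostic("kr-b-fingerprint").start, "AGA")
            _write(seq, diagnostic("kr-a-fingerprint").start, "W")
        _write(seq, diagnostic("kr-epimerization").start, "E" if subtype[1] == "2" else "Q")
    elif kind == "DH":
        active = bool(call)
        _write(seq, diagnostic("dh-catalytic-his").start, "H")
        _write(seq, diagnostic("dh-catalytic-asp").start, "D" if active else "A")
    elif kind == "ER":
        _write(seq, diagnostic("er-tyr44").start, call)
    else:
        raise ValueError(f"no generator for domain kind {kind!r}")
    return "".join(seq), truth


# ---------------------------------------------------------------------------
# whole clusters
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCluster:
    line: AssemblyLine  # calls filled per the truth table
    domains: list  # DomainRef with sequences (classifiable kinds only)
    truth: list  # one row per generated domain

    def fasta(self) -> str:
        out = []
        for d in self.domains:
            out.append(f">{d.gene_id}|{d.module_index}|{d.kind}")
            for i in range(0, len(d.sequence), 60):
                out.append(d.sequence[i : i + 60])
        return "\n".join(out) + "\n"

    def write(self, outdir) -> dict:
        from .cluster import write_module_table

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "cluster.fasta",
            "table": outdir / "modules.tsv",
            "truth": outdir / "truth.tsv",
        }
        paths["fasta"].write_text(self.fasta())
        write_module_table(self.line, paths["table"])
        rows = ["gene_id\tmodule_index\tkind\tcall\tseed"]
        for t in self.truth:
            rows.append(
                f"{t['gene_id']}\t{t['module_index']}\t{t['kind']}\t{t['call']}\t{t['seed']}"
            )
        paths["truth"].write_text("\n".join(rows) + "\n")
        return paths


def make_cluster(
    module_calls: list,
    seed: int,
    mutation_rate: float = 0.0,
) -> SyntheticCluster:
    """Synthetic cluster from per-module expected calls.

    ``module_calls`` is a list of dicts with keys ``index``, ``gene_id``,
    ``domains`` (comma-joined kinds) and optional ``at``, ``kr``, ``dh``
    (bool), ``er`` (residue-44 letter).  The architecture is validated
    before any sequence is generated.
    """
    modules = []
    for mc in module_calls:
        kinds = [k.strip() for k in mc["domains"].split(",")]
        gene = mc.get("gene_id", f"gene{mc['index']}")
        domains = [DomainRef(gene, mc["index"], k) for k in kinds]
        modules.append(
            ModuleSpec(
                mc["index"],
                domains,
                ATCall(mc["at"]) if mc.get("at") else None,
                KRCall(mc["kr"]) if mc.get("kr") else None,
                DHCall(True, bool(mc["dh"])) if "dh" in mc and mc["dh"] is not None else None,
                ERCall(mc["er"]) if mc.get("er") else None,
            )
        )
    line = AssemblyLine(modules)
    errors = [f for f in validate_architecture(line) if f.severity == "error"]
    if errors:
        raise ValidationError("; ".join(str(f) for f in errors))

    out_domains = []
    truth = []
    for m in line.modules:
        per_kind = {
            "AT": m.at_call.specificity if m.at_call else None,
            "KR": m.kr_call.subtype if m.kr_call else None,
            "DH": m.dh_call.active if m.dh_call else None,
            "ER": m.er_call.residue_44 if m.er_call else None,
        }
        for kind, call in per_kind.items():
            if call is None:
                continue
            dom = m.domain(kind)
            if dom is None:
                continue
            dseed = seed * 1000 + m.index * 10 + "ATKRDHER".index(kind) // 2
            sequence, row = make_domain(kind, call, dseed, mutation_rate)
            dom.sequence = sequence
            out_domains.append(dom)
            row.update({"gene_id": dom.gene_id, "module_index": m.index})
            truth.append(row)
    return SyntheticCluster(line, out_domains, truth)


# ---------------------------------------------------------------------------
# the mld fixture (transcribed assembly line + tailoring plan)
# ---------------------------------------------------------------------------

#: Experimentally confirmed absolute configuration of marinolide B.
MARINOLIDE_EXPERIMENTAL_CONFIGS = {
    4: "S", 5: "S", 9: "R", 10: "S", 11: "S", 12: "S", 13: "S", 16: "S",
    17: "R", 18: "R", 19: "R", 23: "R", 25: "S", 26: "S", 27: "S", 30: "R",
}

#: Descriptors established only by experiment (tailoring-born centers).
TAILORING_EXPERIMENTAL_CONFIGS = {5: "S", 18: "R", 19: "R"}

LACTONIZATION_SITE = {"A": 25, "B": 27}
HEMIKETAL_PAIR = (5, 9)
EPOXIDATION_BOND = (18, 19)


def mld_fixture(product: str = "A", experimental: bool = False):
    """The marinolide (mld) assembly line and tailoring plan.

    ``product`` picks the macrolactonization site (A: C-25, B: C-27).  With
    ``experimental=True`` the plan carries the experimentally determined
    descriptors for the three tailoring-born centers (C-5, C-18, C-19);
    otherwise those centers stay unassigned, as in a purely bioinformatic
    run.
    """
    if product not in LACTONIZATION_SITE:
        raise ValueError(f"product must be 'A' or 'B', got {product!r}")
    with resources.as_file(
        resources.files("pkstereo.data").joinpath("mld_modules.tsv")
    ) as path:
        line = read_module_table(path)
    plan = TailoringPlan(
        lactonization_site=LACTONIZATION_SITE[product],
        hemiketal_pair=HEMIKETAL_PAIR,
        epoxidation_bond=EPOXIDATION_BOND,
        experimental_configs=dict(TAILORING_EXPERIMENTAL_CONFIGS) if experimental else {},
    )
    return line, plan


def mld_architecture_calls() -> list:
    """The mld architecture as ``make_cluster`` input (calls = fixture truth)."""
    line, _ = mld_fixture()
    out = []
    for m in line.modules:
        out.append(
            {
                "index": m.index,
                "gene_id": m.domains[0].gene_id,
                "domains": ",".join(d.kind for d in m.domains),
                "at": m.at_call.specificity if m.at_call else None,
                "kr": m.kr_call.subtype if m.kr_call else None,
                "dh": m.dh_call.active if m.dh_call else None,
                "er": m.er_call.residue_44 if m.er_call else None,
            }
        )
    return out


def minimal_architecture_calls() -> list:
    """Loading module plus one unreduced malonyl extension (smallest line)."""
    return [
        {"index": 0, "gene_id": "synA", "domains": "AT,T", "at": "malonyl"},
        {"index": 1, "gene_id": "synA", "domains": "KS,AT,T,TE", "at": "malonyl"},
    ]


# ---------------------------------------------------------------------------
# random small molecules (oracle harness for the CIP engine)
# ---------------------------------------------------------------------------


def make_random_molecule(seed: int, n_min: int = 5, n_max: int = 12):
    """Seeded random small CHO molecule with randomly assigned stereocenters.

    Builds a random tree of C/O atoms, occasionally closes one ring and
    promotes some bonds to double bonds, then marks every carbon whose four
    substituent branches are constitutionally distinct (resolvable by the
    implemented CIP rules) with a random parity.  Centers whose
    stereogenicity would depend on other stereocenters (CIP Rules 3-5
    territory, out of the engine's scope) are not marked.  Returns ``None``
    when the draw yields no markable center.
    """
    from .cip import CIPIncompleteError, rank_substituents
    from .molgraph import IMPLICIT_H, MolecularGraph

    rng = np.random.Generator(np.random.PCG64(seed))
    n = int(rng.integers(n_min, n_max + 1))
    g = MolecularGraph()
    idx = []
    for k in range(n):
        el = "C" if (k < 2 or rng.random() < 0.75) else "O"
        idx.append(g.add_atom(el))

    def free_valence(i):
        cap = 4 if g.atoms[i].element == "C" else 2
        return cap - sum(o for _, o in g.neighbors(i))

    for k in range(1, n):
        cands = [
            i
            for i in idx[:k]
            if free_valence(i) > 0
            and not (g.atoms[i].element == "O" and g.atoms[idx[k]].element == "O")
        ]
        if not cands:
            return None
        g.add_bond(cands[int(rng.integers(len(cands)))], idx[k])
    if rng.random() < 0.4:
        ring = [
            (i, j)
            for i in idx
            for j in idx
            if i < j
            and g.bond_order(i, j) == 0
            and free_valence(i) > 0
            and free_valence(j) > 0
            and not (g.atoms[i].element == "O" and g.atoms[j].element == "O")
        ]
        if ring:
            i, j = ring[int(rng.integers(len(ring)))]
            g.add_bond(i, j)
    for i, j, o in list(g.bonds()):
        if o == 1 and free_valence(i) > 0 and free_valence(j) > 0 and rng.random() < 0.2:
            g.set_bond_order(i, j, 2)

    marked = 0
    for c in idx:
        if g.atoms[c].element != "C":
            continue
        if any(o == 2 for _, o in g.neighbors(c)):
            continue
        nbrs = [nb for nb, _ in g.neighbors(c)]
        h = g.implicit_h(c)
        if len(nbrs) + h != 4 or h > 1:
            continue
        order = tuple(nbrs + [IMPLICIT_H] * h)
        try:
            rank_substituents(g, c, order)
        except CIPIncompleteError:
            continue
        g.set_stereocenter(c, order, int(rng.choice([-1, 1])))
        marked += 1
    return g if marked else None
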