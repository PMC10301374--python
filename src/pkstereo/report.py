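"""End-to-end orchestration and human-readable reporting.

``run_predict`` executes the whole pipeline — classify (when sequences are
provided), build, tailor, ring/CIP analysis — and produces a
:class:`PredictionReport` with a per-center stereo table carrying
provenance (bioinformatic | experimental | unassigned) and an evidence
string naming the domain the assignment came from.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .build import DEFAULT_RULES, LinearPolyketide, build_linear
from .cip import assign_cip
from .classify import classify_all
from .cluster import AssemblyLine, Finding, read_domain_fasta, read_module_table, validate_architecture
from .molgraph import (
    FormulaReport,
    MolecularGraph,
    formula_report,
    graph_to_dict,
)
from .smiles import write_smiles
from .tailor import TailoringPlan, apply_plan


@dataclass
class PredictionReport:
    cluster_id: str
    stereo_rows: list  # {"carbon","descriptor","provenance","evidence"}
    formula: FormulaReport
    n_stereocenters: int
    provenance_counts: dict
    stereoisomer_space: int
    smiles: str
    findings: list
    config_echo: dict = field(default_factory=dict)

    @property
    def has_errors(self) -> bool:
        return any(f.severity == "error" for f in self.findings)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["findings"] = [str(f) for f in self.findings]
        return d


def _ester_bond(g: MolecularGraph) -> Optional[tuple]:
    try:
        c1 = g.atom_by_label("C-1")
    except KeyError:
        return None
    for n, order in g.neighbors(c1):
        if g.atoms[n].element == "O" and order == 1:
            return (c1, n)
    return None


def _evidence(line: AssemblyLine, lp: LinearPolyketide, plan: TailoringPlan) -> dict:
    """Backbone position -> evidence string for stereo-bearing carbons."""
    ev = {}
    for unit in lp.units:
        if unit.module_index == 0:
            continue
        m = line.module(unit.module_index)
        if unit.beta_state == "hydroxyl":
            ev[unit.beta_position] = (
                f"KR {m.kr_call.subtype} (module {m.index}) -> "
                f"({unit.beta_descriptor})-hydroxyl"
            )
        alpha = unit.carbons[1]
        if unit.alpha_substituent == "methyl" and unit.alpha_descriptor not in ("none", None):
            if m.er_call is not None and m.er_call.active and m.dh_call and m.dh_call.active:
                source = "ER residue-44 rule"
            elif m.kr_call is not None and m.kr_call.epimerizing:
                source = f"epimerizing KR {m.kr_call.subtype}"
            else:
                source = "condensation default (no epimerization)"
            ev[alpha] = (
                f"alpha-methyl from methylmalonyl (module {m.index}); "
                f"({unit.alpha_descriptor}) via {source}"
            )
    if plan.hemiketal_pair:
        k, h = plan.hemiketal_pair
        ev[k] = f"hemiketal carbon (C-{k} ketone + C-{h} hydroxyl)"
    if plan.epoxidation_bond:
        a, b = sorted(plan.epoxidation_bond)
        for p in (a, b):
            ev[p] = f"epoxidation of the C-{a}=C-{b} E-olefin"
    return ev


def predict(
    line: AssemblyLine,
    plan: TailoringPlan,
    findings: Optional[list] = None,
    config_echo: Optional[dict] = None,
) -> tuple:
    """Core pipeline: (PredictionReport, MolecularGraph, LinearPolyketide)."""
    if findings is None:
        findings = []
    findings.extend(validate_architecture(line))
    lp = build_linear(line, DEFAULT_RULES)
    g = apply_plan(lp, plan, findings)
    assign_cip(g)

    evidence = _evidence(line, lp, plan)
    rows = []
    prov_counts = {"bioinformatic": 0, "experimental": 0, "unassigned": 0}
    for i, sc in sorted(
        g.stereocenters.items(), key=lambda kv: int(g.atoms[kv[0]].label[2:])
    ):
        pos = int(g.atoms[i].label[2:])
        prov_counts[sc.provenance] += 1
        rows.append(
            {
                "carbon": g.atoms[i].label,
                "descriptor": sc.descriptor or "unassigned",
                "provenance": sc.provenance,
                "evidence": evidence.get(pos, ""),
            }
        )
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        smiles = write_smiles(g)
    report = PredictionReport(
        cluster_id=line.cluster_id,
        stereo_rows=rows,
        formula=formula_report(g, _ester_bond(g)),
        n_stereocenters=len(g.stereocenters),
        provenance_counts=prov_counts,
        stereoisomer_space=2 ** len(g.stereocenters),
        smiles=smiles,
        findings=findings,
        config_echo=config_echo or {},
    )
    return report, g, lp


def summarize(report: PredictionReport) -> str:
    """Deterministic Markdown rendering of a prediction report."""
    f = report.formula
    lines = [
        f"# Stereostructure prediction — {report.cluster_id or 'assembly line'}",
        "",
        "## Molecule",
        "",
        f"- formula: **{f.formula}**",
        f"- monoisotopic mass: {f.monoisotopic_mass:.4f} Da "
        f"([M+Na]+ calcd. {f.adduct_mass['Na']:.4f})",
        f"- degrees of unsaturation: {f.dbe}",
        f"- rings: {f.ring_count} (sizes {', '.join(str(s) for s in f.ring_sizes) or 'none'})",
    ]
    if f.macrocycle_size:
        lines.append(f"- macrolactone ring size: {f.macrocycle_size}")
    lines += [
        f"- SMILES: `{report.smiles}`",
        "",
        "## Stereocenters",
        "",
        f"- total: {report.n_stereocenters} "
        f"(stereoisomer space 2^{report.n_stereocenters} = {report.stereoisomer_space})",
        "- provenance: "
        + ", ".join(f"{k} {v}" for k, v in sorted(report.provenance_counts.items())),
        "",
        "| carbon | descriptor | provenance | evidence |",
        "|---|---|---|---|",
    ]
    for r in report.stereo_rows:
        lines.append(
            f"| {r['carbon']} | {r['descriptor']} | {r['provenance']} | {r['evidence']} |"
        )
    lines += ["", "## Findings", ""]
    if report.findings:
        lines += [f"- {f}" for f in report.findings]
    else:
        lines.append("- none")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# config-file driven entry point
# ---------------------------------------------------------------------------

PRODUCT_SITES = {"A": 25, "B": 27}


def _plan_from_config(cfg: dict) -> TailoringPlan:
    if "plan" in cfg:
        return TailoringPlan.from_json(Path(cfg["plan"]).read_text())
    if "product" in cfg:
        from .synth import EPOXIDATION_BOND, HEMIKETAL_PAIR

        site = PRODUCT_SITES[str(cfg["product"]).upper()]
        plan = TailoringPlan(site, HEMIKETAL_PAIR, EPOXIDATION_BOND)
    else:
        if "lactonization_site" not in cfg:
            raise ValueError("config needs 'product', 'plan', or 'lactonization_site'")
        plan = TailoringPlan(
            int(cfg["lactonization_site"]),
            tuple(cfg["hemiketal_pair"]) if cfg.get("hemiketal_pair") else None,
            tuple(cfg["epoxidation_bond"]) if cfg.get("epoxidation_bond") else None,
        )
    exp = cfg.get("experimental_configs")
    if isinstance(exp, str):
        exp = json.loads(Path(exp).read_text())
    if exp:
        plan.experimental_configs = {int(k): v for k, v in exp.items()}
    return plan


def run_predict(config) -> tuple:
    """Execute a full run from a YAML/JSON config file (or a dict).

    Returns ``(report, artifact_paths)``; artifacts are written only when
    the config names an ``out_dir``.
    """
    if isinstance(config, (str, Path)):
        cfg = yaml.safe_load(Path(config).read_text())
        base = Path(config).parent
    else:
        cfg = dict(config)
        base = Path(".")

    def _resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    findings: list = []
    line = read_module_table(_resolve(cfg["module_table"]))
    if cfg.get("fasta"):
        domains = read_domain_fasta(_resolve(cfg["fasta"]))
        by_key = {(d.module_index, d.kind): d for d in domains}
        for m in line.modules:
            for d in m.domains:
                hit = by_key.get((m.index, d.kind))
                if hit is not None:
                    d.sequence = hit.sequence
        classify_all(line, findings, fuzzy_at=bool(cfg.get("fuzzy_at")))

    plan = _plan_from_config(cfg)
    report, g, lp = predict(line, plan, findings, config_echo=cfg)

    paths = {}
    if cfg.get("out_dir"):
        out = _resolve(cfg["out_dir"])
        out.mkdir(parents=True, exist_ok=True)
        paths["report_md"] = out / "report.md"
        paths["report_md"].write_text(summarize(report))
        paths["report_json"] = out / "report.json"
        paths["report_json"].write_text(json.dumps(report.to_dict(), indent=1) + "\n")
        paths["smiles"] = out / "structure.smiles"
        paths["smiles"].write_text(report.smiles + "\n")
        paths["graph_json"] = out / "graph.json"
        paths["graph_json"].write_text(json.dumps(graph_to_dict(g), indent=1) + "\n")
        paths["linear_json"] = out / "linear.json"
        paths["linear_json"].write_text(json.dumps(lp.to_table(), indent=1) + "\n")
        paths["stereo_tsv"] = out / "stereo_table.tsv"
        rows = ["carbon\tdescriptor\tprovenance\tevidence"]
        rows += [
            f"{r['carbon']}\t{r['descriptor']}\t{r['provenance']}\t{r['evidence']}"
            for r in report.stereo_rows
        ]
        paths["stereo_tsv"].write_text("\n".join(rows) + "\n")
    return report, paths
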