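"""Data model for modular type I PKS assembly lines, plus readers/writers.

An assembly line is an ordered list of modules.  Module 0 is the loading
module; extension modules are numbered 1..E.  Each extension module must
carry the minimal domain set (KS condensation, AT extender selection, T
carrier); reductive domains (KR, DH, ER) are optional and the chain-release
thioesterase (TE) sits in the last module only.

The module table is this package's own schema (TSV or JSON, one row per
module); see ``data/SCHEMA.md``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

DOMAIN_KINDS = ("KS", "AT", "DH", "ER", "KR", "T", "TE")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}

AT_SPECIFICITIES = ("malonyl", "methylmalonyl", "unknown")
KR_SUBTYPES = ("A1", "A2", "B1", "B2", "C1", "C2")


class ParseError(ValueError):
    """Malformed input file; message names the offending row/record."""


class ValidationError(ValueError):
    """Structurally valid input that violates an assembly-line invariant."""


@dataclass
class Finding:
    severity: str  # "error" | "warning"
    code: str
    message: str
    module_index: Optional[int] = None

    def __str__(self) -> str:
        where = f" [module {self.module_index}]" if self.module_index is not None else ""
        return f"{self.severity.upper()} {self.code}{where}: {self.message}"


@dataclass
class DomainRef:
    gene_id: str
    module_index: int
    kind: Optional[str]  # None = kind not yet determined (e.g. raw CDS translation)
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind is not None and self.kind not in DOMAIN_KINDS:
            raise ValidationError(f"unknown domain kind {self.kind!r}")
        if self.module_index < 0:
            raise ValidationError("module_index must be >= 0")
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            bad = set(self.sequence) - AA_ALPHABET
            if bad:
                raise ValidationError(
                    f"illegal residue letter(s) {sorted(bad)} in {self.gene_id} "
                    f"module {self.module_index} {self.kind}"
                )


@dataclass
class ATCall:
    specificity: str  # malonyl | methylmalonyl | unknown
    motif_observed: str = ""
    window_start: Optional[int] = None
    partial_evidence: bool = False

    def __post_init__(self) -> None:
        if self.specificity not in AT_SPECIFICITIES:
            raise ValidationError(f"bad AT specificity {self.specificity!r}")


@dataclass
class KRCall:
    subtype: str
    redox_active: bool = field(init=False)
    beta_descriptor: str = field(init=False)  # "3S" | "3R" | "none"
    epimerizing: bool = field(init=False)
    diagnostic_residues: dict = field(default_factory=dict)
    partial_evidence: bool = False

    def __post_init__(self) -> None:
        if self.subtype not in KR_SUBTYPES:
            raise ValidationError(f"bad KR subtype {self.subtype!r}")
        self.redox_active = self.subtype not in ("C1", "C2")
        self.beta_descriptor = {
            "A": "3S",
            "B": "3R",
            "C": "none",
        }[self.subtype[0]]
        self.epimerizing = self.subtype in ("A2", "B2", "C2")


@dataclass
class DHCall:
    catalytic_his_present: bool
    catalytic_asp_present: bool
    active: bool = field(init=False)

    def __post_init__(self) -> None:
        self.active = self.catalytic_his_present and self.catalytic_asp_present


@dataclass
class ERCall:
    residue_44: str
    active: bool = True
    alpha_descriptor_if_methyl: str = field(init=False)

    def __post_init__(self) -> None:
        if not self.active:
            self.alpha_descriptor_if_methyl = "not_applicable"
        elif self.residue_44 == "Y":
            self.alpha_descriptor_if_methyl = "2S"
        elif self.residue_44 == "X":
            self.alpha_descriptor_if_methyl = "not_applicable"
        else:
            self.alpha_descriptor_if_methyl = "2R"


@dataclass
class ModuleSpec:
    index: int
    domains: list
    at_call: Optional[ATCall] = None
    kr_call: Optional[KRCall] = None
    dh_call: Optional[DHCall] = None
    er_call: Optional[ERCall] = None

    def __post_init__(self) -> None:
        kinds = [d.kind for d in self.domains]
        for k in set(kinds):
            if kinds.count(k) > 1:
                raise ValidationError(f"module {self.index}: duplicate {k} domain")
        for call, kind in (
            (self.at_call, "AT"),
            (self.kr_call, "KR"),
            (self.dh_call, "DH"),
            (self.er_call, "ER"),
        ):
            if call is not None and kind not in kinds:
                raise ValidationError(
                    f"module {self.index}: {kind} call present without a {kind} domain"
                )

    def domain_kinds(self) -> set:
        return {d.kind for d in self.domains}

    def domain(self, kind: str) -> Optional[DomainRef]:
        for d in self.domains:
            if d.kind == kind:
                return d
        return None


@dataclass
class AssemblyLine:
    modules: list
    cluster_id: str = ""

    def __post_init__(self) -> None:
        indices = [m.index for m in self.modules]
        if indices != list(range(len(self.modules))):
            dupes = sorted({i for i in indices if indices.count(i) > 1})
            if dupes:
                raise ValidationError(f"duplicate module index {dupes[0]}")
            raise ValidationError(
                f"module indices must be contiguous 0..E, got {indices}"
            )
        te_modules = [m.index for m in self.modules if "TE" in m.domain_kinds()]
        if len(te_modules) != 1 or te_modules[0] != self.modules[-1].index:
            raise ValidationError(
                f"exactly one TE module required, and it must be last "
                f"(TE found in modules {te_modules})"
            )

    @property
    def n_extensions(self) -> int:
        return len(self.modules) - 1

    def module(self, index: int) -> ModuleSpec:
        return self.modules[index]


# ---------------------------------------------------------------------------
# module table IO
# ---------------------------------------------------------------------------

TABLE_COLUMNS = (
    "module_index",
    "gene_id",
    "domains",
    "at_specificity",
    "kr_subtype",
    "dh_active",
    "er_stereo",
    "partial_evidence",
)


def _row_to_module(row: dict, where: str) -> ModuleSpec:
    try:
        index = int(row["module_index"])
    except (KeyError, TypeError, ValueError):
        raise ParseError(f"{where}: bad or missing column 'module_index'")
    gene = str(row.get("gene_id", "") or "")
    domains_cell = row.get("domains", "")
    if isinstance(domains_cell, str):
        kinds = [k.strip() for k in domains_cell.split(",") if k.strip()]
    else:
        kinds = list(domains_cell)
    if not kinds:
        raise ParseError(f"{where}: empty column 'domains'")
    for k in kinds:
        if k not in DOMAIN_KINDS:
            raise ParseError(f"{where}: unknown domain kind {k!r} in column 'domains'")
    partial = str(row.get("partial_evidence", "") or "").strip().lower() in ("1", "true", "yes")
    domains = [DomainRef(gene, index, k) for k in kinds]

    at_call = kr_call = dh_call = er_call = None
    at_spec = str(row.get("at_specificity", "") or "").strip()
    if at_spec:
        if at_spec not in AT_SPECIFICITIES:
            raise ParseError(f"{where}: bad column 'at_specificity' value {at_spec!r}")
        at_call = ATCall(at_spec, partial_evidence=partial)
    kr_subtype = str(row.get("kr_subtype", "") or "").strip()
    if kr_subtype:
        if kr_subtype not in KR_SUBTYPES:
            raise ParseError(f"{where}: bad column 'kr_subtype' value {kr_subtype!r}")
        kr_call = KRCall(kr_subtype, partial_evidence=partial)
    dh_cell = str(row.get("dh_active", "") or "").strip().lower()
    if dh_cell:
        if dh_cell not in ("true", "false", "1", "0", "yes", "no"):
            raise ParseError(f"{where}: bad column 'dh_active' value {dh_cell!r}")
        active = dh_cell in ("true", "1", "yes")
        dh_call = DHCall(catalytic_his_present=True, catalytic_asp_present=active)
    er_cell = str(row.get("er_stereo", "") or "").strip()
    if er_cell:
        if er_cell not in ("2S", "2R"):
            raise ParseError(f"{where}: bad column 'er_stereo' value {er_cell!r}")
        er_call = ERCall(residue_44="Y" if er_cell == "2S" else "V")
    try:
        return ModuleSpec(index, domains, at_call, kr_call, dh_call, er_call)
    except ValidationError as exc:
        raise ParseError(f"{where}: {exc}") from exc


def read_module_table(path, dialect: Optional[str] = None) -> AssemblyLine:
    """Read a TSV or JSON module table into a validated :class:`AssemblyLine`."""
    path = Path(path)
    if dialect is None:
        dialect = "json" if path.suffix.lower() == ".json" else "tsv"
    rows: list
    if dialect == "json":
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path.name}: invalid JSON ({exc})") from exc
        cluster_id = ""
        if isinstance(payload, dict):
            cluster_id = payload.get("cluster_id", "")
            rows = payload.get("modules", [])
        else:
            rows = payload
        if not rows:
            raise ParseError(f"{path.name}: no module rows")
        modules = [_row_to_module(r, f"{path.name} object {i}") for i, r in enumerate(rows)]
    elif dialect == "tsv":
        lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
        if not lines:
            raise ParseError(f"{path.name}: empty file")
        header = lines[0].split("\t")
        if "module_index" not in header:
            raise ParseError(f"{path.name}: header row missing column 'module_index'")
        cluster_id = ""
        modules = []
        for lineno, ln in enumerate(lines[1:], start=2):
            cells = ln.split("\t")
            row = dict(zip(header, cells))
            modules.append(_row_to_module(row, f"{path.name} row {lineno}"))
            cluster_id = row.get("cluster_id", cluster_id) or cluster_id
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    indices = [m.index for m in modules]
    for i in sorted(set(indices)):
        if indices.count(i) > 1:
            raise ValidationError(f"duplicate module index {i}")
    modules.sort(key=lambda m: m.index)
    return AssemblyLine(modules, cluster_id=cluster_id)


def write_module_table(line: AssemblyLine, path, dialect: Optional[str] = None) -> None:
    path = Path(path)
    if dialect is None:
        dialect = "json" if path.suffix.lower() == ".json" else "tsv"
    rows = []
    for m in line.modules:
        partial = any(
            getattr(c, "partial_evidence", False) for c in (m.at_call, m.kr_call) if c
        )
        rows.append(
            {
                "module_index": m.index,
                "gene_id": m.domains[0].gene_id if m.domains else "",
                "domains": ",".join(d.kind for d in m.domains),
                "at_specificity": m.at_call.specificity if m.at_call else "",
                "kr_subtype": m.kr_call.subtype if m.kr_call else "",
                "dh_active": (
                    "" if m.dh_call is None else ("true" if m.dh_call.active else "false")
                ),
                "er_stereo": (
                    "" if m.er_call is None else m.er_call.alpha_descriptor_if_methyl
                ),
                "partial_evidence": "true" if partial else "",
            }
        )
    if dialect == "json":
        path.write_text(
            json.dumps({"cluster_id": line.cluster_id, "modules": rows}, indent=1) + "\n"
        )
    else:
        out = ["\t".join(TABLE_COLUMNS)]
        for r in rows:
            out.append("\t".join(str(r[c]) for c in TABLE_COLUMNS))
        path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# FASTA / GenBank readers
# ---------------------------------------------------------------------------


def read_domain_fasta(path) -> list:
    """Read domain sequences whose headers follow ``>gene_id|module_index|kind``."""
    from Bio import SeqIO

    out = []
    for recno, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        parts = rec.id.split("|")
        if len(parts) != 3:
            raise ParseError(
                f"record {recno}: header {rec.id!r} does not match gene_id|module_index|kind"
            )
        gene, idx_s, kind = parts
        try:
            idx = int(idx_s)
        except ValueError:
            raise ParseError(f"record {recno}: module_index {idx_s!r} is not an integer")
        if kind not in DOMAIN_KINDS:
            raise ParseError(f"record {recno}: unknown domain kind {kind!r}")
        try:
            out.append(DomainRef(gene, idx, kind, str(rec.seq)))
        except ValidationError as exc:
            raise ParseError(f"record {recno}: {exc}") from exc
    return out


def read_genbank_cluster(path) -> list:
    """CDS translations from a GenBank flat file as kind-undetermined domains.

    Domain-kind annotation inside the CDS translations is left to downstream
    motif scanning or to a user-provided mapping; this reader never invents
    module indices (all entries come back with ``module_index=0`` and the
    locus/protein identifier as ``gene_id``).
    """
    from Bio import SeqIO

    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise ParseError(f"{Path(path).name}: {exc}") from exc
    out = []
    for rec in records:
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            translation = quals.get("translation", [None])[0]
            if translation is None:
                continue
            gene = (
                quals.get("locus_tag", [None])[0]
                or quals.get("gene", [None])[0]
                or quals.get("protein_id", [rec.id])[0]
            )
            out.append(DomainRef(gene, 0, None, translation))
    if not out:
        warnings.warn(f"{Path(path).name}: no CDS features with /translation found")
    return out


# ---------------------------------------------------------------------------
# architecture validation
# ---------------------------------------------------------------------------


def validate_architecture(line: AssemblyLine) -> list:
    """Check the minimal domain inventory; returns findings, never raises."""
    findings = []
    for m in line.modules:
        kinds = m.domain_kinds()
        if m.index == 0:
            required = {"AT", "T"}
        else:
            required = {"KS", "AT", "T"}
        missing = required - kinds
        for k in sorted(missing):
            findings.append(
                Finding(
                    "error",
                    "missing-domain",
                    f"module {m.index} lacks required {k} domain",
                    m.index,
                )
            )
        if "DH" in kinds and "KR" not in kinds:
            findings.append(
                Finding(
                    "warning",
                    "dh-without-kr",
                    f"module {m.index} has DH but no KR; DH cannot act on an "
                    "unreduced beta-ketone",
                    m.index,
                )
            )
        if "ER" in kinds and "DH" not in kinds:
            findings.append(
                Finding(
                    "warning",
                    "er-without-dh",
                    f"module {m.index} has ER but no DH; ER needs an enoyl substrate",
                    m.index,
                )
            )
    return findings
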