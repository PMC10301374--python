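"""Motif-based classification of AT, KR, DH and ER catalytic domains.

Each classifier aligns the query to a bundled reference consensus for its
domain kind and reads diagnostic residues at reference coordinates.  The
coordinates, expected residues and their meanings live in
``data/diagnostics.tsv`` (single auditable source of truth), the reference
sequences in ``data/references.fasta``:

* AT — the 4-residue extender-specificity window: HAFH = malonyl-CoA,
  YASH = methylmalonyl-CoA, anything else = unknown (exact match only
  unless ``fuzzy`` is requested).
* KR — decision procedure: catalytic Ser/Tyr/Asn triad absent -> C-type
  (redox-inactive); else the LDD fingerprint -> B-type, the conserved
  Trp -> A-type; the epimerization fingerprint splits 1 vs 2 subtypes.
  A (3S)-hydroxyl comes from A-types, (3R) from B-types.
* DH — active iff both the catalytic His and the catalytic Asp are present.
* ER — the residue at reference position 44: Tyr dictates a (2S)-2-methyl
  product on methylmalonyl units, otherwise 2R.

An ``X`` at a diagnostic position always degrades the call (unknown /
no-call), never guesses.  Alignment is deterministic: fixed substitution
matrix, fixed affine gap penalties, first (leftmost) optimal traceback.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Optional

from .cluster import (
    AssemblyLine,
    ATCall,
    DHCall,
    ERCall,
    Finding,
    KRCall,
)

MIN_QUERY_LENGTH = 50
MIN_DIAGNOSTIC_COVERAGE = 0.8

GAP_OPEN = -10.0
GAP_EXTEND = -1.0
SUBSTITUTION_MATRIX = "BLOSUM62"


class UnalignableError(ValueError):
    """Query cannot be aligned to the reference diagnostic region."""


class UnknownCallError(ValueError):
    """Diagnostics are unreadable (X residues) or contradictory."""


@dataclass(frozen=True)
class Diagnostic:
    kind: str
    start: int  # 1-based, inclusive, on the reference
    end: int
    expected: str
    meaning: str


@lru_cache(maxsize=1)
def reference_sequences() -> dict:
    from Bio import SeqIO

    refs = {}
    with resources.files("pkstereo.data").joinpath("references.fasta").open() as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            refs[rec.id] = str(rec.seq)
    return refs


@lru_cache(maxsize=1)
def diagnostics() -> tuple:
    rows = []
    with resources.files("pkstereo.data").joinpath("diagnostics.tsv").open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for ln in fh:
            if not ln.strip():
                continue
            cells = dict(zip(header, ln.rstrip("\n").split("\t")))
            pos = cells["positions"]
            if "-" in pos:
                start, end = (int(x) for x in pos.split("-"))
            else:
                start = end = int(pos)
            rows.append(
                Diagnostic(cells["domain_kind"], start, end, cells["expected"], cells["meaning"])
            )
    return tuple(rows)


def diagnostic(meaning: str) -> Diagnostic:
    for d in diagnostics():
        if d.meaning == meaning:
            return d
    raise KeyError(meaning)


def diagnostic_positions(kind: str) -> list:
    """All 1-based reference positions that are diagnostic for ``kind``."""
    out = set()
    for d in diagnostics():
        if d.kind == kind:
            out.update(range(d.start, d.end + 1))
    return sorted(out)


@lru_cache(maxsize=1)
def _aligner():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = Align.substitution_matrices.load(SUBSTITUTION_MATRIX)
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def align_to_reference(seq: str, domain_kind: str) -> dict:
    """Map reference position (1-based) -> query position (1-based) or None.

    Raises :class:`UnalignableError` when fewer than 80% of the reference
    diagnostic-region columns align to query residues.
    """
    refs = reference_sequences()
    if domain_kind not in refs:
        raise KeyError(f"no bundled reference for domain kind {domain_kind!r}")
    if len(seq) < MIN_QUERY_LENGTH:
        raise UnalignableError(f"query too short ({len(seq)} aa < {MIN_QUERY_LENGTH})")
    ref = refs[domain_kind]
    alignment = _aligner().align(ref, seq.upper())[0]
    mapping = {p: None for p in range(1, len(ref) + 1)}
    for (rs, re_), (qs, qe) in zip(*alignment.aligned):
        for k in range(re_ - rs):
            mapping[rs + k + 1] = qs + k + 1
    diag = diagnostic_positions(domain_kind)
    lo, hi = diag[0], diag[-1]
    region = range(lo, hi + 1)
    covered = sum(1 for p in region if mapping[p] is not None)
    if covered < MIN_DIAGNOSTIC_COVERAGE * len(region):
        raise UnalignableError(
            f"only {covered}/{len(region)} diagnostic-region columns aligned"
        )
    return mapping


def _residues(seq: str, mapping: dict, start: int, end: int) -> str:
    out = []
    for p in range(start, end + 1):
        q = mapping.get(p)
        out.append(seq[q - 1] if q is not None else "-")
    return "".join(out)


# ---------------------------------------------------------------------------
# per-domain classifiers
# ---------------------------------------------------------------------------


def classify_at(seq: str, fuzzy: bool = False) -> ATCall:
    """AT extender-unit specificity from the 4-residue motif window.

    Exact-match only by default; with ``fuzzy=True`` a single mismatch
    outside the first motif position is accepted and flagged as
    low-confidence (``partial_evidence``).
    """
    seq = seq.upper()
    try:
        mapping = align_to_reference(seq, "AT")
    except UnalignableError:
        return ATCall("unknown", partial_evidence=True)
    d = diagnostic("at-motif-malonyl")
    window = _residues(seq, mapping, d.start, d.end)
    window_start = mapping.get(d.start)
    if "X" in window or "-" in window:
        return ATCall("unknown", window, window_start, partial_evidence=True)
    exact = {"HAFH": "malonyl", "YASH": "methylmalonyl"}
    if window in exact:
        return ATCall(exact[window], window, window_start)
    if fuzzy:
        for motif, spec in exact.items():
            mism = [i for i in range(4) if window[i] != motif[i]]
            if len(mism) == 1 and mism[0] != 0:
                return ATCall(spec, window, window_start, partial_evidence=True)
    return ATCall("unknown", window, window_start)


def classify_kr(seq: str, findings: Optional[list] = None) -> KRCall:
    """KR subtype via the triad / LDD / Trp / epimerization fingerprints."""
    seq = seq.upper()
    mapping = align_to_reference(seq, "KR")  # UnalignableError propagates

    res = {}
    for meaning in (
        "kr-triad-ser",
        "kr-triad-tyr",
        "kr-triad-asn",
        "kr-a-fingerprint",
        "kr-epimerization",
    ):
        d = diagnostic(meaning)
        res[meaning] = _residues(seq, mapping, d.start, d.end)
    d = diagnostic("kr-b-fingerprint")
    res["kr-b-fingerprint"] = _residues(seq, mapping, d.start, d.end)

    triad = [res["kr-triad-ser"], res["kr-triad-tyr"], res["kr-triad-asn"]]
    if any(r == "X" for r in triad + [res["kr-epimerization"]]):
        raise UnknownCallError("X at a KR diagnostic position; refusing to guess")
    triad_present = triad == ["S", "Y", "N"]
    b_present = res["kr-b-fingerprint"] == "LDD"
    a_present = res["kr-a-fingerprint"] == "W"
    epim = res["kr-epimerization"] == "E"

    if not triad_present:
        subtype = "C2" if epim else "C1"
    elif b_present and a_present:
        if findings is not None:
            findings.append(
                Finding(
                    "warning",
                    "kr-fingerprint-conflict",
                    "both the B-type (LDD) and A-type (Trp) fingerprints present; "
                    "resolved to B (the more specific signal)",
                )
            )
        subtype = "B2" if epim else "B1"
    elif b_present:
        subtype = "B2" if epim else "B1"
    elif a_present:
        subtype = "A2" if epim else "A1"
    else:
        if findings is not None:
            findings.append(
                Finding(
                    "warning",
                    "kr-fingerprint-missing",
                    "catalytic triad present but neither the A- nor the B-type "
                    "fingerprint found; defaulted to B",
                )
            )
        subtype = "B2" if epim else "B1"

    diag_map = {
        "triad": "".join(triad),
        "b_fingerprint": res["kr-b-fingerprint"],
        "a_fingerprint": res["kr-a-fingerprint"],
        "epimerization": res["kr-epimerization"],
    }
    return KRCall(subtype, diagnostic_residues=diag_map)


def classify_dh(seq: str) -> DHCall:
    """DH activity: both catalytic His and catalytic Asp must be present."""
    seq = seq.upper()
    try:
        mapping = align_to_reference(seq, "DH")
    except UnalignableError:
        return DHCall(catalytic_his_present=False, catalytic_asp_present=False)
    his = _residues(seq, mapping, diagnostic("dh-catalytic-his").start, diagnostic("dh-catalytic-his").end)
    asp = _residues(seq, mapping, diagnostic("dh-catalytic-asp").start, diagnostic("dh-catalytic-asp").end)
    return DHCall(catalytic_his_present=his == "H", catalytic_asp_present=asp == "D")


def classify_er(seq: str) -> ERCall:
    """ER stereospecificity from the residue at reference position 44."""
    seq = seq.upper()
    try:
        mapping = align_to_reference(seq, "ER")
    except UnalignableError:
        return ERCall(residue_44="-", active=False)
    d = diagnostic("er-tyr44")
    res = _residues(seq, mapping, d.start, d.end)
    return ERCall(residue_44=res)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def classify_all(
    line: AssemblyLine,
    findings: Optional[list] = None,
    fuzzy_at: bool = False,
) -> AssemblyLine:
    """Fill classifier calls for every sequenced domain of ``line``.

    Calls already present (e.g. transcribed from a table) are never
    overwritten; a disagreement between the existing call and the sequence-
    derived one is reported as a finding.  All classifier failures degrade
    to absent/unknown calls with findings.
    """
    if findings is None:
        findings = []
    for m in line.modules:
        for kind in ("AT", "KR", "DH", "ER"):
            dom = m.domain(kind)
            if dom is None or not dom.sequence:
                continue
            attr = f"{kind.lower()}_call"
            existing = getattr(m, attr)
            try:
                if kind == "AT":
                    call = classify_at(dom.sequence, fuzzy=fuzzy_at)
                elif kind == "KR":
                    call = classify_kr(dom.sequence, findings)
                elif kind == "DH":
                    call = classify_dh(dom.sequence)
                else:
                    call = classify_er(dom.sequence)
            except (UnalignableError, UnknownCallError) as exc:
                findings.append(
                    Finding(
                        "warning",
                        "classification-failed",
                        f"{kind} of module {m.index}: {exc}",
                        m.index,
                    )
                )
                continue
            if existing is None:
                setattr(m, attr, call)
                continue
            disagree = (
                (kind == "AT" and existing.specificity != call.specificity)
                or (kind == "KR" and existing.subtype != call.subtype)
                or (kind == "DH" and existing.active != call.active)
                or (
                    kind == "ER"
                    and existing.alpha_descriptor_if_methyl
                    != call.alpha_descriptor_if_methyl
                )
            )
            if disagree:
                findings.append(
                    Finding(
                        "warning",
                        "call-disagreement",
                        f"{kind} of module {m.index}: table call kept over "
                        f"sequence-derived call",
                        m.index,
                    )
                )
    return line
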