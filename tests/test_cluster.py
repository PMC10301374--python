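"""Assembly-line data model, table/FASTA/GenBank IO, architecture checks."""

import pytest

from pkstereo.cluster import (
    AssemblyLine,
    DomainRef,
    ModuleSpec,
    ParseError,
    ValidationError,
    read_domain_fasta,
    read_genbank_cluster,
    read_module_table,
    validate_architecture,
    write_module_table,
)
from pkstereo.synth import make_cluster, minimal_architecture_calls, mld_fixture


@pytest.mark.parametrize("dialect", ["tsv", "json"])
def test_module_table_round_trip(tmp_path, dialect):
    line, _ = mld_fixture()
    path = tmp_path / f"modules.{dialect}"
    write_module_table(line, path, dialect)
    back = read_module_table(path, dialect)
    assert len(back.modules) == len(line.modules)
    for a, b in zip(back.modules, line.modules):
        assert a.index == b.index
        assert a.domain_kinds() == b.domain_kinds()
        assert (a.at_call is None) == (b.at_call is None)
        if a.at_call:
            assert a.at_call.specificity == b.at_call.specificity
        if a.kr_call:
            assert a.kr_call.subtype == b.kr_call.subtype
            assert a.kr_call.beta_descriptor == b.kr_call.beta_descriptor
        if b.dh_call:
            assert a.dh_call.active == b.dh_call.active


def test_mld_table_reads_sixteen_modules():
    line, _ = mld_fixture()
    assert len(line.modules) == 16
    assert line.n_extensions == 15
    assert line.cluster_id == "OL257848"


def test_empty_table_is_a_parse_error(tmp_path):
    p = tmp_path / "empty.tsv"
    p.write_text("")
    with pytest.raises(ParseError):
        read_module_table(p)


def test_malformed_row_names_row_and_column(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("module_index\tgene_id\tdomains\n0\tg\tAT,T\nxx\tg\tKS,AT,T\n")
    with pytest.raises(ParseError, match="row 3.*module_index"):
        read_module_table(p)


def test_duplicate_module_index_rejected(tmp_path):
    p = tmp_path / "dup.tsv"
    p.write_text(
        "module_index\tgene_id\tdomains\n0\tg\tAT,T\n1\tg\tKS,AT,T,TE\n1\tg\tKS,AT,T\n"
    )
    with pytest.raises(ValidationError, match="duplicate module index 1"):
        read_module_table(p)


def test_two_te_modules_rejected():
    mods = [
        ModuleSpec(0, [DomainRef("g", 0, k) for k in ("AT", "T", "TE")]),
        ModuleSpec(1, [DomainRef("g", 1, k) for k in ("KS", "AT", "T", "TE")]),
    ]
    with pytest.raises(ValidationError, match="exactly one TE"):
        AssemblyLine(mods)


def test_te_must_be_terminal():
    mods = [
        ModuleSpec(0, [DomainRef("g", 0, k) for k in ("AT", "T", "TE")]),
        ModuleSpec(1, [DomainRef("g", 1, k) for k in ("KS", "AT", "T")]),
    ]
    with pytest.raises(ValidationError):
        AssemblyLine(mods)


def test_call_without_domain_rejected():
    from pkstereo.cluster import KRCall

    with pytest.raises(ValidationError, match="KR call"):
        ModuleSpec(1, [DomainRef("g", 1, k) for k in ("KS", "AT", "T")], kr_call=KRCall("B1"))


def test_illegal_residue_rejected():
    with pytest.raises(ValidationError, match="illegal residue"):
        DomainRef("g", 1, "KR", "MKLJ")  # J is not an amino-acid letter


# -- FASTA ----------------------------------------------------------------


def test_fasta_header_grammar(tmp_path):
    p = tmp_path / "d.fasta"
    p.write_text(">mldA|1|KR\nMKLV\n")
    (ref,) = read_domain_fasta(p)
    assert (ref.gene_id, ref.module_index, ref.kind, ref.sequence) == ("mldA", 1, "KR", "MKLV")


def test_fasta_unknown_kind_is_parse_error(tmp_path):
    p = tmp_path / "d.fasta"
    p.write_text(">mldA|1|XX\nMKLV\n")
    with pytest.raises(ParseError, match="record 1"):
        read_domain_fasta(p)


def test_fasta_lowercase_upcased_and_order_preserved(tmp_path):
    cluster = make_cluster(minimal_architecture_calls(), seed=1)
    p = tmp_path / "c.fasta"
    lowered = "\n".join(
        ln if ln.startswith(">") else ln.lower()
        for ln in cluster.fasta().splitlines()
    )
    p.write_text(lowered + "\n")
    back = read_domain_fasta(p)
    assert [d.sequence for d in back] == [d.sequence for d in cluster.domains]
    assert [(d.module_index, d.kind) for d in back] == [
        (d.module_index, d.kind) for d in cluster.domains
    ]


# -- GenBank --------------------------------------------------------------


def _write_genbank(tmp_path, translations):
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    rec = SeqRecord(Seq("ATG" * 60), id="SYN001", name="SYN001",
                    description="synthetic mini-cluster record",
                    annotations={"molecule_type": "DNA"})
    for k, t in enumerate(translations):
        quals = {"locus_tag": [f"orf{k+1}"]}
        if t is not None:
            quals["translation"] = [t]
        rec.features.append(
            SeqFeature(FeatureLocation(k * 30, k * 30 + 30), type="CDS", qualifiers=quals)
        )
    p = tmp_path / "mini.gbk"
    SeqIO.write([rec], str(p), "genbank")
    return p


def test_genbank_single_cds(tmp_path):
    p = _write_genbank(tmp_path, ["MKLVAQPTRS"])
    (ref,) = read_genbank_cluster(p)
    assert ref.sequence == "MKLVAQPTRS"
    assert ref.kind is None  # kind is never fabricated
    assert ref.gene_id == "orf1"


def test_genbank_two_cds_in_file_order(tmp_path):
    p = _write_genbank(tmp_path, ["MAAAA", "MCCCC"])
    refs = read_genbank_cluster(p)
    assert [r.sequence for r in refs] == ["MAAAA", "MCCCC"]


def test_genbank_without_translations_warns(tmp_path):
    p = _write_genbank(tmp_path, [None])
    with pytest.warns(UserWarning, match="no CDS"):
        assert read_genbank_cluster(p) == []


# -- architecture ---------------------------------------------------------


def test_mld_architecture_is_clean(mld_line):
    assert validate_architecture(mld_line) == []


def test_missing_at_is_an_error():
    mods = [
        ModuleSpec(0, [DomainRef("g", 0, k) for k in ("AT", "T")]),
        ModuleSpec(1, [DomainRef("g", 1, k) for k in ("KS", "T", "TE")]),
    ]
    findings = validate_architecture(AssemblyLine(mods))
    assert [f.severity for f in findings] == ["error"]
    assert "AT" in findings[0].message


def test_dh_without_kr_is_a_warning():
    mods = [
        ModuleSpec(0, [DomainRef("g", 0, k) for k in ("AT", "T")]),
        ModuleSpec(1, [DomainRef("g", 1, k) for k in ("KS", "AT", "DH", "T", "TE")]),
    ]
    findings = validate_architecture(AssemblyLine(mods))
    assert [(f.severity, f.code) for f in findings] == [("warning", "dh-without-kr")]
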