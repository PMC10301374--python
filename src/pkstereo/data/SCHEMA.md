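# Module table schema (v1)

One row (TSV) or object (JSON) per assembly-line module. TSV is UTF-8,
tab-delimited, header row mandatory. JSON is either a bare list of row
objects or `{"cluster_id": ..., "modules": [...]}`.

| column | type | meaning |
|---|---|---|
| `module_index` | int >= 0 | 0 = loading module; extensions are 1..E (contiguous) |
| `gene_id` | text | PKS gene carrying the module |
| `domains` | comma-joined kinds | subset of KS, AT, DH, ER, KR, T, TE |
| `at_specificity` | `malonyl` / `methylmalonyl` / `unknown` / empty | AT extender-unit call; empty = no call |
| `kr_subtype` | `A1`/`A2`/`B1`/`B2`/`C1`/`C2` / empty | KR subtype call |
| `dh_active` | `true`/`false` / empty | DH activity call; empty = no call |
| `er_stereo` | `2S`/`2R` / empty | alpha-methyl descriptor installed by an active ER |
| `partial_evidence` | `true` / empty | call rests on an incomplete sequence |

Unspecified call cells are absent calls, never defaults. An optional
`cluster_id` column (TSV) or top-level key (JSON) names the cluster.

# Reference diagnostics (`diagnostics.tsv`)

Single source of truth for classifier coordinates, all 1-based on the
bundled reference sequence of each domain kind (`references.fasta`):
`domain_kind`, `positions` (single or `start-end`), `expected` residue(s),
and a stable `meaning` key the classifier dispatches on.
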