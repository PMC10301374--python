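# Methods

## Scope and model

`pkstereo` models cis-AT modular type I PKS assembly lines under strict
collinearity: one chain extension per module, module order equal to product
carbon order, no module skipping, no iteration, no trans-AT complementation.
The loading unit is modeled as a two-carbon acetyl starter (decarboxylated
malonyl), which matches lines whose loading AT groups with the
malonyl-specific extension ATs and yields a methyl-ketone terminus when the
first extension KR is redox-inactive. The thioester terminus is carried as
a free carboxyl until macrolactonization consumes it.

With E extension modules the backbone has 2(E+1) carbons; total carbons are
2(E+1) plus one per methylmalonyl-specific module. Position arithmetic:
extension module m contributes C(2(E−m)+1) (acyl) and C(2(E−m)+2) (α); its
reductive domains act on C(2(E−m)+3), the acyl carbon delivered by the
upstream module.

## Stereorules

The reductive-loop state machine (`build.apply_reductive_loop`) encodes the
field's standard conventions:

| evidence | β outcome | α-methyl outcome |
|---|---|---|
| no KR, or C1/C2 subtype | ketone | 2R (C2: epimerized to 2S) |
| A1 / A2 | (3S)-hydroxyl | 2R / 2S |
| B1 / B2 | (3R)-hydroxyl | 2R / 2S |
| + active DH | E-2-enoyl | none (sp², descriptor dropped) |
| + active DH + active ER | methylene | 2S if ER Tyr-44, else 2R |

An inactive DH (missing catalytic Asp or His) is treated as absent. An
active DH without any KR is rejected as chemically impossible. The
unreduced α-methyl default is 2R — the condensation product's
configuration — overridden only by an epimerizing subtype or the ER rule.

These 2R/2S/3R/3S labels are assembly-line-local acyl descriptors defined
on the generic ACP-tethered intermediate, where the thioester-proximal
branch always outranks the distal chain. They are converted to neighbor-
order parities with exactly that fixed priority (β-hydroxyl carbons:
OH > C(prox) > C(dist) > H; α-methyl carbons: C(prox) > C(dist) > CH3 > H)
and final R/S labels are recomputed by the CIP engine on the finished
molecule. The two layers genuinely differ: in the marinolide backbone the
(2S) centers C-10 and C-11 read *R* on the open chain and *S* after pyran
closure, and the (3S) center C-9 reads *R* in the product — all pure
priority effects, no bond inversion.

## Domain classification

Classifiers align a query to a bundled per-kind reference consensus and
read residues at reference coordinates listed in `data/diagnostics.tsv`
(the single, auditable source of truth; `references.fasta` carries the
sequences). Alignment is `Bio.Align.PairwiseAligner`, global mode,
BLOSUM62, gap open 10 / extend 1, first optimal traceback; a query is
"unalignable" when under 80% of the diagnostic-region columns align, and
every failure degrades to an unknown/no-call with a finding — never a
guess. An `X` at a diagnostic position likewise refuses a call.

Decision procedures: AT — exact 4-residue motif match (HAFH/YASH); a
single mismatch outside the motif's first position is accepted only under
the opt-in fuzzy mode and flagged low-confidence. KR — catalytic
Ser/Tyr/Asn triad absent ⇒ C-type; else LDD fingerprint ⇒ B, conserved
Trp ⇒ A; the epimerization fingerprint splits subtype 1 from 2. When both
the LDD and Trp fingerprints appear, the call resolves to B with a warning
(LDD is the more specific signal); the same fallback (with a warning)
covers a triad-positive domain showing neither fingerprint. DH — active
iff catalytic His and Asp are both present. ER — the residue at reference
position 44, defined on the bundled reference coordinate system.

The reference scaffolds are curated synthetic consensus sequences built
for this package (seeded draws over the canonical residues with the
diagnostic motifs embedded at documented coordinates); they anchor the
coordinate system and are not database-derived family profiles. This is
sufficient because every decision reads only diagnostic columns.

## Synthetic data

`synth.make_domain` emulates a homologous family member: the reference
scaffold with seeded uniform substitutions at 20% divergence (plus an
optional extra `mutation_rate`), never touching diagnostic positions ± a
3-residue flank, then the diagnostic residues for the requested call are
written in. All randomness flows through numpy's PCG64 with an explicit
seed, so outputs are byte-identical across platforms. What this does and
does not show: recovery tests prove the classifiers read the right
alignment columns under realistic sequence noise and indel-free
divergence; they do not validate the biological motif conventions
themselves, nor performance on domains with long insertions, split genes,
or divergence far beyond ~30%. Real partial sequences are handled by the
`partial_evidence` flag, which annotates but never changes a call
(downweighting partial-evidence calls is deliberately not modeled).

The random-molecule generator (`make_random_molecule`) used by the CIP
oracle harness builds seeded CHO trees with occasional rings and double
bonds, then marks random parities on every carbon whose four branches are
constitutionally distinct under the implemented CIP rules. Centers whose
stereogenicity depends on other stereocenters (CIP Rules 3–5 territory)
are by construction out of the engine's declared scope and are left
unmarked; the engine's error contract (below) still surfaces any such
center encountered in real use.

## Tailoring

Graph edits: macrolactonization removes the carboxyl OH and bonds the site
oxygen to C-1 (net −H2O); hemiketal formation is an isomerization (ketone
→ C–O bond + OH), restricted to the 6-membered pyran (pair separated by
four backbone bonds); epoxidation adds one oxygen across a recorded
double bond. The edits commute on these scaffolds and are applied in a
fixed order (lactonize → hemiketal → epoxidize) for determinism; which
tailoring enzyme performs the pyran closure is annotation, not chemistry,
and is left open. Only the two lactonization sites of the bundled plan are
defaults; other hydroxyls are reachable behind `--force-site`.

Tailoring-born stereocenters start `unassigned`. Experimental descriptors,
when supplied, are realized by parity search (set the parity whose CIP
label matches). For the epoxide the two geometry-consistent parity pairs
are derived from an idealized local 3D construction of the E-olefin with
the oxygen added to either face; a requested pair outside those two (a cis
pair) is rejected with the allowed alternatives named. Experimental values
for centers already predicted bioinformatically are cross-checks only: a
disagreement becomes a warning finding, never an override.

## Molecular graph numerics

Elements C/H/N/O (+ halogens for test molecules), bond orders 1–2,
implicit hydrogens completed from standard valences; any valence violation
raises naming the atom. Monoisotopic masses are pinned to 7+ decimals in
`data/atomic_masses.json`; adduct masses ignore the electron mass
(matching the "calcd." convention) and output is rounded half-up to 4
decimals. DBE is computed as C − H/2 + N/2 + 1 and cross-checked
structurally as rings + π bonds. Ring perception uses a minimum cycle
basis with output sorted by (size, member indices) for reproducibility;
the macrolactone size is the smallest cycle containing the ester C–O bond
— for the 24-membered marinolide A ring this path runs through the pyran
oxygen, not around the all-carbon chain.

### CIP engine

R/S assignment implements Sequence Rules 1a, 1b and 2 on the hierarchical
digraph (duplicate atoms for π bonds and ring closures, duplicates
childless). Branch comparison is breadth-first, sphere by sphere, with
sibling order itself fixed by recursive comparison; this matters — a
depth-first subtree comparison ranks real polyketide branches incorrectly
whenever a sphere decides before a deeper heavy atom is reached (the C-11
branches of the marinolide backbone are such a case). Rule 1b ranks
duplicate nodes below real nodes of equal atomic number and nearer-origin
duplicates higher; Rule 2 is vacuous (no isotopes representable). If two
branches remain indistinguishable the engine raises a CIP-incomplete error
naming the center rather than guessing — Rules 3–5 (like/unlike, auxiliary
descriptors) are intentionally out of scope, as no achiral-skeleton CHO
polyketide of this family needs them; the error contract turns a silent
wrong answer into a loud one if that assumption ever fails.

### SMILES writer

Atom order is a Morgan-style canonical ranking (invariants refined by
neighbor-rank multisets; remaining ties broken at the lowest atom index,
then re-refined), so identical graphs serialize identically. Tetrahedral
parities become @/@@ from the permutation between stored neighbor order
and written order (implicit H in its bracket position); double-bond
geometry becomes directional bonds via a per-bond up/down assignment with
conflict detection, including directional ring-closure digits when the
spanning tree cuts a geometry-bearing bond. There is no reader; round
trips are verified against an independent toolkit in the tests.

## Problem sizes and defaults

The bundled fixture is the full 16-module line (52-atom product graphs).
Test and acceptance sweeps use 216 synthetic domains per noise level for
classifier recovery, 200 random molecules for the CIP oracle comparison,
50–100 random assembly lines (E ≤ 15) for conservation properties, and 50
index permutations for CIP invariance — sizes chosen to exercise every
rule branch while keeping the whole suite in seconds on one core.

## Known limitations

- Collinearity only: no trans-AT systems, iterative modules, module
  skipping or stuttering.
- Starter units other than (decarboxylated) malonyl/acetyl are not
  modeled; neither are unusual extenders (ethylmalonyl, methoxymalonyl).
- Tailoring is limited to lactonization, pyran hemiketal and epoxidation;
  glycosylation, halogenation and oxidative rearrangements are absent.
- KR/DH/ER motif conventions are encoded as given; the classifiers do not
  learn from data, and phylogenetic KR typing is out of scope.
- CIP Rules 3–5 are unimplemented by design (loud error instead).
- The α-methyl descriptor of a redox-inactive non-epimerizing module rests
  on the 2R condensation-default convention; a printed intermediate label
  can legitimately differ from the generic acyl descriptor once the
  specific substituents change CIP priorities (the C-27/"(3R)" case), so
  the report keeps subtype descriptors and final CIP labels as separate
  columns rather than reconciling them by hand.
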