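# pkstereo

Stereostructure prediction for products of modular type I polyketide
synthases (PKS), from domain-level sequence evidence to a fully
stereo-annotated molecular graph.

## The problem

Bacterial macrolactones routinely carry a dozen or more stereocenters; a
molecule with 16 chiral centers has 2^16 = 65,536 possible stereoisomers,
and assigning the right one spectroscopically is among the hardest tasks in
natural-products chemistry. Modular type I PKS assembly lines, however,
encode much of that stereochemistry in sequence: the ketoreductase (KR)
domain of each module reduces the β-keto group with a subtype-specific
hand, and the enoylreductase (ER) sets the α-methyl configuration. Reading
those domains therefore predicts most of the product's stereocenters before
a single NMR spectrum is measured.

`pkstereo` implements that reading as a reusable pipeline, developed around
the marinolides — 24- and 26-membered macrolactones (marinolides A and B,
C41H70O11, from the marine actinobacterium strain AJS-327, *mld* cluster,
GenBank OL257848) whose 16-stereocenter assignment rests on exactly this
kind of analysis. The bundled `mld` fixture transcribes that assembly line:
a loading module plus 15 extension modules across seven PKS genes
(*mldA*–*mldG*).

## The model

1. **Domain classification** (`pkstereo.classify`). Each catalytic domain
   is aligned to a bundled reference consensus (BLOSUM62, affine gaps
   10/1, deterministic traceback) and diagnostic residues are read at
   reference coordinates:
   - AT: the 4-residue specificity window — `HAFH` selects malonyl-CoA
     (acetate unit), `YASH` selects methylmalonyl-CoA (propionate unit);
   - KR: six subtypes — A-types give (3*S*)-hydroxyls, B-types (3*R*),
     C-types are redox-inactive; the "2" subtypes (A2/B2/C2) additionally
     epimerize the α-methyl from 2*R* to 2*S*;
   - DH: active only with both the catalytic His and Asp, producing the
     *E*-2-enoyl intermediate;
   - ER: a Tyr at reference position 44 dictates a (2*S*)-2-methyl product.
2. **Backbone construction** (`pkstereo.build`). Collinearity: with E
   extension modules, module *m* contributes carbons C(2(E−m)+1) and
   C(2(E−m)+2), and its reductive loop acts on C(2(E−m)+3). The reductive
   state machine maps (KR, DH, ER) calls to ketone / hydroxyl / *E*-enoyl /
   methylene states with assembly-line-local stereodescriptors.
3. **Post-PKS tailoring** (`pkstereo.tailor`). Thioesterase
   macrolactonization at a chain hydroxyl, hemiketal tetrahydropyran
   formation (ketone + δ-hydroxyl), and suprafacial epoxidation of an
   *E*-olefin (which admits only the trans descriptor pairs).
4. **Molecular-graph analysis** (`pkstereo.molgraph`, `cip`, `smiles`).
   Formula, monoisotopic/adduct mass, degrees of unsaturation, smallest
   rings, macrolactone size — and final R/S labels from a native
   Cahn–Ingold–Prelog engine (Sequence Rules 1a/1b/2, breadth-first sphere
   comparison). The local acyl descriptors are *not* final CIP labels:
   ring closure can flip them (C-10/C-11 are *R* on the open chain but *S*
   in the pyran-closed macrolactone) — which is why the CIP engine runs on
   the finished graph.

Stereocenters carry provenance: `bioinformatic` (13 of 16 for the
marinolides), `experimental` (supplied descriptors for tailoring-born
centers), or `unassigned`.

## Worked example

```
pkstereo predict --table src/pkstereo/data/mld_modules.tsv --product B \
    --experimental-configs exp.json --out-dir out/
```

with `exp.json` containing `{"5": "S", "18": "R", "19": "R"}` (the three
tailoring-born centers, not predictable from the PKS domains) prints:

```
- formula: **C41H70O11**
- monoisotopic mass: 738.4918 Da ([M+Na]+ calcd. 761.4816)
- degrees of unsaturation: 7
- rings: 3 (sizes 3, 6, 26)
- macrolactone ring size: 26
...
- total: 16 (stereoisomer space 2^16 = 65536)
- provenance: bioinformatic 13, experimental 3, unassigned 0
```

and a per-center table whose descriptor column reads
`4S,5S,9R,10S,11S,12S,13S,16S,17R,18R,19R,23R,25S,26S,27S,30R` — e.g.

```
| C-9  | R | bioinformatic | KR A1 (module 12) -> (3S)-hydroxyl |
| C-18 | R | experimental  | epoxidation of the C-18=C-19 E-olefin |
```

The formula is that of both marinolides; 761.4816 is the calculated
[M+Na]+ for C41H70O11Na; the three rings are the epoxide, the pyran
hemiketal and the 26-membered lactone (`--product A` gives the 24-membered
ring instead). Note C-9: a (3*S*)-hydroxyl from an A1 ketoreductase ends
up *R* in the final molecule purely by CIP priority changes.

Other subcommands: `classify` (sequence → calls JSON), `build` (per-carbon
backbone table), `synth` (seeded synthetic clusters with truth tables),
`report` (re-render a saved report).

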