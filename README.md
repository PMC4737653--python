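# sheetfuse

Backbone-level design of chimeric protein domains by **beta-sheet fusion**:
insert one small alpha/beta domain into another so that the two beta sheets
merge into a single extended sheet.

Complex beta-sheet topologies are hard to design de novo because the number of
alternative strand packings explodes with sheet size.  One route around this is
recombination: take two small, well-folded sheet-containing domains (a *host*
and an *insert*), find a point in the host where the insert's termini can be
grafted so that host and insert strands concatenate into longer strands of one
merged sheet, splice the backbones, and hand the junction neighbourhood to a
sequence-design engine.  `sheetfuse` implements the geometric half of that
protocol — the search, the splice, and the evaluation — as a reusable Python
library with a thin command-line interface.  It is aimed at protein designers
and structural bioinformaticians who want a scriptable, dependency-light
implementation of the insertion-point search and its quality metrics.

## The algorithm

Given host and insert backbones (N, CA, C, O per residue):

1. **Probe enumeration.** Pair each of the first 3 residues of the insert with
   each of the last 3: 3 × 3 = 9 *terminal residue pairs* (probes), the
   geometric search keys.
2. **Insertion-point scan.** Superpose each probe's 8 backbone atoms onto every
   host residue pair (i, j) with fewer than 5 residues between them (Kabsch
   SVD superposition, proper rotations only).  A site is accepted when the
   pair RMSD ≤ 1 Å.
3. **Splice.** Map the insert onto the host frame with the site's transform,
   delete the host segment strictly between i and j, keep the host residues at
   i and j in place of the insert's probe residues (preserving the host's
   sheet register), and connect the junctions with 0–3 residue linkers whose
   torsions are closed by deterministic cyclic coordinate descent.
4. **Screen.** Count backbone clashes (3.2 Å CA–CA / 2.6 Å otherwise,
   sequence separation ≥ 3) and require each junction to read as one
   continuous beta strand under a Kabsch–Sander secondary-structure
   assignment (hydrogen bond called at E < −0.5 kcal/mol), with both
   junctions in a single merged sheet.
5. **Redesign shell.** Select all positions within 5 Å of the inter-domain
   junction interface and emit them as a Rosetta resfile (`ALLAA` over a
   `NATRO` default) for the downstream sequence-design step, which is outside
   this package's scope.

Evaluation tools: Kabsch-optimal C-alpha RMSD over a residue correspondence,
TM-score `TM = (1/L) Σ 1/(1 + (dᵢ/d0)²)` with `d0 = 1.24·(L−15)^⅓ − 1.8`
(clamped at 0.5 Å) under both normalizations, a 75 % coverage filter, and a
canonical beta-sheet **topology string** (spatial strand order plus signed
connectivity jumps, invariant to rigid motion, sheet mirroring, and chain
reversal) for comparing folds.

A deterministic fixture generator builds idealized helices, strands,
antiparallel hairpins, sheets, a toy ferredoxin-like fold (strand order
2-3-1-4), and a host/insert pair engineered to contain exactly one insertion
point — so the entire pipeline is testable without downloading a single
structure.

## Worked example

```bash
python examples/02_scan_and_fuse.py
```

prints

```
host: 15 residues, insert: 19 residues
1 candidate(s), 1 passing
best chimera: probe (2,16) -> host (4,9), pair RMSD 0.0001 Å, 0 clashes, junction continuous: True
chimera secondary structure: LEEEEEEEELLLLLEEEEEEEELL
redesign shell (16 positions): [1, 2, 3, 4, 5, 6, 7, 8, 14, 15, 16, 17, 18, 19, 20, 21]
```

Reading: the scan found one geometric match — insert probe residues (2, 16)
onto host pair (4, 9) at 0.0001 Å pair RMSD.  The spliced 24-residue chimera
has no backbone clashes; its secondary-structure string shows two long E runs,
which are the host and insert strands concatenated through the junctions into
the central strand pair of one merged sheet.  The 16-position shell is what a
sequence-design run would be allowed to mutate.

The same run from the shell:

```bash
sheetfuse fixtures --kind hairpin --lengths 8,2,8 -o hairpin.pdb
sheetfuse scan host.pdb insert.pdb            # sites TSV on stdout
sheetfuse fuse host.pdb insert.pdb -d out/    # chimera PDBs + report + resfiles
sheetfuse evaluate ref.pdb model.pdb          # RMSD / TM-score / topology JSON
```

Other examples: `examples/01_generate_fixtures.py` (fixture architectures and
their topology strings), `examples/03_compare_structures.py` (design-vs-noisy-
crystal comparison metrics).

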