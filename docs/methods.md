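# Methods

## Model and scope

`sheetfuse` operates entirely at the backbone level: a structure is an ordered
list of residues carrying N, CA, C and O coordinates (Å).  The package covers
the geometric stages of domain-insertion design — insertion-point search,
backbone splicing, steric and secondary-structure screening, junction-shell
selection — and the standard evaluation metrics (C-alpha RMSD, TM-score, sheet
topology).  Sequence design, rotamer packing, and energy calculations are
deliberately out of scope; the package's terminal product for those stages is
a Rosetta-style resfile naming the junction-shell positions.

## Insertion search

An insert of length n contributes nine probes: the Cartesian product of its
first three and last three residues (3 × 3 terminal residue pairs — the
pairing semantics consistent with a nine-pair count).  Each probe is an
8-atom rigid
body (N/CA/C/O of both residues).  The scan superposes every probe onto every
host pair (i, j), i < j, with j − i − 1 < 5 and no chain break in i..j, using
the SVD form of the Kabsch algorithm with the smallest singular vector's sign
corrected so the rotation is always proper (backbones are chiral; reflections
would produce D-amino-acid geometry).  Acceptance: pair RMSD ≤ 1.0 Å.  Only
the forward orientation (probe N-terminal residue → host i) is scanned;
a reversed mapping would invert chain direction through the junction.

The 8-atom residue-pair RMSD is the least arbitrary reading of a "residue pair
alignment distance"; the atom set is fixed in code rather than configurable to
keep scan results comparable across runs.

## Splice bookkeeping and linker closure

The site's superposition maps the insert into the host frame.  The host
residues at i and j are retained and the insert's probe residues are dropped
(the merge keeps the host's sheet register intact); the chimera is

    host[0..i] + N-linker + insert(n+1..c−1) + C-linker + host[j..]

so its length obeys the closed form
`host_len − removed + (c − n + 1 − 2) + len_N + len_C`, which every splice
asserts.  Linkers (0–3 residues) are built by natural-extension-reference-frame
placement with ideal covalent geometry (N–CA 1.458, CA–C 1.525, C–N 1.329,
C–O 1.231 Å; trans peptides) and closed by deterministic cyclic coordinate
descent: rotating one free torsion moves the terminal carbonyl carbon on a
circle, so the torsion that best restores the terminal C–N distance to
1.329 Å has a closed-form solution; torsions are swept cyclically (cap 200
sweeps, tolerance 0.05 Å on the bond length).  Because the distance landscape
has local minima, the descent is restarted from a fixed ladder of torsion
schedules (extended, helical, turn-like, and alternating patterns); the ladder
makes closure deterministic while escaping stalls.  A gap whose straight-line
length exceeds 3.8 Å × (linker length + 1), or that the descent cannot close
to tolerance, raises an "unclosable junction" error.  Note that closure has an
effective minimum reach as well: grafts whose matched pairs overlap exactly
leave a ~1.3 Å junction gap that only a zero-length linker can bridge — a
squeezed one-residue linker is correctly reported unclosable.

## Secondary structure and topology

Assignment is three-state (H/E/L) from the Kabsch–Sander electrostatic model:
the amide H is placed 1 Å from N opposite the bisector of N→C(prev) and N→CA,
and E = 0.084 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) · 332 kcal/mol, with a
bond called below −0.5 kcal/mol.  Helices need two consecutive i→i+4 bonds;
strands come from the standard parallel/antiparallel bridge patterns (|i−j| ≥
3); sheets are connected components of the residue-level ladder graph.  Runs
are split at chain breaks, and strands shorter than 2 residues are ignored for
topology (single-residue bridges are noise at diagram level).

A junction "reads as a continuous beta strand" when its residues are all E,
sequence-contiguous with no break, and inside one sheet.  A chimera has two
junctions (N-side and C-side); the pipeline requires each separately to pass
and both to lie in the same merged sheet.

The topology string encodes, per sheet, the left-to-right spatial order of
strands (the unique path through the strand-level ladder graph; cycles are
flagged "barrel", branch points "branched" rather than force-ordered) and the
signed positional jumps between sequence-consecutive strands.  The encoding is
canonicalized as the lexicographically smallest of the four variants generated
by mirroring the sheet and reversing the chain, which makes it invariant to
rigid motion, residue renumbering, viewing direction, and chain direction.

## Comparison metrics

C-alpha RMSD is the Kabsch-optimal RMSD over a strictly monotone residue
correspondence (from shared author numbering, or supplied as a two-column
map).  TM-score uses d0 = 1.24·(L−15)^⅓ − 1.8 clamped at 0.5 Å (the formula
is non-positive for L ≤ 17) with L the length of the designated normalization
chain.  The score-maximizing superposition is sought deterministically: seeds
from the Kabsch fit of the full map and of length-8 windows every 4 residues,
each refined by distance-weighted fits (weights 1/(1+(d/d0)²)) to 1e-6
convergence (≤ 50 iterations), best seed kept.  Sequence-independent
alignment (the database-search half of a TM-align sweep) is intentionally not
implemented: the score here evaluates a *given* correspondence.  The coverage
filter reproduces the ≥ 75 % query-coverage criterion used when screening
database hits.

## Synthetic fixtures: what they emulate and what they do not

All fixtures are idealized backbones built from torsions.  Laddered strands
use (φ, ψ) = (−135.0°, 132.27°), solved so the strand is an exact two-residue
screw (rotation < 0.005° per period): every across-ladder residue pair of the
same parity class is then exactly congruent, which is what makes an engineered
insertion site exactly unique.  The antiparallel partner of a strand is its
image under a 180° rotation about the sheet normal plus a translation; rows
further across the sheet alternate between such flips and pure translations
(a bare 2-fold squared is the identity, so the two cases are generated
separately).  The inter-strand spacing is 5.4 Å: real sheets run ≈ 4.85 Å
CA-to-CA, but these strands are untwisted and flat, and 5.4 Å is the spacing
at which their carbonyl O and amide N meet at the canonical ~2.9 Å
hydrogen-bond distance instead of colliding (at 4.85 Å the O···N contact of
2.3 Å would register as a steric clash).

The host/insert test pair contains, by construction, exactly one scan hit at
default thresholds: the insert's probe (2, 16) and the host's turn-flanking
pair (4, 9) are congruent even-parity across-ladder pairs, while the host's
4-residue turn and the insert's four outermost residues use torsion schedules
frozen from a one-off offline search that keeps every other probe/host-pair
combination at least ~1.05 Å RMSD from acceptance.  The insert is moved by a
seed-derived random rigid transform before being returned, so the scan must
recover a non-trivial superposition.  Optional Gaussian jitter (i.i.d. per
atom, seeded) degrades the match smoothly: at σ = 0.3 Å the engineered site
still passes the 1 Å gate; at σ = 3 Å nothing does.

The toy ferredoxin-like fold places four 6-residue strands in spatial order
2-3-1-4 and packs one ideal 8-residue helix 7 Å off each face of the sheet
(opposite faces, so neither helix can ladder with the strands or the other
helix); 4-residue closure loops and a 2-residue turn connect the elements.
The ladder registry is shifted one step forward so the s2→s3 turn exits past
the sheet edge rather than sitting in a vacant rung slot where its own amides
would read as strand.

What passing tests on these fixtures show: the search, splice, screening and
scoring machinery is correct on geometry whose ground truth is known exactly.
What they do not show: robustness to real crystallographic data — sheet
twist, bulges, bifurcated sheets, non-ideal bond geometry, alternate
conformations beyond the altloc rule, or sequence effects.  In particular the
idealized hydrogen-bond geometry tolerates only ~0.25 Å coordinate noise
before marginal ladder rungs drop out of the assignment, which is far more
brittle than DSSP on refined structures.

## Numerical and design choices

- Occupancy-weighted altloc resolution, ties broken alphabetically; incomplete
  residues dropped (or fatal under `strict`); chain breaks flagged at
  C–N ≥ 2.5 Å.  Internal indices are dense and 0-based; author numbering is
  metadata only.
- Collinear point sets in superposition are solved but flagged
  `ill_conditioned` (the rotation about the line is arbitrary; the RMSD is
  not).
- Clash screen: residue pairs with sequence separation ≥ 3 clash when CA–CA
  < 3.2 Å or any other backbone-atom pair < 2.6 Å; counting uses a KD-tree
  and is verified against brute force in tests.
- Pipeline ranking is (clash count, pair RMSD, then index order) — a
  deterministic geometric proxy for the energy- and packing-based selection a
  full design pipeline would apply; it is a proxy, not an energy.
- Pipeline candidates iterate linker lengths over the configured set
  (default 1–3 per the published protocol, with 0 always legal at splice
  level); candidate reports record every rejection reason, and results are
  invariant to the order in which linker lengths are listed.
- The default host chain for PDB input is chain A (exposed as a flag); the
  protocol's source structures are single-chain entries, so nothing deeper is
  warranted.

## Known limitations

- PDB fixed-column format only (no mmCIF), no hydrogens, no assembly
  expansion.
- Bifurcated sheets and barrels are flagged, not ordered; bulge tie-breaking
  in strand order is not attempted.
- The TM-score refinement is a local optimizer over deterministic seeds; for
  adversarial inputs it can undershoot the global optimum (self-comparisons
  and fixture-scale comparisons converge exactly).
- Linker closure optimizes a single distance; it does not optimize the
  junction's incoming bond angles, which is visible as slightly non-ideal
  geometry at the linker exit (within the tested 1.2–1.5 Å bond window).
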