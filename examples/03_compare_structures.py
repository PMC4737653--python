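"""Compare a 'design model' against a noisy 'crystal structure' of itself.

Demonstrates the evaluation metrics: Kabsch-optimal C-alpha RMSD over a
numbering-based residue map, TM-score under both normalizations (with the
superposition optimized by iterative distance-weighted refitting), the 75%
coverage filter, and beta-sheet topology equality.
"""

import numpy as np

from sheetfuse import FixtureSpec, compare_structures, make_fixture

design = make_fixture(FixtureSpec("toy_ferredoxin"))
# a synthetic 'crystal': the same backbone with 0.2 Å coordinate noise (the
# idealized hydrogen-bond geometry tolerates about this much before secondary
# structure assignment starts dropping marginal ladder rungs)
rng = np.random.default_rng(11)
crystal = design.with_coords(
    design.backbone_coords() + rng.normal(scale=0.2, size=(len(design), 4, 3)))

rep = compare_structures(design, crystal)
print(f"aligned residues : {rep.n_aligned} "
      f"(coverage {rep.coverage_a:.2f} / {rep.coverage_b:.2f})")
print(f"C-alpha RMSD     : {rep.ca_rmsd:.3f} Å")
print(f"TM-score (norm A): {rep.tm_score_norm_a:.3f}")
print(f"TM-score (norm B): {rep.tm_score_norm_b:.3f}")
print(f"topology equal   : {rep.topology_equal}")
# With 0.2 Å per-atom noise the optimal-fit C-alpha RMSD lands near 0.35 Å
# and the TM-score stays near 1: the 'crystal' has the same fold, the same
# sheet topology, and near-identical backbone — the agreement profile a
# successful design shows against its experimental structure.
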