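"""Insert one small beta-sheet domain into another and merge their sheets.

Runs the full domain-insertion pipeline on the built-in host/insert test pair:
enumerate the insert's nine terminal residue-pair probes, scan every host
residue pair for a geometric match (<= 1 Å backbone RMSD, replacing fewer
than 5 host residues), splice the chimera, screen for clashes and junction
strand continuity, and emit the redesign shell a sequence-design step would
consume.
"""

from sheetfuse import (
    FusionConfig,
    assign_ss,
    export_resfile,
    make_chimera_test_pair,
    run_fusion_pipeline,
    select_redesign_shell,
    write_pdb,
)

host, insert, expected = make_chimera_test_pair(seed=0)
print(f"host: {len(host)} residues, insert: {len(insert)} residues")

config = FusionConfig(linker_lengths=(0,), max_clashes=0)
passing, report = run_fusion_pipeline(host, insert, config)
print(f"{len(report)} candidate(s), {len(passing)} passing")

model, cand = passing[0]
print(f"best chimera: probe ({cand.probe_n},{cand.probe_c}) -> host "
      f"({cand.host_i},{cand.host_j}), pair RMSD {cand.pair_rmsd:.4f} Å, "
      f"{cand.clashes} clashes, junction continuous: {cand.junction_continuous}")

ss = assign_ss(model.chain)
print("chimera secondary structure:", "".join(ss.states))
# The two long E runs are the merged central strands: host and insert strands
# concatenated through the junctions, exactly the sheet-fusion architecture.

shell = select_redesign_shell(model, config)
print(f"redesign shell ({len(shell)} positions):", sorted(shell))
print(export_resfile(shell, model)[:120] + "...")
print(write_pdb([model])[:200] + "...")
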