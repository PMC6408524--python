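"""Build the GNN module archive and count the design configurations
the expanded dimer grammar makes available at a fixed base step."""

from zfndesign import Arch, build_gnn_archive, configuration_multiplicity

archive = build_gnn_archive()
print(f"GNN archive: {len(archive.with_fingers(1))} one-finger and "
      f"{len(archive.with_fingers(2))} two-finger modules")

baseline = configuration_multiplicity([Arch.CC], 6, skips_enabled=False)
arch_only = configuration_multiplicity(list(Arch), 6, skips_enabled=False)
skips_only = configuration_multiplicity([Arch.CC], 6, skips_enabled=True)
combined = configuration_multiplicity(list(Arch), 6, skips_enabled=True)

print(f"canonical no-skip baseline : {baseline}")
print(f"four architectures         : {arch_only}  (x{arch_only // baseline})")
print(f"skip plans only            : {skips_only}  (x{skips_only // baseline})")
print(f"architectures x skips      : {combined}  (x{combined // baseline})")
print()
print("Each fold-increase multiplies the number of distinct ZFN dimer")
print("configurations able to center cleavage on any chosen base step.")
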