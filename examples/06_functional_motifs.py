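"""Posttranslational-modification signatures: x-P-G sites, G/R repeat
copies, and the PIWI catalytic triad.
"""

from agoblocks import motifs as fm
from agoblocks import simulate as sim
from agoblocks.scanning import Scanner

specs = sim.default_clade_specs(scale=0.15)
models = sim.table_models()
proteins, truth = sim.generate_family(specs, models, seed=6)
scanner = Scanner(list(models.values()), p_threshold=1e-4)

# pick a member of a repeat-carrying clade
prot = next(p for p in proteins if truth.repeat_counts[p.id] >= 2)
arch = scanner.scan(prot)

k = fm.count_gr_repeat_copies(prot, models[43])
print(f"{prot.id}: {k} N-terminal G/R repeat copies "
      f"(planted {truth.repeat_counts[prot.id]})")
print("these repeats mirror the arginine-methylation region of PIWI-clade")
print("proteins; each copy is a candidate protein-interaction signal.")

hits = fm.find_xpg_sites(prot, architecture=arch, within_block=8)
print(f"\nx-P-G sites near block 8: {[h.position for h in hits]}")

report = fm.check_catalytic_residues(prot, arch)
print(f"\ncatalytic triad residues (blocks 5/3/2): {report.residues} "
      f"-> {report.classification}")
print("DDH/DDD marks an endonucleolytically competent PIWI domain.")
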