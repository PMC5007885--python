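"""Scan proteins with the 50 packaged block models -> block architectures.

Every window is scored in bits against each block's matrix; exact lattice
p-values call presence, and greedy non-overlap selection yields each
protein's ordered block string (the linear architecture).
"""

from agoblocks import simulate as sim
from agoblocks.scanning import Scanner

specs = sim.default_clade_specs(scale=0.1)
models = sim.table_models()
proteins, truth = sim.generate_family(specs, models, seed=4)

scanner = Scanner(list(models.values()), p_threshold=1e-4)
arch = scanner.scan(proteins[0])

print(f"{arch.protein_id}: block string {arch.block_string}")
print(f"planted:         {truth.planted_block_string(arch.protein_id)}")
print("\nfirst hits (block, start, bits, p):")
for o in arch.occurrences[:5]:
    print(f"  block {o.block_id:>2} @ {o.start:>4}  {o.score:6.1f} bits  p={o.p_value:.2e}")
print("the block string is the protein's linear architecture; matching the")
print("planted string means scanning recovered every planted occurrence.")
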