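"""The clade consensus calculus: >=90% consensus, specific blocks, group
consensus, and named domain series.
"""

from agoblocks import consensus as cons
from agoblocks import simulate as sim
from agoblocks.scanning import Scanner

specs = sim.default_clade_specs(scale=0.3)
models = sim.table_models()
proteins, truth = sim.generate_family(specs, models, seed=5)
scanner = Scanner(list(models.values()), p_threshold=1e-4)
architectures = [scanner.scan(p) for p in proteins]
groups = {p.id: p.group for p in proteins}

matrix = cons.build_presence_matrix(architectures, groups)
consensuses = []
for clade in matrix.clades:
    cc = cons.clade_consensus(matrix, clade, architectures, threshold=0.90)
    consensuses.append(cc)
    series = [s.name for s in cons.name_domain_series(cc.ordered_blocks)]
    print(f"{clade:<11} ({cc.member_count:>2} members) consensus "
          f"{len(cc.ordered_blocks)} blocks, series {series}")

specific = cons.clade_specific_blocks(matrix)
print("\nclade-specific blocks (>=1 member of exactly one clade):")
for clade, blocks in specific.items():
    print(f"  {clade:<11} {sorted(blocks)}")

group = cons.group_consensus(consensuses, k=2)
print(f"\ngroup consensus (blocks in >=2 of {len(consensuses)} clade consensuses): "
      f"{len(group)} blocks")
print("this is the cross-clade core shared by most of the family.")
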