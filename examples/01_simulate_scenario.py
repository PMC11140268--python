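"""Build a small synthetic scenario and look at what was planted.

The generator creates two diploid genomes (A, D), an F1 hybrid and an
allopolyploid (AD1), with phased nucleosome arrays, accessible chromatin
regions (ACRs), TE annotations and a planted gene-expression design.
"""
from dnscape import ScenarioConfig, build_scenario

cfg = ScenarioConfig(seed=1, n_chroms=1, chrom_length=300_000, n_genes=25,
                     n_acrs=40, n_tes=60, n_ogs=200, with_sequence=False)
scenario, truth = build_scenario(cfg)

for label, genome in scenario.genomes.items():
    print(f"genome {label}: {genome.total_length:,} bp, "
          f"{len(scenario.genes[label])} genes, "
          f"{len(scenario.tes[label])} TEs, "
          f"{len(truth.planted_acrs[label])} planted ACRs")

print("\nplanted nucleosome repeat lengths (bp):")
for key, nrl in truth.planted_nrl.items():
    n_dyads = sum(len(d) for d in truth.planted_dyads[key].values())
    print(f"  {key:7s} {nrl:6.1f}  ({n_dyads} dyads)")

expr = truth.planted_expression
print("\nplanted expression categories over", len(expr), "orthogroups:")
print(expr["inheritance_F1"].value_counts().to_string())
# Each orthogroup also carries true A, B, Bp log2 ratios and a cis/trans
# class; recovery tests compare estimates against these planted values.
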