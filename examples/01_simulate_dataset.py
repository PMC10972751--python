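"""Simulate a small vertebrate-like dataset from the default scenario.

Builds gene families descending from the scripted duplication history
(shared auto-tetraploidization with paralogon divergence at 527 Ma,
gnathostome allo-tetraploidization with progenitor split at 508 Ma,
cyclostome two-step hexaploidization with homoeologue divergences at 511
and 493 Ma), lays the surviving genes out on chromosomes, and prints what
the truth log records.
"""

from wgdkit.pipeline import simulate_dataset

ds = simulate_dataset(families_per_clg=5, sites=100, seed=7, clgs=[0, 1, 2])

print(f"species: {ds.scenario.species()}")
print(f"families simulated: {len(ds.families)}")
print(f"genes placed on chromosomes: {len(ds.gene_map)}")
print("\nfirst gene-map rows:")
print(ds.gene_map.head(8).to_string(index=False))

hag = ds.gene_map[ds.gene_map.species == "hagfish_like"]
fused = {
    chrom: sorted({(c, l) for c, l in zip(sub.clg, sub.label)})
    for chrom, sub in hag.groupby("chromosome")
}
print("\nhagfish-like chromosomes are fusions of post-WGD units:")
for chrom, units in sorted(fused.items()):
    print(f"  {chrom}: {units}")

# Each (CLG, label) unit is one post-duplication chromosome segment; the
# gene map plus the derived reference table are the inputs every later
# stage consumes.
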