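"""Nuclear F_ST tree vs mitogenome lineage tree (discordance demo).

Builds (1) a neighbor-joining tree of populations from pairwise
genome-wide Hudson F_ST and (2) a NJ tree of samples from Jukes-Cantor
distances over concatenated mitochondrial protein-coding genes.  The
simulation places both mito lineages inside every nuclear population,
so the two trees partition the samples differently -- the classic
signature of founding populations polymorphic for old mito lineages.
"""
import tempfile
from pathlib import Path

from aedespop import (
    DistanceMatrix, SimConfig, assign_lineages, consensus_from_vcf,
    extract_and_concatenate, fst_to_distance, nj, pairwise_fst_matrix,
    read_gene_table, simulate, write_dataset, write_newick,
)

cfg = SimConfig(
    n_populations=3, target_F=0.15, samples_per_population=[8, 8, 8],
    n_sites=8_000, n_hybrids=[], seed=4,
)
bundle = simulate(cfg)
paths = write_dataset(bundle, tempfile.mkdtemp(prefix="aedespop_"))

pops = {}
for s, p in bundle.truth.population_of.items():
    pops.setdefault(p, []).append(s)
fst = pairwise_fst_matrix(bundle.gm, pops)
print("pairwise genome-wide F_ST:")
print(fst.round(4).to_string())
nuclear_tree = nj(DistanceMatrix.from_frame(fst_to_distance(fst)))
print("\nnuclear NJ tree:", write_newick(nuclear_tree))

cons = consensus_from_vcf(paths["mito_vcf"], paths["mito_ref"])
genes = read_gene_table(paths["genes"])
concat = extract_and_concatenate(cons, genes)
lineages, mito_tree = assign_lineages(concat, n_lineages=2)
print(f"\nconcatenated {len(genes)} protein-coding genes, "
      f"{concat.length} bp per sample")

truth = bundle.truth.mito_lineage
match = all(
    (lineages[a] == lineages[b]) == (truth[a] == truth[b])
    for a in truth for b in truth
)
print(f"mito lineage sizes: "
      f"{ {l: list(lineages.values()).count(l) for l in set(lineages.values())} }")
print(f"lineage partition matches simulated truth: {match}")
# Every nuclear population contains samples of both mito lineages, so
# the mito tree's deepest split crosses the nuclear clusters.
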