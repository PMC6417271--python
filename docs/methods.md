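# Methods

This note documents the statistical models, numerical conventions and
design choices behind `aedespop`, and what the simulation-based tests
do and do not demonstrate about real data.

## Hudson F_ST

The divergence estimator is Hudson's two-population F_ST in the
numerator/denominator parameterization

    N_s = (p₁ − p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)
    D_s = p₁(1−p₂) + p₂(1−p₁)

with p the sample alternate-allele frequency and n the number of
called alleles in each group at site s. Sites with fewer than two
called alleles in either group are excluded. Aggregation over any site
set is the **ratio of averages** ΣN/ΣD, not the average of per-site
ratios: per-site ratios are strongly biased at small n and undefined at
monomorphic sites, while the ratio of averages is consistent and lets
window, chromosome and genome estimates share one code path. Per-site
N ≤ D always, so no aggregate estimate can exceed 1; mildly negative
estimates are legitimate sampling outcomes and are reported as
computed in all tables, clamped to 0 only when a matrix is converted
to tree distances.

Two self-comparison facts worth knowing: two *disjoint* samples of one
panmictic population give estimates scattered around 0, while comparing
a group with *literally itself* gives expectation −1/(n_alleles − 1),
because p₁ ≡ p₂ leaves only the within-group correction terms. The
test suite pins both behaviours.

The genome-wide standard error is a delete-one-block jackknife over
non-overlapping 1 Mbp blocks (default; configurable): the estimate is
recomputed leaving each block out, and SE² = (g−1)/g · Σ(θ₋ⱼ − θ̄)².
Blocks of this size absorb local correlation of sites; with a single
occupied block the SE is reported as NaN with a warning.

## Nucleotide diversity and Δπ

Per site, π is the unbiased heterozygosity n/(n−1)·2p(1−p), which
equals the mean pairwise difference over all C(n,2) called-allele
pairs (the tests verify this identity exactly against brute-force
enumeration). Window π sums per-site values and divides by the window
span in **base pairs**, the windowed-scan convention in which
monomorphic and unobserved positions contribute zero; note this makes
window π sensitive to SNP density, which is the intended behaviour for
spotting diversity-depleted regions such as centromeres. Δπ is the
aligned elementwise difference π₁ − π₂; swapping groups flips its sign
exactly.

## Window grids

Windows are enumerated from coordinate 0 at step intervals (default
1 Mbp windows, 500 kbp steps): full windows are laid down while they
fit, and one trailing partial window is appended only when the last
full window does not already reach the chromosome end (a chromosome
shorter than one window yields a single window spanning it). A 3 Mbp
chromosome therefore yields exactly five windows. Windows with fewer
than `min_snps` (default 10) usable sites report NaN rather than a
noisy estimate. Coordinates are 0-based half-open; VCF positions are
1-based internally and converted at the boundary, as with BED masks
(a VCF record at position P is masked when P−1 ∈ [start, end)).

## Site filters

The chain order is fixed: biallelic-SNP → depth mask → strand support
→ region mask → missingness. Depth masking precedes the missingness
filter deliberately, so genotypes below the per-sample depth floor
(default 8×) count toward site-level missingness. The missingness rule
is strict: a site is removed when its missing fraction *exceeds* the
threshold (default 0.20), so a site at exactly 20% is retained. The
strand filter requires ≥1 forward and ≥1 reverse alternate-supporting
read from site-level annotations (SAF/SAR) and is skipped with a
warning when the VCF carries none, since callers often enforce it
upstream. Masking is BED-driven; the package does not infer repeat
intervals from soft-masked reference case, which keeps the stage
reference-free. With depths near 10× and overdispersion, a strict 8×
floor marks a third of genotypes missing and the 20% rule then removes
most sites — the accounting report makes this visible, and the floor
can be disabled explicitly (`min_depth=None`) when depths are known to
be honest.

## PCA, clusters and hybrid flagging

Dosages are mean-imputed per site, centered, and scaled by
1/√(p̂(1−p̂)) (drift-variance scaling; monomorphic and fully-missing
sites are dropped). Components come from the SVD of the prepared
matrix; variance fractions from squared singular values; each
component's sign is fixed by making its largest-magnitude site loading
positive, so results are reproducible and invariant to sample order.

Cluster assignment formalizes the visual cluster-calling step:
k-means (25 restarts, seeded) over the leading components, with k
supplied by the user. The number of components used defaults to the
smallest leading set covering 80% of the **between-cluster** sum of
squares, measured by a pilot k-means pass over all returned
components; trailing components that carry only within-cluster noise
would otherwise dilute the cluster geometry. Labels are GC1..GCk in
descending size order for determinism.

A putative F1 hybrid lies near the midpoint of its parent clusters'
centroids and far from both. The admixture score against a cluster
pair (i, j) is 1 − 2|t − d/2|/d (t = projection on the i→j axis,
d = inter-centroid distance), clipped to [0, 1]: 0 at either centroid,
1 at the midpoint. A sample is flagged when (a) the score against its
**two nearest centroids** reaches the threshold (default 0.5) and
(b) its distance to the nearest centroid exceeds the 95th percentile
of within-cluster distances. The candidate pair is restricted to the
two nearest centroids because any member of a third cluster projects
near the midpoint of the axis joining two other clusters and would
otherwise be flagged spuriously; scores against all pairs remain
available via `admixture_scores`. This is a geometric screen matching
the qualitative reasoning used when eyeballing PCA plots — it is not
model-based ancestry inference and will not resolve backcrosses.

## Trees

Neighbor joining is the standard Saitou–Nei agglomeration on the Q
criterion, with ties broken toward the lowest index pair and negative
branch lengths clamped to zero with the deficit moved to the sibling
branch (path lengths through the join are preserved). On additive
matrices the algorithm provably recovers the generating topology and
branch lengths; the suite checks exact recovery on 50 random trees of
up to 12 leaves and cross-checks topology against an independent NJ
implementation. F_ST matrices are not additive and may contain
negatives (clamped to 0 on entry); trees built from them are
summaries of between-population relationships, not phylogenies.
Sequence distances are Jukes–Cantor, d = −(3/4)·ln(1 − (4/3)p̂), with
gap/ambiguity positions excluded pairwise and an error raised at
saturation (p̂ ≥ 0.75). Newick output uses 17-significant-digit branch
lengths so parse(write(t)) round-trips exactly.

## Mitogenome handling

Consensus sequences apply haploid substitution calls to the reference;
indel records are skipped (counted, warned) so all consensuses keep the
reference length and stay aligned without a multiple-alignment step.
Missing calls are reference-filled and recorded per sample — the
standard consensus-extraction convention; the alternative (gap
characters) would change distances. Protein-coding genes are cut out
by 1-based inclusive coordinates from a per-reference annotation
table (coordinates are reference-specific and must match the supplied
FASTA), reverse-complemented on the minus strand, concatenated in
annotation order, and fed to JC69 + NJ. Lineages are defined by
cutting the n−1 longest internal branches of that tree and labelled
L1, L2, ... largest first. The mitochondrial VCF is assumed to derive
from numt-aware mapping (reads mapped to the mito reference before the
nuclear genome); that read-level step is upstream of this package.

## The synthetic-data generator

Nuclear genotypes follow the Balding–Nichols model: ancestral
frequency p̄ ~ Uniform(0.05, 0.95) per site (configurable), population
k's frequency ~ Beta(p̄(1−F_k)/F_k, (1−p̄)(1−F_k)/F_k), diploid
dosages Binomial(2, p). The model is chosen because expected
divergence is analytic — Hudson F_ST between populations with
parameters F_a, F_b converges to (F_a+F_b)/2 — giving exact truth for
parameter recovery. Defaults mirror a small invasion panel: four
populations of 18/9/7/3 diploids, F = 0.15 (the scale of the most
diverged cluster pair in such studies), three chromosomes of 3/5/4 Mbp
with one central masked interval each in which SNP density drops
tenfold (a centromere stand-in), per-genotype negative-binomial depths
(mean 10, size 5 — low-coverage resequencing), 5% missingness, one F1
hybrid option, and a mitogenome with 13 genes and two lineages, 30
defining substitutions apart, alternating within each nuclear
population so the mito partition crosses the nuclear one. Lineage 1 is
the reference haplotype; further lineages carry disjoint substitution
sets, all placed inside gene intervals so the concatenated alignment
preserves every difference. Private mutations are Poisson (mean 2) at
globally unique positions.

Sites are **independent** — no linkage disequilibrium, recombination
maps, selection (outside the temporal scenario below) or demographic
history. Passing tests therefore demonstrate estimator and pipeline
correctness under known truth, not robustness to LD, batch effects,
reference bias or call-set artifacts of real resequencing data.

### Temporal founder-effect scenario

The two-timepoint generator models a population sampled before and
after re-establishment from 6 founder individuals. Independent-site
resampling alone cannot reproduce the empirical signature of such
comparisons (near-zero genome-wide F_ST with isolated windows above
0.1): with thousands of independent SNPs per window, every window
estimate collapses onto the genome mean. Two mechanisms restore the
local structure, both biologically motivated: (1) post-bottleneck
gametes are recombinant mosaics of the 12 founder haplotypes (mean
segment 5 Mbp), so founder drift is locally correlated along
chromosomes; (2) three 400 kbp regions are shifted half-way toward
fixation in the founded population, emulating local adaptation during
establishment — which is also the standard interpretation of such
windows in field data. With the default 3-vs-4 sample design this
yields genome-wide F_ST of ~0.05–0.09 (small against the ~0.15
between-population scale), a handful of windows above 0.1, and a mean
diversity loss in the later sample.

## Problem sizes and determinism

All simulations are seeded (`numpy` SeedSequence spawning per stage);
identical configuration + seed reproduces byte-identical output files.
Test and acceptance runs use desk-scale sizes chosen to make the
statistical assertions sharp while keeping the full suite fast:
50k sites × 20 diploids/population for parameter recovery (10 seeds
per F), 10k sites × 61 samples for cluster/hybrid recovery (10 seeds),
8k sites × 24 samples for the discordance demonstration, 1000-site
fixtures for exact oracle equivalence. At these sizes the
Balding–Nichols recovery tolerance of ±0.01 sits several Monte-Carlo
standard errors from the truth.

## Known limitations

- No LD-aware statistics; the jackknife SE assumes block-scale
  independence.
- Hybrid detection is F1-oriented; backcrosses and admixture fractions
  need model-based tools.
- The mito pipeline rejects indels and assumes one reference; consensus
  coordinates are not lifted between references.
- The F_ST NJ tree inherits all caveats of non-additive, noisy distance
  matrices; no bootstrap support is computed.
- k (number of clusters) is user-supplied; the package does not select
  it.
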