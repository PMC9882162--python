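# Methods

This note documents the models, estimators and design choices behind
`nlr-divers`, in the order the pipeline applies them.

## Entropy-based hv classification

Per alignment column, Shannon entropy is computed over amino-acid
frequencies only: gap characters (`-`, `.`), the unknown residue `X`, and
`*` are excluded from the tally, so an all-gap column has no entropy value
and can never contribute to classification. The rationale is that the
classification scores *amino-acid positions*; treating gaps as a 21st
character would conflate indel polymorphism with substitution diversity.

Columns whose occupancy (non-gap share) falls below `min_occupancy`
(default 0.5) are excluded from hv counting — sparse insertion columns
carried by a few sequences would otherwise inflate the high-entropy count.
The threshold is a parameter, not a constant, because gap handling for
entropy profiles is a genuine free choice; the default keeps any column
present in at least half the population.

A gene is hv when at least `min_positions` (default 10) counted columns
have entropy strictly greater than `threshold_bits` (default 1.5). The
inequality is strict, matching the rule's phrasing; classification is
monotone in the number of high-entropy columns by construction.

## Alignment-based population genetics

**Missing-data policy: complete deletion.** Any column containing a gap or
IUPAC-ambiguous base in any sequence is removed before computing S, π, θ_W
and D. This keeps every pairwise comparison on one shared site set and
makes S, the total pairwise difference Π and the Tajima constants
internally consistent. Per-gene values can shift slightly under other
policies (e.g. pairwise deletion); that sensitivity is inherent, and the
genotype-matrix path (below) provides the pairwise-complete alternative.

**Tajima's D** is computed on the total scale,
D = (Π − S/a₁)/√(e₁S + e₂S(S−1)), with the constants a₁, a₂, b₁, b₂, c₁,
c₂, e₁, e₂ retained on the result object for audit. D is reported as
missing with a reason code (never as 0) when S = 0, when n < 3, and in the
degenerate n = 3, S = 1 case where e₁ = 0 makes the variance estimate zero.

**Nei–Gojobori πN/πS.** Site counts per codon position are the fraction of
single-base changes that are synonymous among changes not creating a stop
codon (stop-excluded denominator); differences between codon pairs are
averaged over all minimal mutational pathways that avoid stop codons
(when every pathway crosses a stop — a case that does not occur between
sense codons under the standard code, verified exhaustively in the tests —
the unrestricted average is used and flagged). Codons containing gaps,
ambiguity or stops in either sequence of a pair are skipped pair-wise. πS
is the mean over sequence pairs of syn-differences/syn-sites (πN
analogous); the ratio is reported as missing when πS = 0. Raw proportions
are used by default — no Jukes–Cantor correction — because within-species
divergence is far from saturation; the correction is available via
`jc_correction=True`.

A property worth knowing: pathway averaging can attribute fractional
nonsynonymous differences to purely synonymous divergence. Two synonymous
substitutions can leave a codon pair (e.g. CTT vs TTA, both leucine) whose
minimal pathways include amino-acid-changing intermediates. Leucine and
arginine are the only residues whose synonymous codon networks span more
than one codon position, so πN is exactly zero under synonymous-only
evolution precisely when those residues are absent; the simulator exposes
`exclude_amino_acids="LR"` to construct that clean case.

**Domains and windows.** Domain statistics use majority-vote column
assignment: each sequence's 1-based residue ranges are mapped through its
alignment gaps, and a codon column takes the label claimed by a strict
majority (> 50%) of sequences with a residue there; ties and unannotated
columns stay unassigned, so the labels partition the columns. Sliding
windows are 300 bp with a 75 bp step in 1-based alignment coordinates;
trailing incomplete windows are dropped so every window is directly
comparable, and each window is reported at its nucleotide midpoint.

**Genotype matrices.** For VCF-derived haplotype matrices, per-site π uses
pairwise-complete allele counts, π_site = Σ_{a<b} 2nₐn_b/(m(m−1)) over m
called haplotypes; sites with fewer than two calls are dropped; S and D use
the median called sample size. This path exists because per-site sample
sizes vary in population VCFs, unlike curated alignments.

## Genomic features

**CG methylation.** Cytosines with coverage below 5 reads are discarded.
Symmetric CG dyads (+ strand at p, − strand at p+1) are averaged when both
pass coverage, otherwise the surviving strand stands alone; sites are
anchored at the + strand position, and orphan minus-strand cytosines are
used alone with a logged warning. Gene-body methylation is the unweighted
mean of per-site percentages over the full annotated gene span (UTRs and
introns included), per replicate, then the unweighted mean across
replicates with at least one covered site; genes with no covered site in
any replicate are reported missing with a `no-covered-cytosines` flag. The
unweighted (not coverage-weighted) site mean is a deliberate choice: each
site is one epigenetic position regardless of read depth.

**Expression.** Counts convert to TPM with effective length = the exon
union from the gene annotation (counts come from exonic reads; the full
span is available as an option). Replicates are averaged on the TPM scale
first, then log2(TPM+1) for display and testing. Genes on an unmappability
exclusion list stay in the table with the `unmappable` flag and missing
expression.

**TE distance.** Distance from a gene span to its nearest TE on the same
chromosome, 0 on any overlap (a TE inside an intron or UTR is distance 0);
otherwise the gap max(start_g, start_t) − min(end_g, end_t) − 1 under
1-based inclusive coordinates, so directly adjacent features are at
distance 0. Strand is ignored.

All coordinates are 1-based inclusive internally (the GFF3/TAIR
convention); BED export/import converts to 0-based half-open and back
losslessly.

## Inference layer

Permutation p-values default to the plain b/n denominator, so an observed
statistic more extreme than every replicate reports p = 0; the
(b+1)/(n+1) variant — which cannot report 0 and is the better choice when
p-values feed thresholds — is available via `add_one=True` and recommended.
Whenever the full label-assignment set has at most 10,000 elements,
`perm_diff_test` enumerates it exactly.

The matched test draws, per replicate, one non-target gene per target gene
from the same covariate stratum (deciles of the pool covariate; strata are
widened to the nearest non-empty neighbours when too small), without
replacement within a replicate, so every null set reproduces the targets'
covariate distribution. Two caveats are documented properties rather than
bugs: (i) the null draws come from the disjoint non-target pool, whose mean
fluctuates around the population mean with variance ~σ²/N_pool that the
null does not see, making the test mildly anti-conservative (measured
type-I ≈ 0.06 at α = 0.05 with study-sized pools — inside the calibration
band the test suite enforces); (ii) decile matching cannot correct targets
lying beyond the pool's covariate support.

The empirical-tail test's null — the tail count of a uniform random
same-size gene set drawn without replacement — is sampled from its exact
distribution (hypergeometric) rather than by materialising each set; the
two are identical by construction. Tail membership is inclusive at the
percentile cutoff. Balancing-selection candidates are genes at or above
the 95th percentile of both the π and D empirical distributions.

The rank-based gene-set score is (mean midrank − minimum attainable) /
(maximum − minimum attainable) ∈ [0, 1] with a random-set resampling
p-value. It is a simplified rank-enrichment score, flagged as such in its
output; it does not implement the bidirectional normalisation of published
single-sample scoring methods.

Multiple testing uses Benjamini–Hochberg within each family of tests (the
permutation battery and the rank-sum battery are separate families in the
pipeline); the correction method is a documented default, exposed through
`bh_adjust`.

## Synthetic data

`simulate_coalescent` produces neutral population samples via the standard
no-recombination coalescent (msprime backend; haploid samples, constant
population) with infinite-sites mutations at rate θ/2 per lineage per
coalescent time unit, mapped to distinct integer positions on [1, L]
(collisions resampled; negligible at the parameter ranges used). With
θ = 5, n = 10, the estimators recover E[π·L] = θ, E[S] = θ·a₁ and a mean
Tajima's D near zero; the folded site-frequency spectrum matches
E[η_i] = θ(1/i + 1/(n−i)).

`simulate_codon_population` uses a star genealogy — independent lineages
from one stop-free ancestor — with single-base proposals: stop-creating
proposals are rejected, synonymous proposals always retained,
nonsynonymous ones retained with probability `omega_accept`. The star
shape keeps the synonymous/nonsynonymous bookkeeping exact (every retained
event is logged and the log replays to the output alignment); the cost is
that lineages share no genealogical structure, which is fine for πN/πS
ground truth but makes the alignment unsuitable as a coalescent test case.
With `omega_accept=1`, measured πN/πS centres on 1 because Nei–Gojobori
site counts normalise by exactly the mutational opportunity the proposal
process uses.

`simulate_feature_table` emulates the per-gene analysis table: an hv group
of 15 and a non-hv group of 150 genes inside a 2,000-gene universe
(mirroring the scale of an NLR complement within a genome-wide pool),
expression normal on the log2(TPM+1) scale (mean 3, SD 2), methylation
beta-distributed on [0, 100] (mean ≈ 30%), TE distance exponential (mean
3 kbp) with a point mass at 0, and a unitless mutation-probability score
N(1, 0.2). Group effects are injected for the hv group in background-SD
units; the defaults (+1 SD expression, −1 SD methylation, −1.5 SD TE
distance applied as a clipped subtraction so most hv genes sit at distance
0, +1 SD mutation score) reproduce the qualitative and, for TE distance,
the quantitative contrast observed in real hv/non-hv comparisons (hv
median 0 kbp vs ~2 kbp). The CG-site covariate is Poisson with rate
increasing in methylation, deliberately confounding gene-set methylation
comparisons so the matched test has real work to do. Missingness is
injected per feature at `missing_rate` (default 2%).

What the generator does *not* emulate: linkage between genes, cluster
structure on the chromosome, phylogenetic correlation among paralogs,
realistic count overdispersion, or bisulfite conversion artefacts. Passing
tests therefore demonstrate correctness of the estimators and calibration
of the tests under clean conditions, not robustness to every property of
real data.

## Problem sizes in the test suite

The acceptance-style checks run at desk scale, chosen to keep the full
suite fast while leaving the statistical assertions well-powered: 200
random alignments for exact-estimator checks, 2,000 coalescent replicates
for parameter recovery, 200 codon-population replicates for πN/πS
neutrality, 1,000 null datasets per calibration check, and 100 seeded
end-to-end synthetic runs (with 1,000 permutation replicates each) for
effect-direction recovery. The acceptance script uses the same designs at
1,000/200/600/50 replicates respectively.

## Known limitations

- The coalescent simulator has no recombination, demography or selection;
  the codon simulator's star genealogy understates shared ancestry.
- Decile-based matching is coarse for very skewed covariates; the stratum
  count is a parameter.
- The GT-only VCF reader handles minimal population VCFs; it is not a
  general VCF toolchain (no filters, no multi-sample ploidy mixtures).
- Maximum-likelihood site-selection models, phylogeny inference and read
  processing are out of scope; their outputs are consumed as inputs where
  relevant.
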