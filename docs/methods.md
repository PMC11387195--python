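# Methods

This note documents the statistical conventions, default parameters and
design choices behind each module, and what the synthetic-data generators do
and do not emulate.

## Site classification and the bootstrap contrast

A site is classified for a pair of disjoint groups using non-missing
genotypes only. A group is *fixed* when all its calls are the same
homozygote; it is *segregating* when both alleles are observed — a single
heterozygote suffices, since a heterozygote carries both alleles. The
classes are: **P_B** (both groups fixed, for different alleles), **P_A**
(both groups segregating), **UNCLASSIFIABLE** (fewer than
`min_called_per_group` calls in either group; default 4 of 5), and
**NEITHER** (everything else, which includes monomorphic sites and
one-fixed/one-segregating sites; the latter are deliberately tallied
nowhere else and can be counted from the returned class vector).

Per-site FST is Hudson's two-population estimator
F = 1 − H_w/H_b with H_w = (2p₁q₁ + 2p₂q₂)/2 and
H_b = p₁q₂ + p₂q₁ from allele frequencies on non-missing calls, without
finite-sample correction: this form attains exactly 1 at a fixed difference
and exactly 0 at equal frequencies, which is what the P_B criterion needs.
On complete data, P_B ⇔ F = 1 (verified exhaustively for small groups).
The P_B rule is nevertheless implemented directly on genotypes; FST is a
cross-check, not the classifier.

The bootstrap is *group* resampling, not site resampling: each of the 100
replicates draws two disjoint groups of 5 uniformly without replacement —
one from each population, or both from one population for the
within-population control — and re-classifies every site. Replicates are
independent; the whole procedure is deterministic given the seed.
Subgenome tallies assign chromosomes 1–10 to subgenome A and 11–20 to B,
parsed from the trailing integer of the chromosome name. Window densities
use 1-Mb tiling windows, 0-based half-open internally and reported 1-based
inclusive (position 1,000,000 belongs to the first window).

## QC filter cascade and clumping

Filtering mirrors the standard post-calling cascade: genotypes whose carried
allele has < 5 supporting reads become missing (when allele depths are
present), then sites are removed at missing rate strictly > 0.05, MAF
< 0.01 (computed on non-missing allele counts), or > 10 heterozygous
genotypes. A site failing several rules is attributed to the first rule in
that order; filtering is idempotent and never alters retained genotype
values. Clumping with all p-values equal degenerates to order-dependent
pruning, so it is implemented as a deterministic greedy sweep in genomic
order: a site is kept iff its r² with every kept site within 250 kb (the
conventional clump radius) is below 0.5. Multiallelic VCF records are
dropped, not split, because the data model is strictly biallelic.

## LD decay

r² is the squared Pearson correlation of ALT-dosage vectors over
pairwise-complete samples (composite LD). In near-fully homozygous panels
this coincides with the haplotype-based estimator; on strongly heterozygous
data the two can diverge, which is the main caveat when comparing against
haplotype-based tools. Pairs with fewer than 4 complete observations or a
monomorphic member are skipped; a `min_maf` floor is exposed because
reference tools may apply one silently. Bins are left-open/right-closed
((0,100], (100,200], … by default) to 300 kb.

The half-maximum distance takes the *maximum binned mean* as the reference
level (not the first bin, which may be empty or noisy) and reports the
upper edge of the first non-empty bin whose mean is ≤ half that level;
a curve that never crosses reports NOT_REACHED rather than a number.
Sample-size standardization subsamples `n_target` individuals without
replacement, recomputes the half-max per replicate (default 100), excludes
NOT_REACHED replicates with a warning, and summarizes with the inverse
empirical CDF median (type-1 quantile, p = 0.5), whose result is always an
actually observed replicate value.

## Windowed diversity

Per site with non-missing allele counts (c_r, c_a), n = c_r + c_a ≥ 2, the
unbiased heterozygosity is 2·c_r·c_a/(n(n−1)). Window π divides the summed
site values by the *full* window length (200 kb default, 100 kb step), so
uncalled and monomorphic positions count as invariant — the convention of
the standard windowed-π tools. Final windows may extend past the chromosome
end; their denominator is unchanged.

## Chloroplast alignment variants and NJ

On an existing whole-genome alignment (SSC orientation normalized upstream),
a SNP is a column with ≥ 2 distinct non-gap, non-N bases; N never creates
an event. An InDel is a maximal run of columns whose gap/non-gap pattern
varies across the sequences, counted as **one** event per run regardless of
how many sequences share the gap — per-column counting and a
drop-N-columns policy are provided as switches because the counting
convention of alignment-viewer-based tallies is ambiguous. Columns inside
an InDel run can still yield SNPs on their non-gap states.

Distances are p-distances over pairwise non-gap, non-N columns. The NJ
implementation is standard Saitou–Nei with Q-matrix minimization and a
deterministic lowest-(i,j) tie-break; negative branch-length estimates are
clamped to 0 and counted. Support values come from column bootstrap
(resample columns with replacement, rebuild, count bipartitions; 1,000
replicates by default).

## MNR profiling and clustering

Only *maximal* homopolymer runs count; runs of length 3–20 increment their
(base, length) feature — 72 features, A3…T20 — runs > 20 are excluded by
default (a cap-at-20 switch exists), and N breaks runs. "Percentage
abundance relative to sequence length" is ambiguous between occurrences and
covered bases; the default is base coverage (count × length / sequence
length × 100) with the count convention as a switch. Features absent
everywhere or exactly constant across samples are dropped (exact equality
is safe because abundances derive from integer counts).

Clustering follows the two-stage recipe: Euclidean distance on abundance
rows, then a secondary dissimilarity d*(i,j) = 1 − Pearson correlation
between rows i and j of the distance matrix (self-entries of the pair
excluded), then average-linkage agglomeration (delegated to
`scipy.cluster.hierarchy.linkage`). Bootstrap support is the ordinary
feature-bootstrap proportion of replicates reproducing each cluster as a
leaf set; multiscale/AU-corrected p-values are out of scope.

## Synthetic-data generators

**Tetraploid panel.** Sites draw independent categories: fixed difference
with probability `theta_B`, shared polymorphism with `theta_A`, the
remainder split evenly between lineage-private polymorphisms (a private
draw that would fix the ALT allele is redrawn, so residual monomorphic
sites are REF-fixed and never mimic fixed differences). Because peanut is
self-pollinating, the baseline is fully homozygous: at a segregating site
with frequency p an individual is ALT-homozygous with probability p;
heterozygosity (`het_rate`) and missingness (`missing_rate`) are injected
afterwards as per-genotype noise. Segregating frequencies are drawn from
Beta(0.5, 5), emulating the rare-variant-skewed ALT frequency spectrum of
resequencing panels; shared sites are rejected-resampled until both alleles
are realized in both lineages, making the truth labels crisp. The
distinct-founder scenario uses theta_B = 0.2, theta_A = 0.02; the
common-founder scenario theta_B = 0.001 (rare post-split drift fixation),
theta_A = 0.2 — with 5,000 sites and 30 + 30 individuals these are the
standard study conditions used throughout the tests. The generator does
*not* emulate linked selection, population structure within lineages, or
genotyping error beyond the uniform noise rates, so passing recovery tests
demonstrate the statistic's behavior under its own assumptions, not
robustness to every real-data pathology.

**Chloroplast set.** A root sequence is drawn at 36% GC (chloroplasts are
AT-rich) with seeded homopolymer tracts (lengths uniform over 3–20 by
default), then evolved along a user-supplied rooted Newick tree:
substitutions Poisson(branch length × genome length), indels at
`indel_rate` times the substitution count with lengths uniform in 1–6.
Deletions never erase a seeded tract and insertions never land inside one
(they are resampled), and substitutions avoid tract interiors, so seeded
tracts remain recoverable in every descendant — a deliberate idealization
that keeps MNR-recovery ground truth well defined; real homopolymers mutate
primarily by slippage, which is not modeled. Every event is logged.

**Wright–Fisher.** A forward diploid model with per-offspring selfing
probability, Poisson crossovers at per-bp rate, and infinite-sites-style
mutation on a discrete coordinate grid. Defaults (N = 100, 100 kb,
selfing 0.99) reflect a highly selfing crop. The LD property tests and the
acceptance script run pooled batches of six replicate populations at
N = 60, 30 kb regions, 150 generations — sizes chosen so the binned curves
are dense enough for a stable half-max read-out — and verify that more
recombination shortens, and more selfing lengthens, the half-maximum
distance.

## Numerical conventions and degenerate inputs

All RNG flows through `numpy.random.default_rng` with mandatory config
seeds; identical config + seed reproduces outputs byte-for-byte (VCF bodies
included). Dosage is int8 with −1 for missing. Empty matrices round-trip as
header-only VCFs. Curves with only empty bins, alignments with no
comparable columns for a pair, constant distance profiles in clustering,
and undefined FST (zero between-heterozygosity) all raise or return NaN
explicitly rather than silently producing numbers.

## Known limitations

- Composite (dosage) r² rather than haplotype EM; differences appear on
  heterozygous data.
- The NJ and clustering bootstraps are plain proportions, not
  bias-corrected.
- The chloroplast simulator's indel/tract protections make MNR recovery
  easier than in real genomes with slippage mutation.
- Accession-derived quantities (real chloroplast polymorphism totals, real
  LD half-max distances) depend on counting-convention switches documented
  above and require the original data deposits; the package validates the
  machinery on synthetic ground truth.
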