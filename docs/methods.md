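# Methods

haplomosaic reimplements, as a standalone library, the comparative
analyses that mosaic-style multi-genome browsers perform on large panels
of collinear genomes: recombination-free interval discovery, haplotype
identity, identity-by-descent, ancestry and heterozygosity segmentation,
local phylogenies, and the scale-adaptive visual conventions used to
display them. This note records the models, the parameters that matter,
the numerical conventions, and the choices made where the design was
genuinely open.

## Data model

A panel is a `GenotypeMatrix`: strains × biallelic markers, one or more
chromosomes, codes 0 (major allele), 1 (minor), 2 (heterozygous), −1
(missing). The major allele of a column is the most frequent nucleotide
among homozygous calls, ties broken toward the lexicographically smaller
nucleotide; this binarization is deterministic, and every downstream
statistic depends only on allele *sharing*, so complementing columns
changes nothing. Marker indices are 0-based per chromosome; genomic
positions are 1-based inclusive; BED output converts to the standard
0-based half-open form (start − 1, end unchanged). Analyses operate on
one chromosome at a time; multi-chromosome inputs are split and processed
independently.

Heterozygous and missing calls are treated as *uninformative* throughout:
a strain is dropped from a marker pair in gamete counting, a marker is
dropped from a strain pair in mismatch counting, and an HMM emission is 1.
This is the conservative reading for panels of largely inbred strains,
where residual heterozygosity is rare and often reflects intensity
artifacts; the alternative (het as evidence of difference) would shorten
compatible intervals and fragment haplotype groups for wild samples.

## Compatible intervals

Two markers are compatible when at most three of the four gametes
00/01/10/11 occur among doubly-informative strains (four-gamete test);
pairs with fewer than two informative strains, and monomorphic columns,
are compatible by convention. An interval is compatible when *all* its
marker pairs are — a hereditary property, so the maximal right extent
r(i) of a compatible run starting at marker i is non-decreasing and a
two-pointer sweep computes it in O(m·w²) pair tests for window width w.
Pair tests use per-column bitmask pairs (allele-0 and allele-1 carrier
sets as integers), making one test four integer ANDs.

The chromosome is covered by maximal intervals chosen greedily: start
with the interval covering marker 0 that reaches furthest right, then
repeatedly take the maximal interval covering the first uncovered marker
with the largest right end. Because any maximal interval covering that
marker ends no later than the previous pick's end, each new interval
starts strictly after the one before the previous — hence no marker is
ever covered by more than two intervals, which is what lets the covering
render on two alternating parity rows. The covering is verified against a
brute-force oracle (enumerate all O(m²) intervals, filter maximal,
greedily cover) on hundreds of random small matrices.

## Haplotype groups and IBD

Within an interval, strains link when mismatching informative markers /
informative markers compared ≤ `mismatch_tol`, and groups are the
single-linkage closure. The default tol = 0 makes groups exact
row-equality classes up to het/missing wildcards; a pair with no
informative markers in common links by convention, so an all-missing
strain joins the first group (and may chain groups together — accepted
and documented behavior of single linkage). `mismatch_tol` is exposed
because "substantially identical" is inherently a tolerance: with call
error rate ε, same-haplotype strain pairs mismatch at ≈ 2ε of markers
while distinct founder haplotypes differ at tens of percent, so any
tolerance comfortably between those scales (we use 0.1 in the recovery
analyses for ε = 0.01) separates the two regimes; at tol = 0 a single
miscalled genotype isolates a strain.

IBD over a selected subset is per-interval group identity, with maximal
runs of consecutive IBD-positive intervals merged. Merged bounds are the
genomic union of the constituents; because consecutive covering intervals
may overlap, a block can share boundary base pairs with a neighbor of
opposite state — marker-index bounds are authoritative. Enlarging the
selection can only shrink the IBD-positive set (group identity is
intersected), and within any block the default coloring gives all
selected strains identical colors in every constituent interval; both
properties are tested.

## Mosaic coloring

Within one interval, colors are haplotype groups. Across intervals,
colors chain: groups of interval t are matched to the colors of interval
t−1 by maximum-weight assignment on shared-strain counts
(`scipy.optimize.linear_sum_assignment`; zero-weight pairs are not
matches); matched groups inherit the color, unmatched groups take the
smallest index unused in the interval. At any boundary, the strains that
keep their color form an injective matching between the two partitions,
so boundary transitions are at least n − (max matching weight); the chain
attains that bound at every boundary simultaneously, so the coloring
achieves the global minimum of total transitions. A purely greedy
descending-weight matching was considered and rejected: intersection
matrices such as [[3,2],[2,0]] (realizable by partitions of 7 strains)
make greedy strictly suboptimal. The exhaustive-search oracle for the
minimum is test-only.

Order-based recoloring assigns each displayed strain the display rank of
the earliest-ranked strain sharing its group, making the top strain
monochrome and the coloring of the first k strains independent of those
below — the property that makes top-down reading of a small selection
work. Position sorting builds each strain's key from group ids at
intervals radiating from the selected position (containing interval
first; at equal distance right before left; inside an overlap the
interval with the smaller start wins) and sorts stably, so residual ties
preserve the incoming order.

## Ancestry and heterozygosity HMMs

Diagnostic SNPs: among a labeled reference panel of wild/wild-derived
strains of known subspecies, an allele whose homozygous carriers all
belong to one subspecies is diagnostic for it — fully informative
(weight 1) if every labeled strain of the subspecies carries it,
partially informative (weight `partial_weight`, default 0.5) otherwise.
Externally derived weights (e.g. array-intensity based) can be imported
through the diagnostics table.

The subspecific-origin HMM has states {domesticus, musculus, castaneus}
and walks the diagnostic markers of one strain. Log-emissions are
w·log(1−ε) for carrying the current state's diagnostic allele and
w·log(ε/2) for carrying another state's; het/missing/non-diagnostic calls
emit 0. The weight enters as an exponent on the emission likelihood
(log-linear weighting) — one observation model covers both informativeness
classes. Transitions are symmetric: log(1−(k−1)ρ) to stay, log(ρ) to
switch. Defaults ε = 0.05 and ρ = 10⁻⁶ were chosen so that one
fully-informative contrary SNP (gain log((1−ε)/(ε/2)) ≈ 3.64 nats) can
never pay for a switch round trip (≈ 27.6 nats); a contrary block needs
roughly four fully-informative SNPs before a switch is optimal. The
heterozygosity HMM is the two-state analogue with Bernoulli emissions
P(het | heterozygous) = `het_emit` (default 0.5) and P(het | inbred) =
`het_err` (default 0.01).

Viterbi decoding is exact (verified against exhaustive path enumeration
on all small random instances) with ties broken toward the smaller state
index. State paths compress to labeled segments whose boundaries sit at
the integer midpoint between flanking markers of different states;
chromosome ends close at the first/last informative marker. Each segment
carries a posterior proxy: the mean, over its markers, of the assigned
state's emission probability normalized across states (uninformative
markers contribute 1/k). Forward–backward posteriors and Baum–Welch
fitting are out of scope.

## Local phylogenies

For one interval, group consensus sequences (per-marker majority
homozygous allele; ties and empty columns undefined) give pairwise
distances = differing markers / markers where both consensuses are
defined (a pair with no comparable markers gets distance 1.0 with a
warning). Neighbor joining is the standard Saitou–Nei algorithm: join the
pair minimizing Q(i,j) = (n−2)d(i,j) − rᵢ − rⱼ, closed-form branch
lengths, distance updates d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2, and a final
three-taxon star. Negative branch lengths are clamped to zero with the
excess moved to the sister branch, preserving the pair's summed length.
On additive metrics the implementation recovers the generating tree
exactly (lengths to 1e−9, cross-checked against scikit-bio's NJ); on
clean compatible-interval data every SDP bipartitions the tol = 0 groups
along a tree edge, the perfect-phylogeny property the intervals exist to
guarantee.

Leaf annotations: supporting SNPs of a leaf are interval markers at which
all members share a defined allele that differs from at least one other
leaf's defined consensus; confidence is that count over the interval's
marker total. No published formula exists for the browser's displayed
confidence, so this definition is the package's own and is documented as
such. Trees are written as standard Newick (leaves `g<id>`) with a
sidecar table for membership, support and per-strain subspecies labels.

## Rendering

Tracks draw onto a primitive list (rects, lines, text) serialized with
fixed formatting, so identical inputs give byte-identical SVG — the
reference output format; PNG rasterizes the same primitives through
matplotlib/Agg and is not byte-stable across library versions. The
genomic-to-pixel map is pixel_x = round((pos − start) / span ×
pixel_width), clamped. A track renders per-feature detail when its
in-view item count is at most one per pixel, else a histogram with one
bin per pixel, bars normalized to the max bin in view; the un-normalized
bin counts always sum to the in-view item count. Allele letters overlay
mosaic tracks only in detail mode. The interactive browser this emulates
is replaced by CLI parameters (`--region`, `width`): the computation and
the visual semantics are the artifact, not the web stack.

## Synthetic panels

The generator emulates a mosaic-of-founders inbred panel: `n_founders`
founder haplotypes assigned to the three subspecies, founder alleles
independent Bernoulli(½) per marker except that a fraction
(`private_rate`, default 10%) of markers per subspecies carry a private
variant shared by all of that subspecies' founders — guaranteeing fully
informative diagnostic SNPs exist. Markers are uniformly placed. The
first `n_founders` strains are emitted as pure founder copies and serve
as the labeled reference panel; remaining strains are mosaics with
Poisson(`switch_rate`) breakpoints at uniform positions, each switching
to a different founder so drawn breakpoints are real. Generation order is
founder alleles → heterozygosity injection (one contiguous region of
`het_region_fraction` of the chromosome in each designated wild strain,
markers set heterozygous at `het_call_rate`) → allele-flip errors at
`err_rate` → missing at `miss_rate`; everything is reproducible from the
seed, and the recorded truth (founder segments, subspecies segments, het
regions, founder alleles) is exact for the pre-error genotypes.

What the generator deliberately lacks: within-founder linkage
disequilibrium, coalescent ancestry, recombination hotspots, array
intensity artifacts, structural variation. One visible consequence: with
independent founder alleles, most marker pairs already violate the
four-gamete test, so compatible intervals on synthetic panels are much
shorter (often 1–2 markers) than on real inbred panels whose haplotypes
are deeply shared. Passing tests therefore demonstrate algorithmic
correctness and calibrated recovery, not the long-interval structure of
real data.

## Evaluation conditions and problem sizes

The recovery analyses run on panels of 50 strains × 500 markers (the
structural overlap-depth check, 20 seeds) and 50 strains × 900 markers
(recovery), with ε = 0.01 call error, 2% missingness, two founder
breakpoints per strain in expectation, and 15%-of-chromosome
heterozygous regions in the wild strains — sizes at which every segment
holds tens of diagnostic markers and the whole suite runs in seconds. At
these conditions the subspecies HMM labels ≥ 95% of diagnostic markers
correctly, inferred heterozygosity blocks cover ≥ 90% of injected
regions, and haplotype grouping over breakpoint-free regions (≥ 10
markers, tol = 0.1 as motivated above) matches founder identity with
mean adjusted Rand ≥ 0.9. Exact identity (tol = 0) cannot meet that last
bound under 1% call error — a strain is error-free across a 50-marker
segment only with probability 0.99⁵⁰ ≈ 0.6 — which is precisely why the
tolerance exists; the tol = 0 behavior is instead pinned by a
complete-data equality test against row-equality classes.

## Known limitations

Single-linkage chaining can merge groups through wildcard-heavy strains;
the covering's greedy tie-breaks and the Viterbi's state-index tie-break
are deterministic conventions, not biological claims; boundary placement
at inter-marker midpoints is a display convention with uncertainty of
half the local marker spacing; heterozygous-ancestry (F1-like) states,
probabilistic IBD, bootstrap support and structural variation are out of
scope.
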