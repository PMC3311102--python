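# haplomosaic

Comparative analysis of many collinear genomes from a single strain panel:
the computational engine behind mosaic-style multi-genome browsers for
inbred model-organism panels (e.g. laboratory mouse strains), packaged as a
Python library with a thin command-line interface.

Given a biallelic SNP genotype matrix (strains × markers), haplomosaic
computes:

- **Compatible intervals** — a minimal full covering of the chromosome by
  maximal marker runs in which every SNP pair passes the four-gamete test
  (at most 3 of the gametes 00, 01, 10, 11 present), i.e. runs with no
  evidence of historical recombination. Each interval admits a single
  perfect phylogeny over its strain distribution patterns (SDPs), and the
  covering never stacks more than two intervals over any marker, so it
  always fits on two alternating display rows.
- **Haplotype groups and dynamic IBD** — within each interval, strains are
  partitioned into haplotype identity groups (single linkage on the
  fraction of informative mismatching markers; heterozygous/missing calls
  are wildcards). A region is identical-by-descent for a selected strain
  subset when all selected strains share one group; consecutive IBD
  intervals merge into blocks.
- **Mosaic coloring** — a chromosome-wide color assignment in which two
  strains share a color in an interval iff they share a haplotype group,
  with colors chained between intervals by maximum-weight matching on
  shared strains so that the total number of color transitions is
  minimized; plus an order-based recoloring (topmost strain monochrome)
  and haplotype sorting that radiates outward from a selected position.
- **Subspecific origin and heterozygosity HMMs** — diagnostic SNPs are
  called from a labeled reference panel (an allele confined to one
  subspecies is fully informative if all its labeled strains carry it,
  partially informative otherwise), then a 3-state Viterbi HMM
  (*M. m. domesticus* / *musculus* / *castaneus*; emission error ε,
  switch rate ρ) segments each strain's genome; a 2-state analogue
  segments inbred vs heterozygous blocks.
- **Local phylogenies** — neighbor-joining trees over an interval's
  haplotype groups from consensus-sequence distances, with per-leaf member
  strains, supporting-SNP counts and confidence, written as Newick.
- **Rendering** — deterministic SVG track images (ruler, SNPs, intervals
  on parity rows, color mosaics, IBD, origin, heterozygosity) that switch
  between per-feature detail and density histograms at one item per pixel.
- **Synthetic panels** — a ground-truthed founder-mosaic simulator
  (founders from three subspecies, Poisson breakpoints, genotyping error,
  missing data, residual heterozygosity) so every analysis can be tested
  without external data.

## Worked example

```sh
haplomosaic simulate --params sim.yaml --out-prefix demo/
haplomosaic intervals --genotypes demo/genotypes.tsv --out demo/iv.bed
haplomosaic ibd --genotypes demo/genotypes.tsv --strains S006,S007,S008 \
    --out demo/ibd.bed
haplomosaic mosaic --genotypes demo/genotypes.tsv --labels demo/labels.tsv \
    --strain S014 --out demo/origin.bed
```

with `sim.yaml` containing

```yaml
n_founders: 6
founders_per_subspecies: {domesticus: 2, musculus: 2, castaneus: 2}
n_strains: 16
n_markers: 120
chrom_length_bp: 300000
switch_rate: 2.0
seed: 11
```

prints

```
wrote demo/genotypes.tsv (16 strains x 120 markers)
wrote 71 intervals to demo/iv.bed
wrote 18 IBD blocks to demo/ibd.bed
wrote 2 origin segments to demo/origin.bed
```

`iv.bed` holds the 71 compatible intervals of the minimal covering (name
`ci<ordinal>`, score = marker count); the 18 IBD blocks are the merged
runs of intervals in which S006, S007 and S008 fall in one haplotype
group; and `origin.bed` is S014's inferred subspecies mosaic:

```
chr1    1203    163517  domesticus
chr1    163517  298911  musculus
```

The simulator's recorded truth for S014 is domesticus to 164,478 bp then
musculus — the HMM places the boundary at the midpoint between the
flanking diagnostic markers (163,517 bp) and, by design, smooths away a
4 kb castaneus sliver that contains too few diagnostic SNPs to justify
two state switches at the default switch rate ρ = 10⁻⁶.

The same computations are available as library calls (`simulate_panel`,
`maximal_covering`, `assign_all_intervals`, `compute_ibd`,
`default_coloring`, `call_diagnostic_snps`, `subspecies_viterbi`,
`build_local_tree`, `render_tracks`, ...); see the module docstrings and
`docs/methods.md` for the model details.

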