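# Methods

`polyweave` analyzes short-read data from allotetraploids — organisms
carrying two diverged parental genomes (here called A and D, after the
cotton A/D genome groups) in one nucleus. The central difficulty is that a
read may come from either subgenome; every downstream question (diversity
per subgenome, homoeologous conversion, introgression) depends on sorting
reads correctly. The package implements the full chain on a synthetic
allotetraploid panel whose every planted event is ledgered, so detection
can be scored against truth rather than against other callers.

## The simulator and what it does (and does not) emulate

A uniform-random ancestor genome diverges into two progenitor proxies by
independent per-site substitutions on each branch (default total A-vs-D
divergence 1%, matching the A/D divergence scale relevant to read sorting).
A fixed seven-species tree carries the tetraploid panel, with AD4 basal to
the split between the AD1 clade (AD3 diverging first, then AD1 vs
(AD6, AD7)) and the AD2 clade (AD2, AD5). Every edge, including one edge
per accession, applies substitutions at `branch_sub_prob` per site
(default 0.002). Subgenomes are haploid: the accessions modeled are highly
inbred and are genotyped per subgenome as a single consensus, so a diploid
within-subgenome state would add parameters without adding signal for any
operation tested here.

Planted events, all recorded in the event ledger with half-open intervals:

- **Conversion tracts** overwrite one subgenome's interval with the
  accession's own homoeologous alleles at the end of the accession's
  branch, so the output tract is base-for-base identical between
  subgenomes (the defining 4:0 dosage signature).
- **Duplications/deletions** do not alter sequence; they act at
  read-sampling time (deleted intervals produce no reads, duplicated
  intervals are sampled twice).
- **Introgression blocks** replace a recipient ("cultivar") accession's
  interval with the donor species' node consensus.
- **Autapomorphies** are single-site mutations private to one diploid
  proxy, planted away from divergence sites. They reproduce the classic
  false-positive pattern for conversion detection: A2 = AT = DT ≠ D5
  arises from a D5-lineage mutation, not from conversion.

Reads are single-end, uniform-start, fixed length (100 bp), with
independent per-base substitution errors (default 0.5%) and constant Q40
qualities. Not emulated: paired ends and insert sizes, indels, quality
error profiles, repeats, recombination, and coalescent incomplete lineage
sorting. Passing tests therefore demonstrate correctness of the *methods*
under clean mapping conditions, not robustness to repeat-rich real genomes
— mapping ambiguity in repeats, indel misalignment, and reference
incompleteness are explicitly out of scope.

## Mapping and the SNP-tolerant contract

The mapper is exhaustive unique-best: a read maps iff exactly one location
(chrom, start — over either strand) attains the minimal mismatch count,
and that minimum is ≤ `max_mismatch` (default 3 per 100 bp, enough for
~1% divergence plus ~0.5% error). Mismatches at positions listed in a
homoeo-SNP index are never counted, so reads carrying the divergent allele
at a known inter-genome SNP are not penalized. The implementation is a
pigeonhole seed index (a read with ≤ m counted mismatches must contain an
exact seed among m+1 non-overlapping seeds); seed k-mers crossing masked
positions are enumerated over all four bases there, and the seed length
shrinks automatically on dense masks so enumeration stays bounded. The
contract — verified against an all-positions brute-force scan in the tests
— is exact, not heuristic.

## Homoeo-SNP index construction

Reads from the diploid proxy of the *other* genome are mapped to the
chosen reference; positions where those reads support a consensus allele
different from the reference base enter the index, provided both sides are
confirmed at ≥ 5 reads and ≥ 90% allele purity (the purity figure absorbs
sequencing error; it is a package choice, with 5 reads being the standard
minimum-allele-coverage threshold used throughout). The new sites join the
SNP-tolerant mask, previously rejected reads are remapped, and the loop
repeats until a pass adds nothing. Remapping only previously unmapped
reads makes the mapped set, and hence the index, grow monotonically; on
the benchmark conditions the fixpoint arrives in 3–4 passes. A second
fixpoint loop adds tetraploid-specific sites: per species, sites where
≥ 75% of observed per-accession subgenome calls carry one allele in one
subgenome and a different allele in the other (a single observed call must
agree with itself, which is the stricter rule single-accession species are
held to).

## Read categorization

Voting (PolyCat-style): each read's bases at indexed positions vote for
the genome whose allele they match; bases under PHRED 20 do not vote;
strict majority labels the read, ties and zero evidence abstain.
Abstention on ties is deliberate — random assignment would leak signal
into conversion and introgression scans. Best-of-two (PolyDog-style): the
same read mapped independently (unmasked) to both parental references is
assigned to the reference with fewer mismatches; mapping to only one
reference decides outright; equal counts abstain. The voting error rate is
bounded by a per-read binomial argument: a read spanning k indexed sites
can only flip to the wrong genome if more than k/2 of those sites are hit
by sequencing errors, so P(wrong) ≤ P(Bin(k, e) > k/2).

## Genotyping, SNP classes, diversity

An allele is reported at ≥ 5 reads and ≥ 30% of total site depth (the 30%
is of total depth; "of called-allele depth" would differ only at noisy
sites). One qualifying allele is a haploid call; two are carried as
heterozygous and excluded from consensus computations (the simulator's
subgenomes are haploid, so het calls indicate noise or collapsed
paralogs); more are flagged ambiguous. Allele-SNPs are within-subgenome
polymorphisms across accessions, kept at minor-allele frequency ≥ 10%
computed over non-missing calls. Homoeo-SNPs are sites where the two
subgenome consensuses (≥ 75% agreement among observed calls) differ.
Diversity is the mean over accession pairs of differing sites divided by
co-covered within-group-polymorphic sites; a group with no internal
polymorphism has diversity 0 by definition.

## Copy number

Windowed mean depth of categorized reads is compared against a pooled
diploid profile of the matching genome, which cancels locus-specific
coverage and categorization-rate biases shared between diploid and
tetraploid carriers. After median normalization, log2 ratios (pseudocount
0.5, floor −8) are segmented by threshold runs: ≥ 3 consecutive windows
beyond the boundary merge into a segment; windows whose reference depth is
below 25% of the reference median are inaccessible and break runs. The
call thresholds are +1.0/−1.0 (a minimum 2-fold difference). Because a
single extra copy is *exactly* 2-fold, its expected log2 ratio sits
exactly on the call boundary; window qualification therefore includes a
noise allowance `margin` (default 0.4, about 2–3 window-level standard
errors at 20–30x with 1 kb windows — window log2 SD ≈
√2 / (ln 2 · √(reads per window))), without which roughly half the windows
of a true event would fail and run detection would fragment. Deletions are
far from the boundary (ratio floored at −8) and are insensitive to the
margin. Conservation across accessions is single-linkage clustering of
same-class segments at ≥ 50% reciprocal overlap.

## Conversion detection

Two complementary detectors, matching the two temporal regimes of the
phenomenon. The SNP-pattern method calls species consensus genotypes
(≥ 75% of individuals covered, ≥ 75% agreement), selects sites where the
four-way pattern holds (A-dominant: A2 = AT = DT ≠ D5; D-dominant the
mirror), and screens against the basal outgroup: the same pattern in AD4
means the site is an autapomorphy or a conversion coincident with
polyploidization (status `autapomorphy-or-ancient`); AD4 retaining both
parental alleles means a lineage-specific conversion (`likely-conversion`);
anything else is `outgroup-missing` and conservatively excluded. Regions
are maximal runs of ≥ 2 same-direction likely-conversion sites,
consecutive *among informative loci* (sites with diploid divergence and
tetraploid consensus) — physical gaps between informative sites are
data-dependent and carry no evidence. The CNV-overlap method targets
recent tracts at or above read scale: reads from a converted tract are
(correctly, by sequence) categorized to the donor subgenome, doubling its
coverage and zeroing the acceptor's, so a duplication segment reciprocally
overlapping (≥ 50% each way, through a homoeolog coordinate map) a
deletion segment in the same accession is a candidate. A build-time
observation worth keeping: with read-level data a fully converted tract
yields *missing* acceptor genotypes, not donor-like ones, so the
SNP-pattern method is structurally blind to large fresh tracts — the two
methods are complements, not alternatives.

## Introgression

Diagnostic SNPs are fixed differences between a wild conspecific panel and
a donor-species panel (consensus thresholds as above); cultivars are
excluded from the wild panel by construction (the function raises
otherwise), so the index cannot be contaminated by the introgression it is
meant to find. Cultivar reads are then voted native-like vs donor-like
with the same machinery, and introgressed regions are maximal intervals of
donor-like depth ≥ 10x, with a minimum length of two read lengths to
suppress single-read islands. Validation uses the four-taxon ABBA-BABA
D-statistic with the tree (((wild conspecific, cultivar), donor), diploid
outgroup): D = (nABBA − nBABA)/(nABBA + nBABA) over biallelic sites where
the outgroup fixes the ancestral state, with a delete-one block jackknife
(5 kb blocks) for the standard error. The diploid progenitor consensus is
the outgroup allele source — the only unambiguous ancestral proxy in this
design. Restricting the counted sites to predicted regions should push D
toward 1 when the regions are real; the genome-wide value measures overall
admixture.

## Phylogeny

Distances are proportions of co-covered SNP sites with differing haploid
calls; a pair sharing no covered site is an error naming the pair, not a
silent zero. Neighbor joining is the standard Q-criterion agglomeration
with seed-controlled randomization of taxon input order (tie-breaking on
non-additive matrices is order-dependent, and surfacing that through the
bootstrap is more honest than hiding it); negative branch lengths are
floored at zero with the deficit moved to the sibling, preserving path
lengths. Supports come from 1000 subsamples of 5% of sites drawn *without
replacement* — a deliberate departure from the classical with-replacement
bootstrap, kept because it is the resampling scheme this analysis is
defined by — combined by majority-rule consensus greedily extended with
compatible minority splits. Separate trees are built per subgenome; the
two parental genomes are deeply diverged and a joint tree would be
dominated by that split.

## Benchmark conditions and problem sizes

The evaluation scenarios (also run by `scripts/acceptance.py`) use 50–200
kb genomes, 20–30x coverage, 100 bp reads, 0.5–1% error, 1% progenitor
divergence, and desk-scale panels (1–4 accessions per species). Index
recovery runs at 100 kb/30x/0.5%; conversion planting uses ten 2 kb tracts
(≥ 5 informative loci each at 1% divergence) plus 50 diploid
autapomorphies; the CNV-overlap scenario plants one 5 kb tract at 30x with
1 kb windows; D calibration uses 20 replicates at 200 kb with elevated
branch rates (0.02/site) so that homoplasy supplies an informative-site
baseline in the absence of coalescent ILS; introgression recovery plants
three 8 kb donor blocks analyzed at 20x. These sizes are the package's
standard benchmark, chosen so each scenario completes in seconds to a few
minutes on one core.

## Numerical and degenerate-input conventions

All intervals are 0-based half-open internally; 1-based only inside SAM
and VCF. Zero categorized reads, zero informative D sites, and undefined
diversity are flagged (NaN plus a warning or an explicit field), never
silently reported as zero. Consensus and MAF threshold comparisons use a
1e-12 tolerance so that exact boundary fractions (10%, 75%) are kept, as
the definitions intend. Same seed means byte-identical outputs everywhere;
per-stage seeds are derived from the global seed by fixed offsets so
stages can be rerun in isolation.
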