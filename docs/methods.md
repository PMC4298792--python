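# Methods

## Genotype coding and filtering

Genotypes are coded by parental origin: A (homozygous for the reference
parent, i.e. the parent whose assembly the reads were mapped to), B
(homozygous for the other parent), H (heterozygous), U (missing). Reads map
REF to A and ALT to B because variant calling is performed against the
reference parent's own assembly.

Filtering is two-staged and the order matters: per-call thresholds first
(they can only turn calls into U), then per-site thresholds computed on the
already-cleaned calls.

* Call level: a homozygous call needs >= 1 supporting read and genotype
  quality >= 3; a heterozygous call needs >= 3 reads and quality >= 5. In a
  doubled-haploid (DH) population heterozygous calls are biologically
  impossible and are always discarded. Calls without depth/quality
  annotations fail the filter — shallow-coverage data should always carry
  per-sample depth, and silently trusting unannotated calls would defeat
  the filter's purpose.
* Site level: site quality >= 40; heterozygous fraction <= 10% and missing
  fraction <= 80%, both over **all** samples; minor allele frequency >= 5%
  over the **non-missing** calls, with H contributing half an allele to each
  parent. The denominator asymmetry is deliberate and documented in the
  function docstrings.

The stricter pre-mapping filter (`gbs_map_site_filter`, <= 10% missing,
<= 10% heterozygous) bounds the parental allele-count imbalance by
|A − B| / (A + B) <= 0.648, the unique symmetric linear imbalance statistic
that, in the absence of heterozygous calls, equals a minimum MAF of
(1 − 0.648)/2 = 17.6%. The threshold is a parameter.

## Placement model

A SNP's segregation pattern is matched against every framework marker by
Hamming distance over the jointly non-missing individuals; A vs H counts as
one difference like A vs B. *All* markers at the minimal distance are kept
as the neighbor set — ties are never broken, they are information: a
scattered neighbor set means the SNP's address is ambiguous. Markers with
zero call overlap are excluded from candidacy (their distance is
undefined); the case is irrelevant for dense framework maps but matters for
sparse simulated ones.

The four gates run in sequence: call rate (> 20% of individuals scored,
strictly), distance (<= 2, inclusive), chromosome concordance (>= 80% of all
neighbors on the winning chromosome; an exact tie between chromosomes
rejects, because emitting an arbitrary winner would be worse than no call),
and dispersion (unscaled MAD of the winning chromosome's neighbor positions
< 5 cM, strictly). The placed position is the median (midpoint convention
for even counts) of the neighbor cM values on the winning chromosome; the
median and the MAD are deliberately computed on the same restricted set.
For maps whose length is inflated ~3x by treating an advanced RIL
population as DH, the MAD bound is raised to 15 cM — a parameter, not a
code path. Contig anchoring applies the same 80%/MAD rule to a contig's
placed SNPs; the 80% denominator counts placed SNPs by default
(`denominator="all"` counts every SNP on the contig instead).

The batched search uses one-hot indicator matrix products
(distance = overlap − agreement), which is exactly the exhaustive scan in
linear-algebra form; the test suite checks equality against a pure
per-element counting oracle across ~10^4 random instances.

## De novo map construction

Contigs spanning >= 10 SNPs are collapsed to one consensus call per
individual: counts (a, b) of A and B SNP calls (H ignored); any individual
with a >= 2 and b >= 2 sets the whole contig aside as internally conflicted
(evidence of mis-calls or cross-contamination); otherwise the majority wins
when a + b >= 3, ties and thin evidence give U. Contigs consensus-callable
in fewer than 75 of 90 individuals are dropped. The conflict rule is
evaluated per individual — aggregating over the population would reject
every segregating contig, so no aggregate variant is offered.

Two-point estimates use only individuals homozygous-parental at both
markers: r^ = k/n and LOD = k log10 r^ + (n − k) log10(1 − r^) + n log10 2,
with 0·log 0 = 0, LOD = n log10 2 at k = 0, and LOD exactly 0 at r^ = 1/2.
Linkage groups are connected components of the graph with edges at
LOD >= 10 **and** r^ < 0.5; the second condition keeps repulsion artifacts
(significant but negative association) from bridging chromosomes. Groups
smaller than 3 markers are discarded.

Ordering is intentionally simple: minimum spanning tree under edge weight
r^, diameter path (in cumulative Kosambi cM) as the backbone, off-path
markers inserted after the backbone marker their tree path first reaches.
This stands in for external multi-point ordering tools; its contract is
order recovery on simulated data (|Spearman rho| >= 0.99 error-free), not
equality with any particular tool. All tie-breaks are lexicographic in
marker id, so the ordering is deterministic. Map distances use Kosambi
d = 25 ln((1+2r)/(1−2r)) by default (Haldane d = −50 ln(1−2r) available);
r >= 0.5 is capped at a configurable 1000 cM with a warning.

## Map projection

Positions are translated between two maps of the same genome by a
per-chromosome loess fit (cm_target on cm_source) over anchor markers known
to both maps: tricube weights, local degree 1, span 0.3. The degree is
fixed at 1 — local quadratics buy nothing for monotone map-to-map relations
and misbehave at chromosome ends. Queries beyond the anchor range are
linearly extrapolated from the boundary neighborhood's local fit.
Chromosomes with fewer than 5 anchors return NaN with a warning.

## The simulator

`popsim` emulates the experiment the package targets, with every random
draw flowing from a single seed:

* Genome: 7 chromosomes x 150 cM; framework markers and contigs uniform;
  contig lengths log-normal (median 1 kb, sigma 0.7); SNPs per contig
  geometric (mean 3, min 1), co-inherited within a contig. A subset of
  contigs is bundled into clones — groups of 2–6 contigs sharing one
  genetic position, emulating ~100–200 kb BAC inserts (at barley-like
  scale, 200 kb is ~0.04 cM, i.e. genetically one point).
* Meiosis: crossover counts Poisson(L/100), positions uniform — the
  Haldane no-interference model. Interference is out of scope because every
  threshold in the method operates at multi-cM scale. DH: one gamete,
  doubled. RIL: g − 1 rounds of selfing from the F1 with two independent
  meioses per round, leaving the textbook 0.5^(g−1) residual
  heterozygosity (0.78% at F8). An optional `residual_het` rate can inject
  heterozygosity directly.
* Observation: each true call is seen with probability `call_rate` (0.35
  by default — with n = 90 this reproduces a mean of ~31–32 present calls
  per marker, the signature of ~1x sequencing; the Lander–Waterman helper
  maps fold-coverage to call rate), flipped A<->B with probability
  `genotype_error` (0.005), and dressed with a zero-truncated Poisson read
  depth and GQ = 3 per read so the genotype filters are exercisable. Site
  qualities are drawn around 75 so that the QUAL >= 40 filter removes a
  realistic trickle.
* Framework map: markers carry their *true* genotypes (array genotyping is
  essentially complete and error-free at these scales), with one
  adjustment real maps share: markers with identical segregation patterns
  are genetically inseparable, so each co-segregation group collapses to a
  single cM position (the median of its generating positions). Without
  this, self-placement of a marker whose pattern recurs at another position
  would return a blurred position that no estimated genetic map would
  produce.

What the simulator does **not** model: read-level errors and depth
correlation along contigs, repeat-induced mis-mapping, assembly chimeras,
segregation distortion, and crossover interference. Passing tests therefore
demonstrate the correctness and calibration of the algorithms under clean
genetics, not robustness to artifacts of real assemblies.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run the full default conditions
(2,000 framework markers, 5,000 contigs, n = 90) for the anchoring route
and 800 high-SNP contigs (min 10, mean 20 SNPs — contigs that clear the
>= 75-individuals consensus bar at a 35% call rate necessarily carry more
than the bare minimum of SNPs) for the de novo route; smaller unit-test
fixtures use 60–90 individuals and a few hundred markers. Medians of
even-sized sets use the midpoint convention throughout; MAD is unscaled.
Distance comparisons are inclusive (<= 2), MAD comparisons strict (< 5),
matching how the thresholds are stated. Degenerate inputs (empty neighbor
sets, zero informative meioses, chromosome ties) each have an explicit,
deterministic outcome documented in the corresponding docstring.

## Known limitations

* Pairwise two-point estimation is quadratic in the number of consensus
  markers; fine for ~10^3–10^4 markers, not for 10^5 without pruning.
* The MST-diameter ordering can locally permute markers inside
  zero-recombination bins (they are genetically indistinguishable) and has
  no error-correction step; multi-point likelihood ordering is a non-goal.
* Consensus-map merging across populations and genotype imputation /
  sliding-window smoothing are not implemented.
* Contig orientation and intra-contig SNP order are below genetic
  resolution and are not attempted.
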