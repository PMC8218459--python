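# Methods

This note documents the models, estimators and numerical choices behind
`ssrgbas`, in the order data flows through the package.

## Synthetic data model

The generator reproduces the structure of an SSR-GBAS study so that every
downstream stage can be validated against known truth.

**Loci.** A locus is a perfect tandem repeat (motif length 2–5, defaults
tetranucleotide) between two fixed flanks, amplified by a forward and a
reverse primer. Default geometry: 20 bp primers, 115 bp flanks, 8–15
repeats. This puts every primer-trimmed insert at 262–290 bp — above the
250 bp read-length threshold even after single-unit stutter — and every full
amplicon at 302–330 bp, inside the 300–450 bp product window used when
designing markers for 2×300 bp paired-end sequencing. Half of the loci (by
default) carry one flanking SNP, so same-length sequence alleles exist and
the WAI caller is actually exercised.

**Population model.** Allele frequencies per population follow the
Balding–Nichols island model: given ancestral frequencies `p` and a target
differentiation `F`, population vectors are Dirichlet draws with parameters
`p_i (1 − F)/F`. The first two moments are exact — E[p_pop] = p and
Var(p_pop,i) = F p_i (1 − p_i) — which is what makes F recoverable by an
F<sub>ST</sub> estimator and is the reason this model was chosen over a
coalescent simulation (closed-form expectations, no genealogy machinery).
`F = 0` returns the ancestral vector unchanged. Genotypes are drawn with an
inbreeding mixture: with probability `f` an individual is autozygous (one
allele drawn, duplicated), otherwise two independent gametes, giving
E[heterozygosity] = (1 − f)·2pq and E[F<sub>IS</sub>] ≈ f.

**Reads.** Per (sample, locus) the read count is Poisson(`mean_depth`,
default 100). Each read copies one of the two true alleles uniformly,
loses one repeat unit with probability `stutter_prob` (default 0.15 — the
dominant PCR-slippage mode; multi-unit and gain stutter are not modelled),
then receives independent per-base substitutions at `base_error_rate`
(default 0.001). Reads are emitted already merged, 5'
primer → insert → reverse-complemented 3' primer, with constant Phred-38
qualities (quality is unused downstream). Indel errors, chimeras and
fragment-length variation are not modelled; a passing end-to-end test
therefore demonstrates correctness of the calling logic under the stated
artifact model, not robustness to every failure mode of a real sequencer.

**Mitochondrial alignments.** A random ancestor of length L (default 658)
is mutated into one founder per group at `divergence_spec[g]` distinct
sites; site pools are disjoint across groups, so inter-group Hamming
distances are exactly the sum of the two counts. Optional
`within_variation` adds private singleton mutations per non-founder
sequence. No recombination, rate heterogeneity or back-mutation.

## Marker discovery

The scanner reports every maximal run of a primitive unit (a unit that is
not a power of a shorter one) meeting the per-motif-length repeat minimum
(defaults 9, 7, 5, 5 for lengths 2–5); N breaks tracts. Motifs are
canonicalized to the lexicographically smallest rotation of the observed
strand; reverse-complement folding is deliberately not applied, matching
per-strand reporting of merged reads (the alternative would halve motif
classes but lose strand information). A tract may start up to one unit
before its planted position when a flank base happens to extend a rotation;
this is correct maximal-tract behaviour, not an off-by-one.

Candidate filters, applied read by read with a first-failing-rule tally:
flanks ≥ 30 bp on both sides; exactly one qualifying tract; no interrupted
motif — operationalized as another copy of the motif (any rotation) within
two unit lengths of either tract end, since "interrupted" is otherwise
undefined for a perfect-repeat scanner; no A/C/G/T homopolymer longer than
6 bp anywhere in the read. The amplicon-placement check accepts a candidate
whose complete tract lies within the first or the last 300 bp of the
template (so one mate of a 2×300 bp pair covers it fully); templates longer
than the 450 bp maximum product with a mid-template tract are rejected.

## Genotyping

**Demultiplexing** matches the read's fixed 5' prefix against each forward
primer and its 3' suffix against each reverse-complemented reverse primer by
Hamming distance (≤ 2 mismatches per primer; primers are synthesis anchors,
so indels are not expected at the read ends). Reads matching both primers of
two loci are "ambiguous", mixed primer pairs are "chimera"; both stay
unassigned, and assigned + unassigned always equals input.

**Length calling.** Reads shorter than 250 bp are discarded; per-length
counts form the histogram. Peaks with ≥ 10 reads are candidate alleles. A
candidate exactly one motif length below a higher-count candidate, with
fewer than `stutter_ratio` (default 0.5) times its reads, is reclassified as
stutter; its reads are added to the parent, since they originate from the
parent template. Parents are processed in decreasing count order so chained
shadows collapse. After absorption: two candidates are a heterozygote when
the minor/major count ratio is ≥ `min_minor_ratio` (default 0.25; below it
the major peak is called homozygous with a flag), one candidate is a
homozygote, none is missing (`low_depth`), three or more is missing
(`ambiguous`). The 0.5 and 0.25 ratios are exposed configuration defaults —
reasonable operating points for ~100× amplicon data, not published
constants.

**WAI calling.** Within each called length class the consensus is the
per-position majority base (ties → N). A position "splits" the class when
the second base reaches ≥ 25% of the class and ≥ 10 reads. A
length-homozygote with a split becomes a heterozygote of two same-length
sequence alleles (reads partitioned by the bases at the splitting
positions); more than two well-supported sub-groups, or a split inside one
class of a length-heterozygote, would imply a third allele in a diploid and
yields a missing/ambiguous call. Allele identity is keyed by
(locus, length, consensus sequence) rather than by a SNP signature relative
to a per-sample consensus — a sample homozygous for the alternate base would
otherwise collide with the reference homozygote. Ids are assigned after all
samples are processed, sorted by (length, consensus), so the matrix is
independent of sample processing order; signatures are reported relative to
the first consensus of each (locus, length).

**Missing-data filter.** Loci with > 60% missing entries are removed first
(failed markers), then samples are re-evaluated on the retained loci at the
same threshold; both thresholds and the order are configurable and every
exclusion is reported with its missing fraction.

## Population statistics

Frequencies count two allele observations per fully typed individual;
missing entries leave the denominator. H<sub>e</sub> = 1 − Σp² is the
biased (GenAlEx-style) estimator used for the main tables; the unbiased
2n/(2n−1) variant is reported alongside as uHe. Ne = 1/Σp²,
F<sub>IS</sub> = (H<sub>e</sub> − H<sub>o</sub>)/H<sub>e</sub> (undefined at
H<sub>e</sub> = 0), Npa counts alleles seen in exactly one population, and
PIC = 1 − Σp² − Σ<sub>i<j</sub> 2p<sub>i</sub>²p<sub>j</sub>².

**HWE.** Chi-square goodness-of-fit over all k(k+1)/2 genotype classes with
expectations from the sample allele frequencies; df = k(k−1)/2. Rare
classes are not pooled (a warning is attached when an expectation drops
below 1); exact tests are out of scope. No multiple-testing correction is
applied by default, matching the raw-p reporting convention of the marker
tables.

**Null alleles.** The EM estimator fits allele frequencies
(p₁…p<sub>k</sub>, β) with β the null allele, under Hardy–Weinberg
proportions, treating each observed homozygote class i/i as a mixture of
true homozygotes (p<sub>i</sub>²) and null heterozygotes
(2p<sub>i</sub>β). No blank (null/null) class is observed, so the model is
the deficient multinomial with a structural zero count for β²; the tests
verify the EM against a profile-likelihood grid of the same model
(agreement < 10⁻³). Convergence is on the total parameter change
(default 10⁻⁶); near β = 0 the EM converges linearly, so boundary cases
report a small positive value of order the tolerance. A single visible
allele leaves β unidentifiable (reported as unavailable).

## AMOVA, F<sub>ST</sub>, PCoA

Sums of squares are computed at the allele-copy (gamete) level: the
distance between two copies at a locus is 0/1 by allele identity, which is
exactly half the squared Euclidean distance between allele-count vectors —
so the analysis partitions the classic squared genotypic distances
(0, 1, 2, 3, 4 per locus between diploid genotypes) while adding the
within-individual stratum. Strata: regions, populations within regions,
individuals within populations, allele copies within individuals. Variance
components come from the standard expected-mean-square equations with
unbalanced-design coefficients computed from gene-copy counts; negative
components are truncated to zero for percentages and Phi statistics, with
raw values reported alongside. The overall F<sub>ST</sub> of a hierarchical
design is (σ²<sub>regions</sub> + σ²<sub>pops</sub>)/σ²<sub>total</sub>.
With missing data, per-locus sums of squares use the individuals typed at
that locus while degrees of freedom come from the full design; the
partition identity SS<sub>total</sub> = Σ strata still holds exactly.

Pairwise F<sub>ST</sub> defaults to the same allele-level AMOVA restricted
to the pair, whose Phi statistic is an unbiased estimator of Wright's
F<sub>ST</sub> under random mating (it agrees with Weir–Cockerham θ to
within sampling error in the tests). The individual-level PhiPT variant —
which omits the within-individual stratum and has expectation 2F/(1+F)
under Hardy–Weinberg, i.e. systematically larger than F — and
Weir–Cockerham θ are available as alternative methods for cross-checks.
Permutation tests shuffle units at the stratum under test (individuals
among populations, individuals within regions, whole populations among
regions) and compare the raw, untruncated statistic, keeping the null
distribution continuous so p-values are uniform under the null;
p = (hits + 1)/(n + 1). All permutation procedures take an explicit seed.
Note that permuting whole populations among regions has very few distinct
arrangements in small designs (e.g. 2 regions × 2 populations), so the
region-level p-value is coarse by construction.

PCoA double-centers −½D² (or −½D when the input already holds squared
distances, as the genotypic distance matrix does), takes the
eigendecomposition, scales eigenvectors by √λ and reports percent variance
over positive eigenvalues only; negative eigenvalues (possible for
non-Euclidean inputs) are excluded from both coordinates and percentages.

## Mitochondrial analyses

Haplotype collapsing uses strict character equality by default (N ≠ A):
wildcard matching would merge distinct haplotypes through shared ambiguous
positions; a flag enables wildcard collapsing when desired. p-distances
exclude positions where either sequence carries N/-/? (pairwise deletion),
which can make the matrix slightly non-metric — triangle-inequality
violations are possible and tolerated.

**Parsimony connection limit.** The limit is the largest number of steps j
for which the probability that j observed differences equal j true
substitutions is ≥ α (default 0.95), floored at 1 (single-step connections
are parsimonious by definition). The probability model is an explicit
finite-sites Jukes–Cantor construction: from the observed proportion
p = j/L, the per-site substitution count is Poisson with mean
d = −¾ ln(1 − 4p/3); conditional on a site differing, it was hit exactly
once with probability d·e^(−d)/p, and conditional on matching, it was never
hit with probability e^(−d)/(1 − p); the parsimony probability is the
product over all L sites. At 658 bp and α = 0.95 this gives 8 steps, inside
the range practitioners report for COI-length alignments; the limit is
non-decreasing in L and collapses to 1 as α → 1. The test suite checks the
computation against an independently coded version of the same algebra.

**Network.** Haplotype pairs are processed in increasing Hamming-distance
order (ties broken by smallest id pair, making the result input-order
independent). A pair within the limit is connected — unless the graph
already offers a path no longer than its distance — by a chain of d − 1
inferred intermediate nodes, realizing the differing sites in ascending
position order (one deterministic path; alternative mutational orders are
not enumerated). Pairs beyond the limit are never joined directly, so
deeply diverged groups remain separate components.

**UPGMA.** Arithmetic-mean agglomeration with node height = half the merge
distance (so ultrametric inputs are reproduced exactly) and smallest-id tie
breaking. Bootstrap: alignment columns are resampled with replacement,
distances and trees recomputed, and bipartition frequencies attached as
percent supports. Cross-checked against scipy's average-linkage heights.

**Haplotype F<sub>ST</sub>.** Frequency-based
(H<sub>T</sub> − H<sub>S</sub>)/H<sub>T</sub> per population pair, with
H<sub>S</sub> the mean within-population haplotype heterozygosity and
H<sub>T</sub> the pooled value; permutations shuffle sequences between the
pair (default 1023). Populations with one sequence are reported as
unavailable.

## Problem sizes and reproducibility

The test suite and `scripts/acceptance.py` run everything on simulated
data at the package's chosen design sizes: genotype recovery on
3 populations × 12 individuals × 10 loci at depth 100;
F<sub>ST</sub> recovery on 20 loci × 3 × 30 individuals (the acceptance
script averages three replicate draws of that design, since a single draw
of 20 loci has Monte-Carlo scatter of ±0.03–0.04 in mean F<sub>ST</sub>);
F<sub>IS</sub> recovery on 20 loci × 50 individuals; permutation-null
uniformity on 40 replicates of a small two-population design at 199
permutations; mitochondrial analyses on 658 bp alignments. Every stochastic
step takes an explicit seed and is bit-for-bit reproducible given it.

## Known limitations

- Primer matching is substitution-only; primer-site indels send reads to
  the unassigned pool.
- The stutter model and its thresholds target tetra/pentanucleotide loci;
  dinucleotide panels would need a stronger stutter model (multi-unit
  shadows, additive SNP interference).
- The chi-square HWE test is anti-conservative for rare alleles; no exact
  test is provided.
- AMOVA handles missing data by per-locus exclusion with full-design
  degrees of freedom, which is approximate under heavy missingness.
- The parsimony-probability model is an explicit reconstruction of the
  finite-sites argument behind statistical-parsimony limits; other
  implementations of the idea may differ by a step or two at a given
  length.
- Bayesian clustering (STRUCTURE-style), linkage disequilibrium and
  maximum-likelihood phylogenetics are out of scope.
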