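# Methods

## Model and assumptions

Male mutation bias (α = male/female germ-line mutation rate) modulates
neutral substitution rates by chromosome class because the classes differ
in how much evolutionary time they spend in males: Y always, autosomes
half, X one third.  Under the standard residence-time argument the
expected rate ratios are

    X/A = 2(2+α) / (3(1+α)),   Y/A = 2α / (1+α),   Y/X = 3α / (2+α),

and each ratio inverts to a closed-form α estimator.  The estimators share
three assumptions: substitutions at the analysed sites are neutral, α has
been constant along the compared branches, and no other force (GC-biased
gene conversion, selection, replication timing) differs systematically
between the classes.  Estimates outside the model (α < 1, or rates past an
estimator's pole) are flagged rather than clipped so that real-data
pathologies stay visible.

A sex-chromosome turnover converts X-linked sequences back to autosomal
inheritance.  A lineage that carried the ancestral X for T Myr before the
turnover therefore carries a substitution deficit relative to an
always-autosomal lineage, proportional to T.  Two calibrations of the
deficit are implemented:

* `paper_linear` (default): Δ = (c6/6)·α·T/10 with c6 = 0.0227 per 10 Myr,
  the calibration anchored so that α = 6 gives 0.0227 and α = 2.4 and 4
  give 0.0091 and 0.0151.  This is the calibration used for the published
  simulation scenarios.
* `miyata`: Δ = μ·T·(α−1)/(3(1+α)), the X-vs-autosome deficit implied by
  inverting the X/A ratio at conversion rate μ.  It is internally
  consistent with the μ = 2.22e-9/site/year time-to-substitution
  conversion — note that the linear constants are not: at α = 6 the linear
  deficit (0.0227/10 Myr) slightly exceeds the total autosomal length
  accumulated per 10 Myr (0.0222), so a full-retention lineage at high α
  exhausts its branches.  Branches are clamped at 1e-6 substitutions/site
  with a logged warning when a scenario over-shortens them.

Scenario application distributes a lineage's deficit along its
root-to-tip path in proportion to the Myr each branch overlaps the
X-linked window [system_age − T, system_age] (measured before present,
using the Myr metadata carried through unit conversion).  A branch
ancestral to several focal tips is shortened once, with the mean α of its
focal descendants — the tree-structure averaging rule for internal
branches.

## Estimators

**TN93.**  Pairwise distances use the closed-form Tamura–Nei estimator
(two transition classes, unequal base frequencies, frequencies averaged
over both sequences).  For pairwise data the closed form coincides with
maximum likelihood under TN93.  The implementation agrees with
`ape::dist.dna(model = "TN93")` to 1e-12 on fixtures.  Saturated pairs
(non-positive log argument) are flagged and excluded from downstream
medians, never truncated.  Zero-frequency corner cases drop the vanished
term (its coefficient is zero).

**Synonymous proxy.**  Synonymous rates are estimated as TN93 on third
positions of codons that are four-fold degenerate in *both* sequences
(same codon-family prefix among CTN, GTN, TCN, CCN, ACN, GCN, CGN, GGN;
stop codons excluded and counted).  This is a deliberate, documented
replacement for a full codon-model dS: it is closed-form, dependency-free
and targets the same neutral site class, but it ignores the small
synonymous signal at two-fold sites and any codon-usage effects.
A configurable floor (default 50 four-fold sites per pair) guards against
unstable distances.

**Branch lengths.**  Branch lengths on the fixed species topology are
estimated by non-negative least squares on the leaf-pair path design
(NNLS equals ordinary least squares with negative estimates clamped to
zero and the remainder refit).  The fit is exact on additive matrices.
The two child edges of a degree-2 root are not separately identifiable
from pairwise distances; they are fitted as one stem and split evenly.
No topology search is performed anywhere.

**Resampling.**  The intron analysis uses a double bootstrap: introns
resampled with replacement to the original intron count, then columns
resampled within the concatenated resample to the original column count,
1,000 replicates by default.  For the default TN93 statistic the column
resample is drawn as a multinomial over pooled per-intron site-pattern
counts — distributionally identical to explicit column resampling and far
faster; an explicit-resampling path exists for arbitrary statistics and
the two are checked against each other in the tests.  The codon analysis
resamples whole codon columns (triplets, all taxa together) 100 times and
takes per-branch medians as the consensus tree, retaining the replicate
distributions.  All intervals are percentile (2.5/97.5) unless noted;
point estimates are medians wherever the method prescribes medians.

**α confidence intervals** propagate the paired bootstrap distributions
through the Miyata equations replicate-by-replicate (matched by replicate
index); undefined replicates are excluded and counted, and an estimate
with more than 50% undefined replicates is flagged unstable.

## The dating scan

Observed per-species values are cumulative synonymous branch lengths from
a focal common ancestor to each tip, corrected replicate-wise by matched
autosomal trees (corrected_i = x_i − (a_i − mean_focal(a)); the corrections
sum to zero over the focal set, and the operation is invariant to adding a
constant to all autosomal lengths).  A ratio-form correction is available
behind a flag but is not the default.

The simulation arm evolves random sequences (HKY, κ = 2, uniform
frequencies by default; GTR accepted via configuration) along the
scenario-transformed tree and re-estimates branch lengths from the
simulated alignments with the same TN93 + least-squares machinery, so both
arms share every estimation artefact.  Two variance-control choices
matter at desk scale:

* **Common random numbers.**  Simulation replicate r uses the same RNG
  stream in every scenario, so between-scenario contrasts are not swamped
  by independent simulation noise.  Marginal per-scenario CIs remain
  valid.
* **Replicate-wise rescaling.**  Simulated and observed data are put on a
  common scale through a reference group carrying no X-linkage signal
  (e.g. the never-X-linked snake group).  Each replicate is divided by its
  own reference value and re-anchored at the observed reference median.
  A single global median-ratio factor would leave the reference-group
  noise outside both confidence intervals and miscalibrate the overlap
  decision; the module-level global rescale remains available as an
  operation.

For every scenario retention time T the Welch 95% CI of the simulated
lineage mean (one-sample t interval over simulation replicates, the
interval R's `t.test` prints) is intersected with the observed 95%
bootstrap CI.  The overlapping T values form the inferred interval
[T_min, T_max]; loss dates are system_age − T.  Non-contiguous overlap
sets are reported verbatim with a flag.  Whether T = 0 overlaps is the
null hypothesis test: a lineage that never carried the system should be
compatible with the null scenario and nothing else systematic.

Group statistics use Welch two-sample t-tests, Benjamini–Hochberg step-up
adjustment, and two-sided Mann–Whitney U, all through scipy/statsmodels.

## Synthetic data

The generator produces the two kinds of input the pipeline consumes, with
known truth records sufficient to score recovery.

**Two-species intron design.**  A-class introns evolve at the base rate
(default: 30-Myr divergence at μ = 2.22e-9/site/year); X- and Y-class
introns at the Miyata-implied multipliers 2(2+α)/(3(1+α)) and 2α/(1+α).
Generator and estimator therefore share only the algebra — recovery is a
genuine round trip through sequence space.  Defaults: 77 genes per class,
2–5 introns of 200–3,000 bp each plus a decoy first intron, 20-nt flanks,
CpG decoys injected at 1% of positions, ambiguity codes at 0.2%.  Each
intron's rate is scaled by a lognormal multiplier (log-sd 0.3, mean
exactly 1): local mutation-rate variation between introns is the reason
the bootstrap resamples introns, and without it the double bootstrap
double-counts site-level variance and over-covers.

The intron backbone is cytosine-free (base frequencies 1/3, 0, 1/3, 1/3).
This is a deliberate synthetic-design choice, not an attempt at realism:
applying the CpG column filter to a homogeneous four-letter backbone
removes mismatch-enriched columns (removal is conditioned on C–G adjacency
in either sequence, which correlates with mismatch status) and biases the
class distances differentially by 10–14%, confounding the very estimand
the dataset exists to test.  With a C-free backbone every detectable CpG
is an injected decoy, the filter's work is measurable (the injection rate
is recovered from the audit ledger), and the retained sites are an
unbiased sample of the backbone.  Real intron data differ in exactly this
respect: genuine CpG hypermutability and compositional structure are not
emulated, so passing tests certify the machinery, not the filter's
behaviour on real GC landscapes.

**Multi-taxon codon design.**  Genes are built from four-fold-degenerate
codon families; third positions evolve along the scenario-transformed tree
(the truth), first/second positions at 5% of the neutral rate so
amino-acid structure is realistic without destroying degeneracy.  The
packaged demo tree has 10 taxa (3 snake-like, 3 always-X "pleurodont-like",
2 focal "agamid-like", 2 outgroup) with a 120-Myr-old system.  The
always-X background clade runs at α = 2.4 (the mammal/bird-typical value)
so that no branch exhausts its length under the linear calibration.

## Problem sizes

Desk-scale defaults keep every analysis on one core: α recovery uses 200
genes (single estimate) and 200 repeated generations of 40 genes for CI
coverage; the dating recovery uses 50 genes of 999 nt, 100 codon
bootstraps, 13 scenarios × 20 simulation replicates of 1,000 nt, repeated
20 times each for the T = 80 and T = 0 truths.  These sizes were chosen as
the smallest at which the scan's 10-Myr grid step remains informative.

## Known limitations

* The scenario-grid step (10 Myr) bounds dating resolution; observed-arm
  sampling noise at 50-gene scale widens the recovered interval to roughly
  ±15–20 Myr.
* The published per-10-Myr constants are mutually inconsistent with the
  μ-based time conversion at high α (see above); both calibrations are
  exposed and the choice is recorded in every output.
* The synonymous proxy underuses two-fold degenerate sites and assumes the
  standard genetic code.
* No rate-across-sites variation, indels, selection, or GC-biased gene
  conversion in the simulator; branch lengths are the only channel through
  which male mutation bias acts.
* Scenario application assumes an ultrametric (time-calibrated) input tree
  for window placement along root-to-tip paths.
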