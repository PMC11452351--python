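# Methods

## The statistics

At a biallelic core SNP x0 with derived-allele frequency f, the n phased
haplotypes split into a derived class H1 and an ancestral class H0.
Classic extended-haplotype tests (iHS) integrate the class-level extended
haplotype homozygosity

    EHH(x_i) = sum_h C(n_h, 2) / C(|H|, 2)

outward from the core over genetic distance (trapezoidal quadrature,
iHH).  A sweep rising on several founder haplotypes — soft, via standing
genetic variation (SGV) or recurrent beneficial mutation (SRM) — breaks
class-level homozygosity quickly even while each founder lineage remains
internally homogeneous, which is why iHS loses power on soft sweeps.

The local-cluster family measures homozygosity inside clusters instead.
For each focal haplotype h_j, its local cluster is h_j plus the s nearest
haplotypes of the same allele class by Hamming distance over the local
window (L = 400 SNPs per side), with

    s = min(max(ceil(r * |Hc|), 8), |Hc|),   r = 0.1 by default.

iHH is integrated within each cluster and averaged over focal haplotypes
to give iHHL_c per class; the statistics are

    uiHSL   = ln(iHHL_1 / iHHL_0)
    uRiHS_c = ln(iHHL_c / iHH_c)
    RiHSL   = iHSL^2 + RiHS^2        (on standardized scores)

Raw scores are z-standardized in derived-allele-frequency bins fitted
genome-wide (allele age confounds haplotype length).  RiHS uses the class
selected by the sign of the standardized iHSL.  Setting r = 1 makes every
cluster the whole class and iHSL collapses to iHS exactly.  Under
neutrality iHSL is approximately standard normal and RiHSL approximately
chi-square with 2 df; p-values are 2*Phi(-|iHSL|) and exp(-RiHSL/2).
The exponential form is the upper-tail chi-square(2) probability — the
convention under which the 1% critical value 9.2103 is exceeded by 1% of
neutral scores; a lower-tail reading would make large scores
non-significant and is inconsistent with that threshold.

Power at a 1% false-positive rate uses the analytic thresholds 2.3263
(one-tailed standard normal, derived-allele direction) for iHSL/iHS/nSL
and 9.2103 with iHSL > 0 for RiHSL.  H12 significance uses the empirical
99th percentile of matched neutral simulations.

### Numerical choices

* Integration extends per side to the earlier of L = 400 markers or the
  chromosome end; no EHH cutoff is applied by default (see above).  When
  a cutoff is configured, integration stops after the trapezoid that
  crosses it (the iHS convention).  Sites whose window is cut by a
  segment edge are scored on the truncated window and flagged
  `edge_truncated`.
* Hamming ties at the s-th neighbour break by (distance, haplotype
  index); all cluster operations are deterministic.
* Cluster membership is focal + s neighbours (|cluster| = s + 1, capped
  at the class size); neighbour candidates are restricted to the focal's
  own allele class by default, since the s-rule and the iHHL average are
  defined on |Hc| and only under this restriction does r = 1 reduce iHSL
  to iHS exactly.  A whole-sample neighbour pool
  (``ScanParams(neighbor_pool="all")``) is implemented as well — clusters
  may then mix core alleles and cluster EHH starts below 1 at the core;
  it calibrates identically under neutrality but dilutes the
  derived-class cluster signal of very soft (recurrent-mutation) sweeps,
  which is why it is not the default.
* ceil(r*|Hc|) uses the ceiling; the frequency-scorability filter is
  derived frequency in [0.05, 0.95]; SD uses the n-1 convention.
* Standardization uses 50 equal-width frequency bins on (0, 1); bins
  with < 20 finite scores merge into their smaller adjacent neighbour
  until all are usable.  A zero-variance bin is an error.
* uRiHS is mathematically >= 0 when cluster EHH dominates class EHH at
  every marker.  Because neighbours are selected on the whole L-window,
  the cluster's EHH can dip marginally below the class's immediately next
  to the core; in neutral coalescent data ~1% of sites show negatives,
  all tiny (> -0.05).  Values are left unclamped — standardization makes
  the choice immaterial.
* nSL replaces genetic distance by SNP counts: the class score is the
  mean pairwise identity length in SNPs around the core (500-SNP cap per
  side, the selscan `--max-extend-nsl 500` semantics), log-ratioed and
  standardized like iHSL.  iHS here is iHSL at r = 1 with the same L
  cap, not an external implementation.

## Sweep-type classification

Significant sites are classified neutral / hard / soft by majority vote
among the k = 200 nearest points (Euclidean distance in the standardized
(iHSL, RiHS) plane, where both axes are already z-scores; majority ties
fall back to the single nearest point) in a simulated reference built
under a matching demographic model.  The reference draws hard and soft
sweep parameters from the priors 2*Ne_ref*s ~ U(50, 1000) with Ne_ref =
10,000 (the "selection intensity" read as the msms-style scaled 2Ns),
onset ~ U(0, 2000) generations, soft-sweep standing frequency f0 ~
U(0.01, 0.2); replicates are retained when the sampled adaptive-allele
frequency lies in (0.05, 0.95), hard sweeps when exactly one founder
lineage survives, soft sweeps when at least two do.

Soft-shoulder correction: a significant SNP (p < 0.001 on RiHSL) is a
*core* SNP when at least 20% of the 50 SNPs on each side (edge-truncated)
are significant; maximal runs of core SNPs with gaps of at most 10
non-core SNPs form sweep regions; the region takes the label of its
most significant SNP, and hard/soft calls of member SNPs are overwritten
by the region label.  The window, proportion, gap and significance
defaults are package choices (the procedure's shape, not its constants,
is prescribed); all are configurable.

## Simulation machinery

Neutral segments come from msprime (binary mutation model, continuous
coordinates, ancestral allele = 0), 2 Mb at mu = 2.5e-8 and rec =
1.25e-8 per bp per generation by default.  Demographic presets:
equilibrium Ne = 10,000; exponential growth 1,000 -> 20,000 over the last
1,000 generations (0.3%/generation); mild / severe bottlenecks (Ne halved
/ to 0.1x between 300 and 350 generations ago — the 50-generation variant;
a 400-generation variant is exposed as a parameter); and a three-population
out-of-Africa model (African / European / East Asian with an ancestral
expansion, out-of-Africa bottleneck, Eurasian split with exponential
growth; parameters in `src/sweepscan/data/ooa_model.json`), sampled at
216 / 198 / 206 haplotypes for YRI / CEU / CHB.

Sweeps are generated in three conditioned stages:

1. **Trajectory.**  The beneficial-allele count follows per-generation
   Wright-Fisher binomial sampling with additive (genic) fitness
   (1, 1+s/2, 1+s) at the full population size, forward from onset.
   Modes: hard = single origin at onset; SGV = standing allele at
   frequency f0 at onset; SRM = recurrent origins at rate theta_b/(4*Ne)
   per copy per generation.  Trajectories are rejection-sampled until the
   present-day frequency lands in the requested window; when a grid
   specifies an onset *range*, each attempt redraws the onset uniformly,
   which realizes the usual benchmark design of varying the onset while
   conditioning on the realized present-day frequency.
2. **Rescaling.**  The trajectory is thinned to a population rescaled by
   Q (default 10): sizes /Q (capped at 3,000 haplotypes — drift in
   larger epochs is negligible on sweep time scales), durations /Q,
   per-generation rates xQ.  Recurrent-origin events are thinned
   binomially by 1/Q, preserving the expected number of origin events
   per scaled generation.
3. **Forward haplotypes.**  An explicit haplotype population, initialized
   from an msprime sample drawn at the onset time (for SGV the standing
   variant nearest the segment centre with the prescribed count is
   promoted to beneficial, which is exactly a neutrally-arisen allele
   observed at f0), is driven forward by the prescribed carrier counts:
   carrier children copy the selected-site segment from a carrier parent,
   the partner chromosome is uniform over the population, crossovers are
   Poisson along the segment with the selected site pinned to the first
   parent, and new neutral mutations enter as fresh columns.  Founder
   identities ride with the selected-site copy, so the founder-lineage
   count of the sample (the quantity the hard/soft retention filters act
   on) is read off directly.

This engine is a desk-scale alternative to a structured-coalescent sweep
simulator: it reproduces trajectory-conditioned haplotype structure and
founder-lineage bookkeeping at a cost that scales with Q, at the price of
coarsening lineage granularity by the same factor.  A built-in check
(tests) verifies that Q = 10 and Q = 5 give statistically
indistinguishable mean raw iHSL at the sweep site.

### What the generator does and does not emulate

It emulates: frequency-conditioned incomplete sweeps, founder-lineage
structure of SGV/SRM soft sweeps, background diversity at the correct
theta and rho, demographic size histories, and recombination-driven decay
of sweep haplotypes.  It does not emulate: gene conversion, mutation-rate
or recombination-rate heterogeneity along the segment, genotyping or
phasing error, or ancestral-state misidentification.  Tests passing on
this generator therefore certify the statistics' behaviour under the
model's own assumptions, not robustness to those artefacts.

## Benchmark procedures and desk scales

All benchmark sizes below are package defaults chosen to make the full
study reproducible on a single workstation core; each is a scaled-down
version of the corresponding full-scale design (which used thousands of
replicates per cell and 100,000 reference points per class).

* **Neutral calibration** — 100+ neutral 2 Mb equilibrium segments with
  1,000 haplotypes, several well-separated focal sites per segment,
  self-standardized; checks the one-tailed 1% exceedance and the
  chi-square(2) fit of RiHSL (KS distance).
* **Robustness FPR study** (`evaluate.neutral_fpr_study`, also what
  `scripts/acceptance.py` runs) — standardization fitted on baseline-rate
  neutral segments, then applied to conditions with recombination 0.2-0.9x
  and mutation 1.2-3x baseline (18 conditions, default 10 replicates x 4
  sites each); reports per-condition and mean FPR at 2.3263.  The raw
  uiHSL distribution is left-skewed (as for classic iHS), so the
  one-tailed rate runs slightly below the nominal 1%.
* **Power comparison** (`evaluate.sweep_power_study`) — SRM theta = 50
  and SGV f0 = 0.2 grids over s in {0.01, 0.02, 0.05}, onsets drawn from
  100-2,000 generations conditioned on a present-day frequency in
  (0.25, 0.85), grouped into the six standard frequency bins; power per
  (s, bin) cell at each statistic's 1% threshold, mean over the grid.
  Desk default: 1 Mb segments (long enough that the 400-SNP windows
  rarely hit segment edges even under diversity-depleting sweeps),
  ~20-34 replicates per s, 1,000 haplotypes.
* **Classification** — references at 500 points/class (YRI) with
  Q = 20 and 200 kb segments; held-out sweeps classified at p < 0.01;
  accuracy = mean diagonal of the confusion matrix.  Cross-demography
  robustness classifies one population's held-out points against another
  population's reference, holding the test set fixed so the comparison
  is paired.
* **Soft shoulder** — a strong recent hard sweep under the CHB-like
  model on an extended segment; all sites scored, significant sites
  classified, core SNPs and regions called, and flanking soft calls
  revised to the leading SNP's hard label.

## Known limitations

* Rescaling (Q) coarsens founder-lineage granularity; Q = 20 (used for
  reference building) halves resolution relative to the Q = 10 default.
  A consequence visible in the simulated reference distributions: both
  sweep types sit *below* the neutral band on the standardized RiHS axis
  (hard well below, soft mildly below), i.e. the soft-sweep cluster
  excess manifests here as "less depressed than hard" rather than
  "elevated above neutral".  Hard/soft separation on the (iHSL, RiHS)
  plane survives, but is narrower than a full-scale structured-coalescent
  reference would give, which caps desk-scale classification accuracy.
* Detection power for extremely soft recurrent-mutation sweeps
  (theta_b = 50) is sensitive to the engine's lineage-size distribution;
  the rescaled forward simulator produces many near-balanced small
  founder lineages at these rates, on which the cluster statistic fires
  less often than the full-scale study reports.
* iHS is the r = 1 special case with the same L = 400 cap, not an
  external scan implementation; published iHS pipelines that skip sites
  whose EHH never falls below the cutoff inside the segment will report
  lower soft/hard-sweep power than this capped variant.
* The out-of-Africa preset's parameter values follow the canonical
  three-population model; population labels are nominal for simulation
  purposes and no real genotype data is consumed anywhere.
* Very high recurrent-mutation rates (theta_b = 50) push many origin
  events into each scaled generation; the binomial thinning preserves
  rates in expectation but not the exact origin-time spacing.
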