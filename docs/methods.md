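# Methods

`euscan` re-implements, as a tested pipeline, a genome-scan analysis for a
pair of incipient orchid-bee lineages (*Euglossa dilemma*, with a northern
and a southern population, and *E. viridissima*): windowed differentiation
statistics with a net-interspecific-differentiation outlier scan,
composite-likelihood selective-sweep detection with simulation-calibrated
significance, demographic model selection on the joint allele-frequency
spectrum, gene-level selection tests, and perfume-chemistry dissimilarity
statistics.  Everything is exercisable on synthetic data from a built-in
haplodiploid simulator; no external data are required.

## The haplodiploid forward simulator (`synthsim`)

Males are haploid and develop from unfertilised eggs: a male receives a
single recombined maternal gamete.  Females are diploid: a recombined
maternal gamete plus the paternal haplotype, which is transmitted without
recombination because males are haploid.  Mutation is infinite-sites
(continuous positions internally, integerised on output; the per-gamete
mutation count is Poisson(mu L)).  Recombination occurs only in female
meiosis, with Poisson(rec L) crossovers per gamete.  A sweep allele has
multiplicative fitness: hemizygous males 1+s, heterozygous females 1+hs,
homozygous females 1+s.  Population splits resample founders from the
parent population; migration replaces a Binomial(N, m) fraction of each
population with copies of individuals from the partner population each
generation.

The pairwise coalescent time for two random gene copies in this system is
2 Ne_hd generations with Ne_hd = 9 Nm Nf / (4 Nm + 2 Nf) (the classic
X-linked effective size), so equilibrium diversity is pi = 4 Ne_hd mu per
bp.  The test-suite verifies this against msprime as an independent oracle
and checks the neutral folded SFS against the 1/i + 1/(n-i) expectation.

**Coalescent initialisation.**  Scenario simulations start the root
population from a neutral msprime coalescent sample at size 2 Ne_hd
(ploidy-1 convention) with recombination at 2/3 of the female rate (the
fraction of time an X-like lineage spends in females), so the forward
phase begins at mutation-drift equilibrium without a burn-in.  The
monomorphic-initialisation + burn-in path remains available and is what
the oracle tests exercise, so the forward dynamics are validated
independently of the initialiser.  The initialiser ignores the small
male/female asymmetries of the stationary haplodiploid state; these decay
within a few generations of forward simulation.

**Scaled study conditions (`ORCHID`).**  Desk-scale censuses cannot match
real bee populations, so the defaults are chosen to preserve the
dimensionless quantities that control every statistic in the pipeline
rather than any absolute rate:

| quantity | scaled value | rationale |
|---|---|---|
| census per population | 250 males + 250 females (Ne_hd = 375) | 2 Ne_hd s = 75 for the planted sweeps: strongly selected, near-deterministic trajectories |
| mutation rate | 2e-6 /bp/gen | pi = 4 Ne_hd mu = 3e-3 /bp, a realistic insect diversity, ~250 SNPs per 50 kb window at n = 10 |
| recombination rate | 1e-6 /bp/meiosis (calibration draws U(7e-7, 1.4e-6)) | sweep footprint (escape scale ~1/(r T_fix)) of tens of kb; population rho/bp ~5e-4 so 50 kb windows average over many genealogies |
| splits | species split 135-155 generations before sampling, intraspecific split 20 | interspecific Fst ~0.15-0.2, intraspecific ~0.03, matching the study system's "low genome-wide differentiation" regime |
| sweep | s = 0.1, h = 0.6, new mutation shortly after the species split | fixes ~20-40 generations before sampling, so the footprint is fresh; dominance 0.6 balances establishment probability against the late-phase sheltering of dominant alleles in heterozygous females |
| samples | 10 haploid males per population | the study design |

The generator emulates equilibrium standing variation, lineage-restricted
hard sweeps, splits and migration.  It does not emulate read-depth noise,
reference bias, linked background selection, or variation in mutation and
recombination rate along the genome — passing tests therefore demonstrate
correctness of the estimators and calibration machinery under the stated
model, not robustness to those real-data complications.

The perfume generator draws each individual as a composition: a
species-specific major compound with Beta-distributed share (means 0.55
and 0.37 for the two species, matching the reported relative abundances of
the two diagnostic compounds), a symmetric-Dirichlet split of the
remainder over shared minor compounds, zero-inflation of minors, and row
renormalisation.

## Window statistics and the outlier scan (`scanstats`)

Per-window statistics over 0-based half-open windows: pi (unbiased
per-site heterozygosity n/(n-1) 2p(1-p), summed and divided by window
length, so monomorphic positions contribute zero), Dxy
(pA(1-pB)+pB(1-pA) summed / length), and Hudson-type Fst as a ratio of
per-site sums 1 - sum(Hw)/sum(Hb) (ratio of averages, which avoids the
instability of averaging per-SNP ratios).  Weir-Cockerham would be a
defensible alternative; Hudson was chosen for its simple haploid form and
estimator transparency.  Windows without usable data return NaN, never 0.

The net interspecific differentiation track z-transforms the
interspecific and intraspecific Fst tracks over all windows with data and
subtracts them; delta pi = pi_Ev - pi_Ed with both *E. dilemma*
populations pooled (matching the interspecific contrast).  Outliers are
windows strictly above the empirical quantile (default 99th); flagged
windows separated by at most 100 kb (two windows) merge into peaks — the
merging gap is a package choice.

The end-to-end recovery check plants a strong fresh sweep in one of 21
independent 20 kb scaffold-windows and requires the scan to flag it (at
the 90th percentile — a top-2 screen, since a 99th-percentile rule can
flag at most the single maximum of 21 windows) with the most Ed-skewed
delta pi; at the desk-scale effective size, window-level genealogy noise
sets the floor on how weak a sweep this combined evidence can recover.

Permutation tests permute individual-to-population assignment preserving
group sizes, with the add-one convention p = (count+1)/(B+1); an
exhaustive mode enumerates all assignments and returns the exact
permutation p (observed assignment included) when the assignment count is
small.  The f4 statistic is the SNP-mean of (pA-pB)(pC-pD) with a
delete-one block jackknife over contiguous SNP blocks.

## Sweep detection (`sweepclr`)

The scan is a SweepFinder/SweeD-family composite likelihood on the folded
SFS.  The hitchhiking model: a lineage at distance d from a sweep of
strength alpha escapes with probability 1 - exp(-alpha d); the
non-escaping lineages coalesce into the single sweeping haplotype, so a
site's ancestral sample behaves as k+1 draws from the background spectrum
— the k escapees plus one lineage whose allele is copied onto all n-k
hitchhikers.  Outcomes that would be monomorphic are excluded and the
class distribution renormalised (`sweep_site_probability`, verified
against exhaustive enumeration of escape configurations).

The composite likelihood combines, per position, (a) the folded class of
each polymorphic site and (b) whether the position is polymorphic at all:
under the sweep model the per-bp polymorphism probability lambda (the
background SNP density) is multiplied by the model's
polymorphism-retention factor phi(alpha d).  The invariant-site term is
essential at desk scale: conditioning on polymorphism alone discards the
local SNP-density crash that carries most of a completed sweep's signal,
and in calibration experiments the polymorphic-only statistic could not
separate planted sweeps from the null maxima.  `include_invariant=False`
recovers the class-only statistic.  CLR(x) = 2 max_alpha
(lnCL - lnCL0), floored at zero; alpha is maximised over a log grid on
[1e-7, 1e-1] with golden-section refinement, and model tables are
evaluated through a dense interpolation grid in u = alpha d for speed.

Significance follows the calibration-by-simulation design: neutral 50 kb
regions are simulated under the fitted demography with recombination
drawn uniformly per region, and each lineage's threshold is the top CLR
value observed across all calibration regions (a quantile option exists
but is off by default).  Backgrounds are the folded spectra pooled over
the calibration regions.  Regions are classified from per-lineage
significance: "Ed-specific" (both *E. dilemma* lineages significant,
*E. viridissima* not), "Ev-specific", "shared", or "none"; partial
patterns (one *Ed* lineage only) are "none".  For localization the
pipeline takes the argmax of the pointwise minimum of the two *Ed*
lineages' CLR curves — the sweep is shared by both lineages, so requiring
consensus suppresses single-lineage noise peaks.  Classification is
evaluated in the 50 kb window centred on that peak, mirroring the
original workflow (outlier windows are 50 kb, and the calibration regions
are 50 kb), and keeping the calibration and test statistics at matched
region length; length-mismatched thresholds are dominated by the extreme
of whichever side scans more positions.

## Demographic inference (`demofit`)

The model space is 6 topologies x 16 gene-flow configurations = 96
models.  A topology picks the first-diverging population (3 ways) and
which sister population's size parameter continues through the internal
branch between the splits (2 ways) — the latter is the "budding
speciation" ambiguity: a daughter species arising from within a
persistent species shares the persistent lineage's size.  Gene flow is
any subset of four bidirectional vertices: three between the terminal
population pairs (active while all terminals coexist) and one between the
two lineages extant between the splits.  Every model has sizes n1-n3
(relative to the ancestral size of 1, bounds [0.001, 100]), split times
t1 >= t2 (units of N_ref generations in the ploidy-1 coalescent
convention, bounds [0, 10]), and migration rates per lineage per time
unit (bounds [0, 20]): 5 to 9 free parameters.

The expected joint AFS is a Monte-Carlo estimate: unlinked genealogies
simulated with msprime and accumulated in branch-length mode, normalised
over polymorphic entries (the all-ancestral and all-derived corners are
masked).  The likelihood is the multinomial composite likelihood
sum(obs ln p), which profiles out the overall scale theta.  Fitting uses
Nelder-Mead on transformed parameters (log sizes, log t1, logit t2/t1,
log migration; bounds enforced by clipping), from several screened random
starts, with a fixed Monte-Carlo seed per restart so each objective is
deterministic (common random numbers).  An explicit initial simplex with
0.6-unit steps is supplied because scipy's default simplex degenerates at
zero coordinates.  After optimisation the best parameters are
re-evaluated five times at high Monte-Carlo precision and the mean of
those replicate estimates gives the reported log-likelihood and AIC;
fitting all candidate models with the same seed makes the replicate seeds
common across models, so comparison noise largely cancels.  Model
selection reports delta-AIC and Akaike weights.

## Gene-level selection tests (`seltests`)

A variable site is *fixed* when the two species are each monomorphic for
different bases and *polymorphic* when a minor allele is carried by more
than one individual within a species (within-species singletons are
ignored; the singleton rule is applied per species sample).  Synonymy is
decided by swapping the alternate base into its codon with the other
positions at species consensus.  The McDonald-Kreitman test is a
four-field Fisher's exact test (two-sided, verified against full
hypergeometric enumeration).  Branch dN/dS counts only fixed
inter-species differences, polarised against the outgroup consensus by
parsimony (sites where the outgroup matches neither base remain
unassigned and are reported); potential site counts are Nei-Gojobori
equal-weight counts on the ancestral sequence, with pathway averaging for
multi-difference codons and changes to stops counted as non-synonymous.
No maximum-likelihood codon model is attempted, so likelihood-ratio
statistics from such models are out of scope.

## Perfume statistics (`chemoprofile`)

The filter cascade zeroes peaks below 1% of each individual's largest
peak, drops individuals with fewer than 10 compounds, drops compounds
seen in fewer than 3 individuals, then renormalises rows (the 1% rule is
applied per individual).  Bray-Curtis dissimilarity feeds ANOSIM
(Clarke's R with mid-rank ties and denominator M/2, the vegan-compatible
convention; permutation p with the add-one convention, or exact
enumeration for small designs — the R statistic is cross-checked against
scikit-bio in the test-suite) and SIMPER (per-compound share of the mean
between-group dissimilarity, summing to 100%).  The electrophysiology
helper converts spike counts in the 0.5 s windows before/after stimulus
onset to a corrected rate (post - pre) x 2.

## Numerical and degenerate-input conventions

* "No data" is NaN (never silently 0); windows with sum(Hb)=0 have no
  defined Fst.
* Permutation and ANOSIM p-values use (count+1)/(B+1) for Monte-Carlo
  permutations and exact count/total for exhaustive enumeration;
  ties count as exceedances (>= with a 1e-12 tolerance).
* The sweep model's class probabilities are floored at 1e-300 in log
  space; escape probabilities at 1e-12; the polymorphism-retention factor
  at 1e-12 inside logs.
* z-transformed tracks raise on (numerically) constant input rather than
  emitting infinities.
* Optimisation and simulation randomness is fully seed-determined;
  repeated calls with one seed are byte-identical.

## Problem sizes used by the test-suite and acceptance analyses

Simulated regions are 50-200 kb; sweep power and false-positive rates use
20 replicates against thresholds from 50 calibration regions; the
forward-vs-coalescent diversity comparison uses 200 replicate regions;
demographic model recovery fits six candidate models to spectra of
50,000-60,000 unlinked sites with five optimizer restarts each.  These
sizes keep every analysis reproducible in minutes on one CPU while
leaving the statistical margins (3 standard errors, chi-square p > 0.01,
>= 70-80% power criteria) meaningful.

## Known limitations

* The scan's invariant-site term assumes a uniform background SNP density;
  real genomes violate this through rate variation, and the calibration
  absorbs only as much of that as the simulated demography reproduces.
* The composite likelihoods (CLR scan and joint-AFS fits) ignore linkage
  between sites; p-values and information estimates are therefore
  calibrated rather than exact.
* The counting dN/dS has no correction for multiple hits along a branch
  and is intended for closely related lineages.
* The simulator's migration model is a simple per-generation fraction
  replacement; long-distance or sex-biased dispersal is not modelled.
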