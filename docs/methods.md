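# Methods

hzkit delimits hybrid zones from SNP genotype data: it estimates per-individual
ancestry between two parental gene pools, reduces sample coordinates to a 1D
transect, fits geographic cline models to nuclear ancestry and mitochondrial
haplogroup frequency, classifies hybrid individuals from diagnostic markers,
and compares the fitted cline width with the neutral-diffusion expectation.
This note records the models, their assumptions, the defaults, and the design
choices made where the design was genuinely open.

## Cline model

The trait expectation along the transect is a central sigmoid with optional
exponential introgression tails and an affine trait-interval rescaling:

    g(x) = 1 / (1 + exp(-4 (x - c) / w))
    p(x) = p_min + (p_max - p_min) f(x)

`c` is the cline centre (km), `w` the width — the inverse of the maximum
slope, i.e. the distance over which the central sigmoid makes most of its
transition. Tails start `delta` km from the centre and decay exponentially
with a slope ratio `tau` in [0, 1] relative to the sigmoid at the junction:

    left  (x < c - delta_L):  f(x) = g_L exp( tau_L (4/w)(1 - g_L)(x - x_L) )
    right (x > c + delta_R):  f(x) = 1 - (1 - g_R) exp( -tau_R (4/w) g_R (x - x_R) )

with `g_L = g(c - delta_L)`, `g_R = g(c + delta_R)` and `x_L`, `x_R` the
junction positions. The curve is continuous at both junctions for every valid
parameter set, and `tau = 1` continues the sigmoid's log-scale slope exactly,
so the no-tail model is nested smoothly in the tailed ones. The widely used
cline-fitting literature states this family in several algebraically
different but equivalent-in-spirit forms; the parameterisation above is this
package's concrete definition, and numerical equality with any particular R
implementation is not claimed — correctness is established by continuity and
slope checks, brute-force likelihood oracles, and simulation-recovery
studies instead.

Fifteen model variants arise from three trait-interval scalings crossed with
five tail modes, plus a null model with no cline (a constant trait level):

* scalings — `fixed01` (p_min = 0, p_max = 1), `observed` (pinned to the
  extreme locality-mean traits), `free` (both estimated, ordered);
* tails — `none`, `left`, `right`, `mirror` (one shared delta/tau pair on
  both sides), `both` (two independent pairs).

Free-parameter counts: centre and width always; +2 for free scaling; +2 per
independent tail side (mirror counts once); +1 for the Gaussian residual SD;
null has a single level parameter (+1 Gaussian SD).

**Localities for the `observed` scaling.** The data carry no locality
labels, so localities are defined by binning transect positions at 10 km
(configurable). `p_min`/`p_max` are the minimum/maximum bin-mean traits,
clipped to [0, 1]. This is a deliberate concrete choice for a convention the
underlying method leaves open.

## Likelihoods

Individuals are the likelihood unit. Binary traits (mtDNA haplogroup
membership) use a Bernoulli likelihood with p(x) clamped to
[1e-9, 1 - 1e-9]. Continuous ancestry proportions use an independent
Gaussian likelihood with a free residual-SD nuisance parameter (counted in
k), floored at 1e-4 so that data lying exactly on the curve cannot drive the
likelihood to infinity. A locality-binned analysis can be emulated by
aggregating the input; the default is individual-level.

## Fitting, intervals, selection

Each model is fitted by Metropolis–Hastings MCMC with componentwise Gaussian
proposals (default 100,000 iterations, 10% burn-in). Proposal scales start
at a tenth of each prior range and are multiplicatively adapted every 100
burn-in iterations toward an acceptance rate in [0.2, 0.4], then frozen, so
the post-burn-in chain is a valid fixed-kernel sampler. Priors are uniform:
centre over the data range widened by one span on each side, width over
(0, 2 span], tail offsets over [0, span], tau over [0, 1], trait bounds over
[0, 1] with p_min <= p_max enforced through the joint support, residual SD
over [1e-4, 1]. Initial states are drawn from the prior until the likelihood
is finite (50 attempts, then a fit error).

The maximum-likelihood point is the best post-burn-in draw refined by
Nelder–Mead inside the prior box; 95% credible intervals for centre and
width are the 2.5/97.5 percentiles of the post-burn-in draws (widened, if
necessary, to bracket the refined MLE). The credible cline envelope is the
pointwise min/max of p(x) on a 200-point grid over draws whose log-likelihood
is within 2 units of the best; for tractability the envelope set is thinned
with a uniform stride to at most 5,000 draws. Widths and centres are
reported at 0.1 km resolution.

Models are compared by AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1); the minimum
wins, ties broken by smaller k and then enumeration order. Models with
n <= k + 1 are excluded with a warning. A negative control is part of the
acceptance suite: on flat Bernoulli(0.4) traits the null model is expected
to win against all 15 cline variants.

## Ancestry (q-value) estimation

The admixture proportion q of each individual is estimated by a supervised
two-pool likelihood: with parental alternate-allele frequencies f_A, f_B
(clamped to [1e-6, 1 - 1e-6]) the genotype g at a locus is
Binomial(2, q f_B + (1-q) f_A), allele copies independent; q maximises the
summed log-likelihood over [0, 1] by bounded search (|dq| < 1e-6), missing
genotypes skipped. This replaces an unsupervised Bayesian clustering run at
K = 2: the pipeline's cline input is per-individual q on a two-cluster
sub-dataset where parental references exist, which makes the supervised
estimator appropriate, deterministic and fast. Numerical equality with any
particular clustering program is not claimed. A flat-likelihood flag marks
individuals whose likelihood varies by < 1e-9 across a grid on [0, 1]
(no usable loci, or f_A = f_B everywhere).

Parental reference pools are designated by strict q thresholds (q > 0.98
parental, q > 0.90 "pure" for sub-dataset construction — both exposed,
defaulting per stage as above), and pool frequencies are computed from the
designated parentals with a 0.5 pseudo-count per allele class so that
non-diagnostic loci avoid exact 0/1. The pipeline runs two passes: a first q
estimate from the metadata population labels, then a re-estimate from the
strictly designated parentals.

## Variant filters and diagnostic markers

Filters mirror a Stacks *populations*-style pass, in order: minor allele
count >= 3 (counted across all genotyped samples); observed heterozygosity
<= 0.5 (higher values suggest paralog collapse); genotyped in >= 80% of the
samples of at least p populations; optionally one random SNP per parent
locus (seeded; loci ordered lexicographically before sampling, so the
selection is platform-stable). Missing genotypes are excluded from every
numerator and denominator; nothing is imputed.

Per-locus differentiation is the Weir & Cockerham (1984) theta for two
populations, clamped to [0, 1] for selection purposes; loci with fewer than
two genotyped samples in either group are undefined. Diagnostic
(ancestry-informative) loci are those with parental frequencies exactly 0
and 1 (either orientation) and at least `min_n` genotyped samples per side —
the FST = 1 rule. With fully diagnostic codominant markers the
maximum-likelihood hybrid index reduces exactly to the allele-count
proportion, so the closed form is used.

## Hybrid classification

h = proportion of parent-B alleles and H = heterozygous fraction over
genotyped diagnostic loci. Classes follow the standard triangle-plot rules:
h exactly 0 or 1 is pure (exact, because only fixed-difference loci are
used); 0.25 < h < 0.75 with H >= 0.5 is a recent-generation hybrid and with
H < 0.5 a later-generation hybrid; h in (0, 0.25] or [0.75, 1) is a
backcross. Boundary semantics are strict for the intermediate range and
inclusive at 0.25/0.75 for backcrosses. An F1-consistency flag marks
h = 0.5 with H = 1 exactly. Individuals genotyped at fewer than 3 diagnostic
loci (configurable) are left unclassified.

## Transect geometry

Longitude/latitude are converted to planar km by a local equirectangular
projection about the baseline's mean latitude (x = R cos(phi0) dlambda,
y = R dphi, R = 6371 km); over transects of a few hundred km the projection
error is orders of magnitude below cline-width credible intervals, and this
avoids a projection-library dependency. The transect position is the minimum
Euclidean distance to the baseline polyline, signed by a cross-product test
against the nearest segment; when the nearest point is a shared vertex of
two equidistant segments the sign comes from the angle-bisector normal. The
declared positive side points toward the gene pool the cline approaches at
+infinity, so fitted clines are increasing.

The preferred baseline is user-supplied (reproducibility). When none is
given, the centre line is estimated by fitting logit(q) = a + b east +
c north by maximum likelihood and returning the q = 0.5 straight-line
contour clipped to the sample bounding box — a deliberately simple,
documented substitute for spatial-ancestry surface methods; it raises an
estimation error when both gradient coefficients are below 1e-8.

## Neutral diffusion

Without selection a cline widens as w = 2.51 sigma sqrt(T) (sigma = average
lifetime dispersal in km/generation, T generations since contact). The
inversion T = (w / 2.51 sigma)^2 gives the time unrestricted diffusion needs
to reach an observed width; years are reported raw and rounded half-up,
which reproduces the published worked examples for this system (677, 6,144,
20,490 and 22,619 years at sigma = 0.26 km/yr x 3 yr = 0.78 km/generation).
An observed width far below the expectation for any plausible contact age
indicates selection against hybrids — a tension zone.

## Synthetic data generator

`synth.simulate_zone` emulates the structure the analysis assumes:
individuals uniform on a +/-150 km transect crossing a straight north-south
baseline; true ancestry following a known 30-km sigmoid cline; 40 diagnostic
loci (fixed differences) plus 400 background loci whose pool frequencies are
drawn independently from Beta(2, 2); genotypes Binomial(2, mixed frequency);
a binary haplogroup following its own (optionally centre-offset) cline; 10%
of genotypes missing completely at random. Defaults mirror the scale of the
motivating field system (sub-datasets of tens of individuals and hundreds of
SNPs; 40 diagnostic loci in the sharpest contact zone). Positions are
uniform because opportunistic field sampling is unmodellable and uniform
coverage maximises cline identifiability; loci are unlinked (sparse
genome-wide reduced-representation markers); missingness is completely at
random because the completeness filters are exercised downstream, not here.

`synth.simulate_pedigree` produces P1/P2/F1/F2 and first/second backcross
classes at diagnostic loci by explicit gamete draws under free
recombination, giving the textbook expectations (F1: h = 0.5, H = 1; BC1:
h = 0.25 or 0.75, E[H] = 0.5; BC2: h = 0.125 or 0.875, E[H] = 0.25).

**What passing tests do and do not show.** The generator draws genotypes
independently across loci given ancestry, with no linkage disequilibrium,
no selection against hybrids, no coalescent structure within pools, and
missingness unrelated to genotype quality. Tests passing on this synthetic
structure validate the estimators under the model they assume; they do not
demonstrate robustness to LD between markers, related individuals,
genotyping error, or informative missingness in real reduced-representation
data.

## Study sizes used by the acceptance suite

The simulation studies run at sizes chosen to give decisive statistics on a
single CPU:

* width-CI coverage: 20 zones, n = 150, true width 30 km, Bernoulli trait,
  full 100,000-iteration chains (the study consumes posterior quantiles);
* flat-trait negative control: 20 replicates, n = 100, all 16 models at
  10,000 iterations — AICc model selection uses the locally refined MLE,
  which short chains locate reliably;
* tail recovery: 20 replicates, n = 400, 30,000 iterations, two models.

The tail-recovery study fixes the tail at delta_R = 40 km, tau_R = 0.3 and
n = 400; the remaining design knobs were set by a power analysis over core
width and transect span *before* the study was frozen: with w = 30 km the
junction sits at g ~ 0.995 and the tail contributes ~0.2 expected
observations per replicate (the study would measure nothing), whereas
w = 90 km on a +/-300 km transect puts the junction at g ~ 0.86 with the
tail observable over 260 km. The frozen design is therefore w = 90 km,
halfspan 300 km.

## Known limitations

* The supervised q estimator conditions on parental reference frequencies;
  uncertainty in those frequencies is not propagated.
* The equirectangular projection is inappropriate for transects spanning
  many degrees of latitude or near the poles.
* The credible envelope thins the within-2-log-units sample set (uniform
  stride, cap 5,000) rather than using every draw.
* Cline concordance/coincidence tests across traits, genomic clines and
  per-locus introgression outliers are out of scope.
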