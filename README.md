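# hzkit

Hybrid-zone delimitation from SNP genotype data.

When two differentiated populations meet and interbreed, the geography of
their admixture carries a signal about reproductive isolation: old, selected
boundaries stay narrow, while freely admixing lineages blur over hundreds of
kilometres. hzkit implements the analysis chain that turns a SNP genotype
matrix and sample coordinates into that signal, for two-population contact
zones such as those between parapatric amphibian lineages:

* **Variant filtering** in the style of a Stacks *populations* pass
  (minor-allele count, observed heterozygosity, per-population completeness,
  one random SNP per locus).
* **Supervised ancestry**: each individual's admixture proportion
  *q* between two parental gene pools, by maximising the binomial genotype
  likelihood Π_l Binom(g_l; 2, q f_B + (1−q) f_A) over q ∈ [0, 1].
* **Diagnostic markers**: per-locus Weir–Cockerham F_ST and selection of
  ancestry-informative loci fixed between the parental pools (F_ST = 1).
* **Hybrid classification** from the hybrid index
  h = (# parent-B alleles) / (2 × loci) and interclass heterozygosity H:
  pure (h = 0 or 1), recent-generation (0.25 < h < 0.75, H ≥ 0.5),
  later-generation (0.25 < h < 0.75, H < 0.5), backcross (h ≤ 0.25 or ≥ 0.75).
* **Transect geometry**: signed minimum distances from a baseline polyline
  through the zone centre (or a baseline estimated from the ancestry surface).
* **Geographic clines**: p(x) = p_min + (p_max − p_min) f(x) with a central
  sigmoid f of width *w* and centre *c* plus optional exponential
  introgression tails; 15 model variants (3 trait-interval scalings × 5 tail
  modes) plus a null model, fitted by Metropolis–Hastings MCMC (100,000
  iterations, 10% burn-in) and compared by
  AICc = −2 lnL + 2k + 2k(k+1)/(n−k−1), with 95% credible intervals and a
  credible cline envelope.
* **Neutral diffusion**: the no-selection width expectation
  w = 2.51 σ √T and its inversion T = (w / 2.51 σ)², to ask how long
  unrestricted diffusion would need to produce an observed width.
* **Synthetic data**: a generator for hybrid-zone transects (known cline,
  diagnostic + background loci, mtDNA haplogroup cline, missingness) and
  explicit pedigree classes (F1, F2, backcrosses) with truth tables.

See `docs/methods.md` for the models, priors, numerical choices and
limitations.

## Worked example

Simulate a hybrid zone (150 individuals on a ±150 km transect, true nuclear
cline width 30 km, 40 diagnostic + 400 background loci, 10% missing data)
and run the full pipeline:

```python
import numpy as np
from hzkit.synth import ZoneScenario, simulate_zone, write_zone
from hzkit.geometry import Baseline
from hzkit.genio import FilterPolicy
from hzkit import pipeline

gm, meta, truth = simulate_zone(ZoneScenario(seed=7))
write_zone("zone", gm, meta, truth)
Baseline(np.array([[135.0, 33.0], [135.0, 37.0]]),
         positive_side="right", crs="lonlat").to_tsv("zone/baseline.tsv")

config = pipeline.RunConfig(
    genotypes="zone/genotypes.vcf", metadata="zone/samples.tsv",
    baseline="zone/baseline.tsv", outdir="run",
    filter_policy=FilterPolicy(min_mac=3, max_obs_het=0.5,
                               completeness_r=0.8, min_pops_present=2),
    cline_iterations=20_000,
    dispersal_km_per_year=0.26, generation_time_years=3.0, seed=11)
report = pipeline.run(config)
print(open("run/summary.txt").read())
```

which prints (about two minutes on one CPU):

```
hzkit run (config 715fa0402ccf73a7, seed 11)
ancestry cline: model fixed01/none/gaussian, width 27.6 km (95% CI 26.7-28.4), centre 0.1 km
haplogroup cline: model observed/none/bernoulli, width 38.1 km (95% CI 25.4-67.3), centre -0.5 km
hybrid classes: backcross_A=7, backcross_B=8, later_generation=8, pure_A=62, pure_B=62, recent_generation=3
neutral diffusion: 27.6 km reached in 595 years (sigma 0.78 km/gen)
```

Reading the output: AICc selected the plain sigmoid (no tails) for both
traits, as simulated; the fitted nuclear width of 27.6 km brackets the 30-km
truth between the two traits' estimates; most individuals are pure with a
mix of backcrossed and later-generation hybrids near the centre; and a
27.6-km cline needs only ~595 years of neutral diffusion at
σ = 0.26 km/yr × 3 yr = 0.78 km/generation — so a real zone of this width
whose contact is known to be much older than that would have to be kept
narrow by selection against hybrids (a tension zone).

The same stages are available as a CLI (`hzkit synth zone`, `hzkit genio
filter`, `hzkit ancestry`, `hzkit project`, `hzkit cline fit`,
`hzkit classify`, `hzkit diffusion`, `hzkit run --config run.yaml`).

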