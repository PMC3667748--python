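# fourfold

Are synonymous sites neutral? `fourfold` implements a population-genetic
pipeline for detecting **strong purifying selection on four-fold
degenerate (4D) synonymous sites** from deep population samples, using
short introns as the neutral reference. It is aimed at population
geneticists who have per-site polymorphism tables (e.g. from an inbred
reference panel resequencing project) and want to quantify how much
synonymous polymorphism is *missing* and how strong the selection
removing it is.

Strong purifying selection is nearly invisible to classical SFS methods:
it removes variants so efficiently that the few surviving SNPs sit at
very low frequencies, and a shallow sample never sees them. Two ideas
restore the signal:

1. **An extended SFS likelihood.** The folded site-frequency spectrum is
   augmented with its zero-frequency (monomorphic) class, so the
   *density* of polymorphism — not just its shape — enters the
   likelihood. Sites fall into a mixture of selection categories
   (neutral, weak, strong) with fractions `f_c` and scaled selection
   coefficients `γ_c = 4N_e s`. Under mutation–selection balance the
   expected spectrum of a category is

       g(i | γ) = ∫₀¹ θ · (e^{γq} − e^{γ}) / [(1 − e^{γ}) q(1−q)]
                   · C(n,i) qⁱ (1−q)^{n−i} dq,      g(0) = 1 − Σᵢ g(i)

   with `θ = 4N_e μ` anchored by a jointly fitted all-neutral reference
   spectrum. Both spectra contribute multinomial log-likelihoods and the
   five structural parameters `(θ, f_weak, f_strong, γ_weak, γ_strong)`
   are fitted by multi-start Nelder–Mead. An optional per-frequency-class
   modifier `α_x` (shared by both spectra, `α₀ = 1`) absorbs demography
   and other distortions common to test and reference.

2. **A matched bootstrap.** 4D sites are GC-rich relative to short
   introns, and mutation rates vary with base composition and along the
   chromosome. Each 4D site is therefore paired with nearby (<1 kb)
   short-intron sites sharing its major allele; resampling these pairs
   equalises GC content and regional mutation/diversity structure, and
   the deficit `1 − density(4D)/density(introns)` over replicates
   estimates the fraction of synonymous polymorphism removed by
   selection, with the replicate SD as its standard error.

A synthetic-data generator produces site tables with the full structure
the analysis assumes (two site classes with distinct GC, 1-kb regional
diversity covariation, variable per-site call depths, a selection
mixture on 4D sites), so the whole pipeline is testable without any
external data. Stratification utilities reproduce the standard slicing
of such analyses: substitution-rate bins, codon preference and
polarization, genic features, expression tertiles, and a gene ranking
surrogate for extensive constraint.

## Worked example

```python
import numpy as np
from fourfold import (
    GeneratorConfig, generate_sites, filter_and_resample,
    build_pair_index, bootstrap_deficit, paired_spectra, SfsMixtureModel,
)

# synthetic deep population sample: 22.6% of 4D sites under gamma = -283
cfg = GeneratorConfig(n_4d_sites=200_000, n_si_sites=200_000)
sites = filter_and_resample(generate_sites(cfg, seed=1), rng=2)
test = sites[sites.site_class == "4D"]
ref = sites[sites.site_class == "SI"]

# matched bootstrap: how much synonymous polymorphism is missing?
index = build_pair_index(test, ref, mode="major_allele", max_dist=1000)
est = bootstrap_deficit(index, n_boot=10, seed=3)
print(est)

# mixture fit on one replicate's paired spectra
tspec, rspec = paired_spectra(index, n_boot=1, seed=3)[0]
print(SfsMixtureModel(tspec, rspec).fit().summary())
```

Output:

```
BootstrapEstimate(mean_deficit=0.2207, se=0.0108, n_boot=10, n_pairs_drawn=113237, coverage=1.000)
SFS selection-mixture fit
=============================================
sample depth n              130
sites (test / ref)          113237 / 113237
theta (4Ne*mu)              0.0132852
f_neutral                   0.7737
f_weak                      0.0000
f_strong                    0.2263
gamma_weak (4Ne*s)          -4.999
gamma_strong (4Ne*s)        -166.7
missing polymorphism        0.2022
log-likelihood              -106155.3448
alpha correction            no
converged                   True
gamma_strong at limit       False
```

The bootstrap finds ~22% fewer segregating 4D sites than matched
short-intron sites, and the likelihood attributes that deficit to a
strong-selection category holding ~22.6% of sites. At this reduced scale
a single replicate pins the fraction well but estimates the strength `γ`
noisily (here −167 for a generating value of −283); the spread over
bootstrap replicates supplies its standard error, and the study-scale
runs of `scripts/acceptance.py` recover `γ` to within a few percent. The
weak category collapses to zero: there is no detectable weak selection
differentiating 4D sites from introns.

The same pipeline is scriptable from the shell:

```bash
fourfold simulate --out run/ --seed 1
fourfold prepare --sites run/sites.tsv --out run/filtered.tsv --seed 1
fourfold pair --test run/filtered.tsv --ref run/filtered.tsv \
    --out-prefix run/boot --seed 1
fourfold fit --test-sfs run/boot.rep0.test.sfs \
    --ref-sfs run/boot.rep0.ref.sfs --out run/fit.txt
```

## Scope

The package consumes per-site substitution counts and gene-level
attributes (expression, codon-bias metrics) as plain input columns;
phylogenetic inference, GO enrichment, and genotype calling are out of
scope. See `docs/methods.md` for the model, its assumptions, numerical
choices and limitations.
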