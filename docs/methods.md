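# Methods

## Model

Each candidate site is treated as an independent two-state observation:
monomorphic, or polymorphic with a single mutation segregating at some
population frequency `q`. Under mutation–selection balance with scaled
selection coefficient `γ = 4N_e s` (negative = deleterious, acting on the
derived allele) the density of sites with a derived allele at frequency
`q` is the Wright stationary form

    f(q) = θ · (e^{γq} − e^{γ}) / [(1 − e^{γ}) · q(1−q)],

whose `γ → 0` limit is the neutral `θ/q`, with `θ = 4N_e μ` the per-site
scaled mutation rate. The expected fraction of sites carrying a derived
allele count `i` in a sample of `n` chromosomes integrates `f` against
binomial sampling,

    g(i | γ) = ∫₀¹ f(q) · C(n,i) qⁱ (1−q)^{n−i} dq ,  i = 1..n−1,

and the monomorphic ("zero-frequency") class `g(0) = 1 − Σᵢ g(i)` is
appended. Appending `g(0)` is the crucial step: strong selection barely
changes the *shape* of the observed spectrum (the surviving variants are
rare either way) but sharply reduces its *amplitude*, and the zero class
is where that amplitude information lives. Spectra are folded onto
minor-allele counts (`G(j) = g(j) + g(n−j)`, midpoint un-doubled) to
avoid ancestral-state inference.

Test (4D) sites are a mixture of selection categories — neutral
(`γ = 0`), weak (`0 < |γ| < 5`) and strong (`|γ| > 100`, capped at 700) —
with fractions `f_c` summing to one; the reference (short-intron)
spectrum is modelled as all-neutral with the *same* `θ`, anchoring the
mutation rate. Each spectrum contributes a multinomial log-likelihood
`Σ_x k_x log G(x)` over all folded classes including the zero class; the
data-only multinomial constant is dropped everywhere, so only likelihood
differences are meaningful.

The per-category segregating mass defines a retention ratio
`r(γ) = Σᵢ g(i|γ) / Σᵢ g(i|0)` (independent of `θ`); the model-implied
missing-polymorphism fraction of a fitted mixture is `Σ_c f_c (1 − r(γ_c))`,
which is what the matched bootstrap estimates non-parametrically.

### Frequency-class correction (α)

To absorb demography, linked selection, and the binomial-sampling
approximation itself, an optional modifier `α_x` multiplies the
probability of frequency class `x` in **both** spectra, renormalised,
with `α₀ = 1` as anchor. Because the α's are shared, they soak up any
distortion common to test and reference without touching the selection
parameters. At `n = 130` this adds one free parameter per folded
polymorphic class — 65 of them, with the zero class anchored. (If one
counts the zero class among the frequency classes, the same model reads
"65 classes, 64 free modifiers plus the anchor"; the parameterisation
here is the former.)

## Fitting

The five structural parameters `(θ, f_weak, f_strong, γ_weak, γ_strong)`
are fitted by Nelder–Mead on transformed coordinates: `log θ`;
additive-log-ratio coordinates for the fraction simplex; bounded
logistic maps confining `γ_weak` to `(−5, 0)` and `γ_strong` to
`(−γ_limit, −strong_lower)` (defaults 700 and 100). Eight deterministic
starts (a moment-based point — `θ₀` from the reference SNP density over
the harmonic number — a near-neutral point, and seeded Gaussian spreads)
are run to convergence and the best is polished by one simplex restart.
Invalid points (category segregating mass exceeding 1) return `+inf`.
`γ̂_strong` within 1% of `γ_limit` raises a boundary flag: that fit is
indistinguishable from an infinitely strong (or mutational) deficit.

**Weak-category collapse.** As `γ_weak → 0` the weak category becomes
likelihood-equivalent to neutral, leaving `f_weak` unidentified along an
exactly flat ridge; a simplex will report arbitrary mass there. After
the search, the model is therefore refitted with the weak category
emptied (its fraction pinned at zero), and the collapsed model is
adopted unless the full model wins by more than a BIC penalty `ln N`
for its two extra parameters (`N` = total sites). BIC is used rather
than a fixed likelihood-ratio cut because it is a consistent selection
rule at these sample sizes; a 5% LRT cut would by construction retain
spurious weak mass in ~10% of replicates. A fixed cut can be supplied
via `FitConfig.collapse_tol`.

**α profiling.** With the correction enabled, the α vector is not
searched by the simplex. At each structural-parameter point the joint
log-likelihood is concave in α, and the stationarity condition gives the
multiplicative fixed point `α_x ← K_x / Σ_s L_s g_x^{(s)} / Z_s(α)`
(`K_x` = pooled counts in class `x`, `Z_s` = normaliser of spectrum `s`),
iterated to `10⁻¹²` relative change. The outer search thus stays
five-dimensional while the reported fit is the joint MLE (profile
likelihood). Classes with zero pooled counts get `α_x = 0`, their MLE;
the fit is flagged as ill-conditioned in that case only through the
likelihood surface itself. With α absent (or identically 1) the code
path is bitwise identical to the uncorrected model.

Standard errors of the headline quantities are replicate-level: the SD
of estimates across the ten matched-bootstrap replicates, not a Hessian.

## Numerics

The spectrum integral is evaluated by fixed Gauss–Legendre panels on
`(0, 0.02], (0.02, 0.2], (0.2, 1)` with 256 nodes each. The integrand's
only difficult feature is a boundary layer of width `~1/|γ|` at `q = 0`;
the inner panels resolve it for all `|γ| ≤ 700` while keeping the node
set independent of `γ`, so the binomial kernel
`C(n,i) q^{i−1}(1−q)^{n−i−1} w_k` is precomputed once per depth `n` and
every likelihood evaluation is a single matrix–vector product (~0.04 ms
at n = 130). Against a 10⁶-point trapezoid oracle the relative error is
below 10⁻⁶ for all `γ ∈ [−700, 0]` tested (≤6×10⁻⁸ in practice). The
selected shape `(e^{γq} − e^{γ})/(1 − e^{γ})` is evaluated with `expm1`
and underflow suppressed; `|γ| < 10⁻⁵` switches to the exact neutral
limit, making the neutral spectrum `θ/i` exact to machine precision. The
cap `γ_limit = 700` reflects double-precision exponent range: beyond it
the selected spectrum is numerically zero everywhere.

Deterministic spectrum simulation (`noise="none"`) rounds each
polymorphic class to the nearest integer and lets the zero class absorb
the residual so counts sum exactly to `L`; `noise="multinomial"` draws
the classes jointly from a seeded generator.

## Matched bootstrap

Pairing predicates: same chromosome arm, identical major allele (or
identical ordered major-allele triplet in context mode), distance
`≤ 1000 bp` inclusive (`mode="none"` drops the distance predicate only).
Each replicate draws `N` pairs with replacement, `N` = number of
pairable test sites; a test site drawn twice redraws its partner
independently. The deficit `1 − density(test)/density(ref)` is computed
per replicate and averaged, with the replicate SD as SE — matching the
mean ± SE structure of a ten-replicate design. Deficits are never
clamped; negative values (an excess of test polymorphism) are reported
as such. The estimator converges in `N` to `f_strong (1 − r(γ_strong))`
under the generating model.

Because all replicates resample the *same* realised site table, the
estimator also carries table-level noise of roughly
`√(2 / (N · density))` — about 0.8% at the default scale of ~5×10⁵
pairable sites. Assertions and reported SEs in the tests are sized to
this, and the confound-neutralisation check is run at 1.5×10⁶ sites per
class so that a 1% bias bound is a >2σ statement.

## Synthetic data

The generator emulates exactly the structure the analysis relies on, and
nothing more. Genes with two CDS exons (63 codons each; every third
codon position a 4D site) separated by two 85-bp introns (interior
16/6-bp-trimmed positions are the reference sites) tile five chromosome
arms with 400-bp gaps, guaranteeing that essentially every 4D site has
reference partners within 1 kb. Major alleles are drawn to per-class GC
targets (64% / 31%). A lognormal multiplier (unit mean, sd 0.3) constant
within each 1-kb window and shared by co-located sites of both classes
creates the regional diversity covariation the bootstrap exists to
cancel; the sd is a stand-in choice, not an empirical claim. Per-site
called depths are uniform on {100..168} so the depth-130 filter path is
exercised (the binomial-sampling formula is consistent under
subsampling, so generating at the called depth and resampling to 130 is
distributionally identical to generating at 130). Folded minor-allele
counts are drawn from the class-conditional sample SFS: a site
segregates with probability `θ_site · Σᵢ hᵢ(γ)` and its derived count
follows the normalised `hᵢ(γ)` at its own depth. Confound knobs scale
`θ` at A/T-major sites (GC-dependent mutation), replace the strong class
with a zero-mutation class, or apply a shared α distortion to both
classes.

What the generator does **not** emulate: linkage (sites are
independent; real SFS counts are correlated, so real-data SEs are larger
than multinomial ones), demography (only α-style distortions),
finite-sites/multiple hits, context-dependent mutation beyond the
triplet labels, and any realistic gene architecture. Passing tests
demonstrate the estimator's behaviour under the model's own assumptions
plus the stated confounds — not robustness to everything real data can
do.

Codon annotations assign each 4D site an amino acid from the five
four-fold families, an ancestral codon whose third base is the major
allele, preference against the optimal-codon table
(GCC/GGC/CCC/ACC/GTG), a conserved-amino-acid flag (default 70%), and a
substitution count from a zero-inflated gamma whose zero mass and mean
differ by selection class when `subst_correlated` is set (strong: 35%
zeros, mean 2.0; neutral: 10% zeros, mean 4.5) — enough correlation to
exercise the rate-bin and gene-ranking analyses in the qualitative
direction expected, with a switch to sever the correlation for null
checks.

## Stratifications

Substitution-rate bins use fixed boundaries `0 | (0,1.4] | (1.4,1.92] |
(1.92,3.10] | (3.10,4.40] | (4.40,6.20] | (6.20,9.30) | [9.30,∞)`; the
first bin is exactly zero substitutions and 9.30 belongs to the top bin.
Polarization assigns the ancestral allele by parsimony to a single
outgroup with major-allele fallback (sites are never dropped, so SNP
densities are unchanged), or requires a deep-outgroup consensus match
(`ten_species`) and otherwise marks the site unpolarized. Tertile
groupings split ranked genes into thirds differing by at most one, ties
broken by stable gene-identifier order. The gene-ranking surrogate
scores each gene by the fraction of its SNP-free, conserved-amino-acid
4D sites that are unpreferred and fully conserved; genes with under 20%
conserved-amino-acid sites are ineligible, and the top sixth of eligible
genes forms the high-constraint set.

## Problem sizes and study conditions

Defaults are the study conditions throughout: `θ = 0.0132`,
`f_strong = 0.226`, `γ_strong = −283`, `f_weak = 0`, depth 130 of up to
168 chromosomes, 864,000 / 870,000 generated sites per class, GC 64% /
31%. The acceptance script runs ten replicate fits at L = 863,972 sites
per spectrum and one full-table bootstrap. Unit tests use reduced site
counts (3×10⁴–1.5×10⁵) with tolerances widened to the corresponding
Monte-Carlo noise; the discrimination and recovery checks run at the
full L = 8.6×10⁵ since the fit cost is independent of L.

## Known limitations

- `f_weak` is structurally unidentified as `γ_weak → 0`; the BIC
  collapse reports zero weak mass unless the data demand it. A genuinely
  small weak effect below the BIC penalty will be absorbed.
- At shallow depth (n ≈ 60) the likelihood cannot separate strong
  selection from a class-specific mutation deficit: the noiseless
  margin between `γ = −283` and the computable limit is ~2.6
  log-likelihood units (vs ~7.7 at n = 130), so estimates of `γ_strong`
  scatter to the boundary. The depth of the sample is what buys the
  discrimination.
- `γ̂_strong` has heavy replicate-level noise even at n = 130
  (SD ≈ 40–50 across multinomial replicates at study scale); the
  fraction `f_strong` is far better determined than the strength.
- The independence (multinomial) likelihood understates uncertainty on
  linked real data; SEs should come from the bootstrap replicates, as
  implemented, not from likelihood curvature.
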