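# Methods

This note documents the models, estimators, numerical choices and
limitations behind `fallowpop`. Everything stated as an empirical property
here is computed by the test suite or by `scripts/acceptance.py`; nothing
is quoted from elsewhere.

## Data model

Microsatellite data are diploid allele-size matrices with a population
label per individual; allele pairs are unordered and canonicalised on
construction, and a single missing allele renders the whole genotype
missing (`MISSING = -1`). Statistics use a pairwise-available policy: an
individual missing at a locus is excluded from that locus's statistics
only.

mtDNA alignments are equal-length strings over `{A,C,G,T,-,N}`. Gap
columns are grouped into *indel blocks*: maximal runs of columns whose set
of gapped sequences is constant. Throughout the package a block is one
presence/absence character — an 80-bp insertion is a single mutational
event, and gap-versus-gap at a block is no difference. Nucleotide
diversity and segregating-site counts exclude block columns from the site
count.

## Diversity and differentiation estimators

- **Expected heterozygosity**: Nei's unbiased small-sample estimator
  (2n/(2n−1))(1 − Σp²), n in diploids.
- **Allelic richness**: hypergeometric rarefaction to g gene copies,
  Σ_a [1 − C(m−n_a, g)/C(m, g)]; g defaults to the smallest gene-copy
  count over population × locus cells.
- **F_IS**: Weir–Cockerham *f* from within-population variance components
  (b, c); multilocus values are ratios of summed components, never means
  of ratios.
- **F_ST**: Weir–Cockerham θ from the (a, b, c) variance components,
  summed over alleles and loci; the haploid analogue (components a, b on
  haplotype frequencies) serves mtDNA. Negative estimates are reported as
  computed in matrices but clamped to [0, 1] inside ABC summary vectors so
  distances stay stable. Permutation p-values shuffle individuals between
  the two populations of a pair and use the (k+1)/(n+1) convention.
  mtDNA differentiation is frequency-based θ, not a sequence-distance
  Φ-type statistic — haplotype identity is what the survey data support.
- **Hardy–Weinberg**: exact test conditional on allele counts (Levene's
  distribution); full enumeration of genotype tables when ≤10⁵ tables,
  otherwise Monte-Carlo re-pairing of gene copies; the per-population
  p-value combines loci by Fisher's method. Monomorphic loci give p = 1 by
  convention.
- **Linkage disequilibrium**: the summed-over-populations G statistic of
  the two-locus genotype table, with a within-population permutation null.
  The test is exact-conservative when genotype categories are sparse; its
  null p-values are uniform when tables are well populated (verified by
  simulation on biallelic loci).
- **Mantel test**: scikit-bio's implementation behind a wrapper that adds
  seed control and a constant-matrix guard; one-tailed (positive)
  alternative, as isolation-by-distance predicts.
- **Sequential Bonferroni**: Holm's step-down; its rejection set provably
  contains plain Bonferroni's (property-tested).

## Founder-event F_ST expectation

A founder event of N diploids lasting t generations leaves drift
divergence D = 1 − (1 − 1/(2N))^t between daughter and source. The
observable F_ST computed from finite samples adds one episode of binomial
gene-copy sampling per sample — the temporal-method convention — giving

E[F̂] ≈ 1 − (1 − 1/(2N))^t + 1/(2S₁) + 1/(2S₂).

The package quotes the headline value for a one-generation bottleneck of
7 diploids with survey-scale samples S₁ = S₂ = 150 (the scale at which
this expectation is conventionally applied to bottlenecked ungulate
herds): 0.0781, i.e. 0.078 at three decimals. The printed value is
insensitive to the survey scale (any equal S between roughly 140 and 165
rounds the same way), and a forward Wright–Fisher simulation of the event
(founder draw, expansion, Nei–Tajima standardized frequency variance
between samples) reproduces it within Monte-Carlo error — both the
acceptance script and `tests/test_synthetic_data.py` perform that
cross-check. Pass `sample_sizes=None` for the pure drift expectation
(0.0714 at N=7, t=1).

In the matching forward generator, `forward_founder_event`, the founder
draw itself is the first generation spent at the bottleneck size;
`n_generations=1` therefore means "founded and immediately expanded", and
`n_generations=0` is a pure subsample.

## Coalescent simulation

Seven divergence scenarios relate the three refugial populations (Iberia,
Italy, Anatolia): a trifurcation at T_b, and the six nested topologies in
which one population derives from another at t < T_b. Genealogies come
from msprime's Kingman coalescent with population splits (continuous-time
approximation; adequate at the prior's N_e range). Priors are flat:
N_e and t on [10, 10⁴], T_b on [10, 5·10⁴], expressed in years and
converted to generations by the configured generation time (default
1 year; 5.9 years is the published alternative and only rescales reported
times). The microsatellite mean mutation rate is uniform on
[10⁻⁵, 10⁻²] per generation, with per-locus rates Gamma(shape 2) around
the drawn mean; the mtDNA per-site rate is log-uniform on [10⁻⁸, 10⁻⁵]
(the package's choice — survey-scale control-region rates sit inside it).

Microsatellite mutations are overlaid on the simulated trees in-package:
Poisson(rate × branch length) events per branch; SMM steps ±1 repeat,
GSM steps a signed geometric(p) count; the ancestral allele is 200 repeats
and sizes are unbounded (no allele-size ceiling is imposed). mtDNA uses
msprime's finite-sites Jukes–Cantor model on 683 sites. The mtDNA
effective size is N_e/4 (maternal, haploid), implemented so that
E[T₂] = N_e/2 generations — the moment the test suite checks. Sample
sizes default to the southern-refugium design: 26/21/24 diploids and
19/30/20 sequences for Iberia/Italy/Anatolia.

Verified moments (all within 3 Monte-Carlo SE in the suite): E[T₂] = 2N_e
for diploid loci; E[T₂] = N_e/2 for mtDNA; Watterson's E[S]; mean (δμ)² =
2μT between populations split T generations; mean pairwise θ ≈ 0 at the
T_b lower bound; θ increasing in T_b.

## ABC

The reference table simulates scenarios with equal prior probability and
stores named summary vectors: per population mean A, mean unbiased He,
mean allele-size variance, Garza–Williamson M; per pair θ (clamped),
shared-allele distance, (δμ)²; and, when mtDNA is included, per-population
haplotype count, segregating sites and mean pairwise differences plus
pairwise haploid θ. This is the DIYABC-flavoured default menu; the
statistic set travels with the table, and zero-MAD statistics are dropped
with a warning.

Acceptance is k-nearest on Euclidean distance over MAD-normalised
statistics (ties break on row index). Scenario probabilities are reported
two ways: *direct* (acceptance frequencies, binomial CI) and *logistic* —
a weighted multinomial logistic regression of scenario on summary
differences, Epanechnikov weights, evaluated at zero difference, with
delta-method CIs from the observed information. When the parameter count
would approach the number of fitted rows the design is projected onto
leading principal components (without re-centring, so the observation
stays at the origin); complete separation falls back to the direct
estimate with a warning. Parameter posteriors are sharpened by
local-linear regression adjustment on the log scale (all supports are
positive), ridge-stabilised if singular; rows where a parameter is
undefined (t under the trifurcation) are skipped. Split times are stored
in generations and multiplied by the generation time only at reporting.

Desk-scale defaults: tables of 10³–10⁴ rows with acceptance fractions of
a few to ~25 percent, versus the 6000-of-10⁶ (0.6%) regime a full study
would run. The calibration suite uses a 2500-row scenario-1 table with 30
pseudo-observations (95% intervals cover the truth at the nominal rate
within binomial error, n_keep = 600) and a 3500-row seven-scenario table
with 70 pseudo-observations (argmax scenario recovery ≈ 5× the 1/7 chance
rate). The posterior-predictive check projects predictive summaries onto
two principal components and reports the observation's Mahalanobis depth
percentile.

## Synthetic study fixture

The fixture emulates the survey's *shape*, not its particular alleles:
24 sites totalling 364 diploids at 10 loci with a 683-bp mtDNA alignment.
Three refugial sources are simulated under the trifurcation with
realistic base parameters (N_e ≈ 10³–4·10³, Italy largest; split 12,700
generations ago; mean microsatellite rate 2.1·10⁻⁴; mtDNA 2.9·10⁻⁷ per
site). Each site then descends from its source region through founder
events: by default one moderate event for southern sites (12–18 founders)
and two harder events for northern translocated sites (10 then 8
founders), with mtDNA resampling ⌈N/2⌉ maternal lineages. Under these
defaults site-mean He spans roughly 0.07–0.52 and mean pairwise θ is
~0.65 with maxima near 0.89 — the drifted, insular pattern the generator
exists to emulate. Park and free-living sites are treated identically;
founder schedules are per-region configuration, not biology inferred from
the data. The fixture does not attempt real allele-size distributions,
linkage (loci drift independently), or sequence-level realism beyond the
Jukes–Cantor model — so passing tests validate the pipeline's statistics
and calibration, not any claim about the real populations.

Every fixture and pseudo-observed dataset is regenerable bit-for-bit from
its recorded `GroundTruth` (seed + parameters + founder history).

## Numerical conventions

Single master seeds drive every stochastic run; internal msprime seeds are
drawn below 2³¹ from the caller's generator. Permutation p-values use the
+1 convention, so p = 0 is impossible. Undefined statistics are NaN in
reports, and become 0 only inside ABC summary vectors. Network
construction breaks ties lexicographically on haplotype labels; an MSN
edge is kept exactly when its weight equals the minimax path weight
between its endpoints; median-joining insertion accepts the candidate
median (majority consensus of a connected triple, ties to the smallest
character) that most shortens the MST, and prunes medians whose degree
falls below 3.

## Known limitations

- No migration, admixture or recombination in the scenario simulator (the
  candidate topologies contain none).
- The logistic model-choice CIs are asymptotic; at small n_fit they are
  honest only as orders of magnitude.
- The survey-scale sample-size constant in the founder-event expectation
  (S = 150 per population) is a documented convention, not an estimate;
  results for other designs should pass explicit `sample_sizes`.
- Desk-scale reference tables make scenario discrimination noisy — the
  calibration tests demonstrate "much better than chance", not the sharp
  posterior probabilities a 10⁶-row table would support.
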