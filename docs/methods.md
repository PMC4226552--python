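# Methods

## Model

### Band-intensity observation model

For individual *n* at locus *j*, the observed fluorescence intensity
y<sub>nj</sub> ≥ 0 is modelled as a mixture over the latent allele copy number
c ∈ {0, 1, 2}:

    y | c  ~  TruncNormal( c·μ_j , σ_c,j ; y ≥ 0 )

with per-locus single-copy mean μ_j > 0 and class spreads
σ_c,j = κ_c · μ_j. The three relative spreads κ₀ (absent), κ₁ (heterozygote),
κ₂ (homozygote) are shared across loci. The homozygote mean is exactly twice
the heterozygote mean, the geometry that makes AFLPs near-codominant. Sharing
relative spreads across loci (instead of three free spreads per locus) keeps
the mixture identified with ~20 individuals per population and reflects how
peak width scales with peak height on capillary sequencers; it is the one
structural simplification relative to a fully per-locus mixture.

Mixture weights are the inbreeding-adjusted genotype probabilities

    P(c=2) = p² + F_IS·p(1−p),  P(c=1) = 2p(1−p)(1−F_IS),  P(c=0) = (1−p)² + F_IS·p(1−p)

with population-specific F_IS. Genotypes are marginalized analytically at every
likelihood evaluation rather than sampled — lower variance, simpler convergence
behaviour.

### F-model

Population allele frequencies follow the biallelic multinomial-Dirichlet
(Beta) island model around a locus ancestral frequency a_j:

    p_ij ~ Beta( a_j·θ_ij , (1−a_j)·θ_ij ),   θ_ij = (1 − F_ij)/F_ij,
    F_ij = logistic( δ_j·α_j + β_i )

β_i is the population effect (shared across loci), α_j the locus effect
(shared across populations), and δ_j ∈ {0,1} the selection indicator sampled
by reversible jump: δ_j = 0 is the neutral model. γ_j = P(δ_j = 1 | data)
gives posterior odds PO_j = γ_j/(1−γ_j) (reported as infinite when γ_j = 1 at
the retained-sample resolution); PO > 10 is the "strong evidence" outlier
rule, and the sign of the posterior-mean α_j separates positive (α > 0) from
balancing (α < 0) selection.

Priors (the original method papers do not publish theirs; these are weakly
informative and configurable): α_j ~ N(0, 3²) when active; β_i ~ N(−1, 1);
a_j, F_IS,i ~ U(0,1); μ_j half-normal with scale 10× the initialization
median; κ_c half-normal(1). Prior model odds are 10:1 in favour of the
neutral model (configurable), so γ already embodies a multiplicity penalty.

### MCMC

One sweep updates, in order: all p_ij (logit-scale random walk, elementwise
accept), F_IS,i, μ_j (log scale), the three κ_c (log scale, one component of
the cached density matrix recomputed each), a_j (logit), β_i, α_j (random walk
on active loci) and δ_j (reversible-jump toggle; on activation α* is drawn
from its prior, so proposal and prior densities cancel and the acceptance
ratio is the frequency-likelihood ratio times the prior model odds).
Per-(individual, locus) component log-densities and genotype-marginal
log-likelihoods are cached and updated only where proposals are accepted; the
inner loops are numba-compiled.

Proposal scales are tuned during pilot runs toward acceptance rates in
[0.25, 0.45] (multiplicative 1.3 steps). Convergence is asserted by the
acceptance window plus seed-fixed regression tests, not a formal diagnostic.
The default schedule is 20 pilots × 5,000 sweeps, 50,000 burn-in, 50,000
estimation sweeps thinned by 10; `ScanSettings.reduced()` (5 × 1,000; 5,000;
5,000) is the desk-scale schedule used in tests and the acceptance script,
where a 10-population × 300-locus scan takes ~5 minutes on one core.

### Multiple testing

q-values come directly from the posterior probabilities: ranking loci by γ
descending, the q at rank k is the running mean of (1 − γ) — the expected
false-discovery proportion of the top-k list — made monotone. The q ≤ 0.05
set is the FDR-controlled call set used for power/FDR evaluation; the PO > 10
rule is the per-locus evidence threshold.

## Triage of low-F_ST outliers

Categories are assigned in strict precedence: (1) batch artifact if the plate
test (Welch t for 2 plates, one-way ANOVA for more) has p < 0.05; (2)
sex-linked if the female-vs-male Welch t-test on raw intensities has p < 0.05;
(3) low frequency if the pooled band-frequency moment estimate of the allele
frequency is < 0.25; (4) prime balancing candidate if the present-band
intensities are bimodal overall *and* in at least half the populations;
(5) bimodal overall only; (6) uni/multimodal otherwise.

Decisions behind the knobs:

* **Raw intensities (zeros included) in the sex/plate tests** — X-linkage
  shifts both the zero-class weight and the present-band mean, so the
  full-distribution test has the most power; with balanced sexes the raw-mean
  female/male ratio is ≈ 2 for X-linked markers.
* **No multiple-testing correction** at α = 0.05 — a liberal artifact screen
  is conservative for balancing-selection claims.
* **freq_threshold = 0.25** separates the low-frequency class (observed range
  ~0.04–0.21) from the bimodal classes (~0.48–0.85).
* **Bimodality** is a 1- vs 2-component Gaussian mixture comparison on
  above-threshold intensities, decided by small-sample-corrected AIC (n ≈ 20
  per population) plus minor-weight ≥ 0.1 and mean separation ≥ 2 pooled SDs;
  scale-invariant by construction.
* **"Half the populations"** is the per-population bimodality quorum for a
  prime candidate; the qualitative requirement is heterozygotes visible
  *within* populations, and half is a conservative, configurable reading.
* On mixture-shaped (platykurtic) intensities the plate ANOVA is slightly
  conservative (realized type-I ~2–3% at nominal 5%); on its nominal Gaussian
  model both tests calibrate at ~5%. Conservatism here only under-flags
  artifacts, it never inflates the balancing-candidate class.

## SAMOVA and associations

F_CT is the among-group share of the allele-indicator variance in the
standard two-level nested AMOVA (expected mean squares with unequal sizes;
negative component estimates truncated to 0 before forming the ratio).
Exhaustive k = 2 search enumerates all 2^(P−1) − 1 bipartitions via bitmask
subset sums (feasible through P = 21; ties broken by lexicographically
smallest group A); the annealing mode is a seeded single-population-move
search with geometric cooling. No geographic-contiguity constraint is imposed
(classical SAMOVA has one; the analysis reproduced here does not state it).
Population allele counts are derived from model-estimated frequencies as 2N
copies with configurable N when true counts are unavailable. Pairwise locus
associations are Pearson correlations of population frequency vectors with
Holm step-down correction over all pairs; constant vectors are skipped.

## Synthetic data generator

Emulates the survey conditions: 21 populations × 21 diploid individuals ×
500 loci by default (desk-scale stand-in for the study's ~2,000 informative
markers; full size is one config field away), population F_ST targets
linspaced over 0.16–0.44 and F_IS over 0.001–0.043, locus classes 90%
neutral / 5% positive / 2% balancing / 1.5% X-linked / 0.5% batch /
1% low-frequency. Ancestral frequencies are U(0.05, 0.95) (low-frequency:
U(0.02, 0.2); balancing and X-linked: U(0.45, 0.75), since the balancing
signature being emulated is intermediate frequencies with visible
heterozygotes in essentially every population). Locus effects are +2
(positive) and −2 (balancing); the X-linked, batch and low-frequency nuisance
classes also get −2 so they surface, as in the real survey, inside the
low-F_ST outlier list that triage must clean. Intensities use μ scale 1,000
(arbitrary fluorescence units), lognormal locus-to-locus spread (CV 0.25),
relative spreads 0.06/0.15/0.20 for absent/het/hom — chosen so presence
calling has <1% error, matching a clean AFLP assay. Males are hemizygous at
X-linked loci (copies 0/1), giving the ≈2× female/male raw-mean ratio; batch
loci share one primer combination and get a ×1.5 multiplicative shift on half
of the ~96-well plates (plates assigned at random across individuals).

What the generator does **not** emulate: spatial structure
(isolation-by-distance, range-expansion allele surfing), linkage between
loci, missing data, fragment-size homoplasy, and between-run normalization
drift. Passing tests therefore demonstrate correctness of the machinery under
an idealized island model, not robustness to non-equilibrium demography —
under range expansions the scan's false-positive rate is known to be higher
than the island-model calibration suggests.

## Operating characteristics (desk scale)

Computed by `scripts/acceptance.py` and `tests/test_acceptance.py` on
10-population × 300-locus data with the reduced schedule: the fraction of
populations whose posterior-mean F_ST lands within ±0.05 of truth, the
realized FDR of the q ≤ 0.05 set, the fraction of +2-spiked loci in that set,
and the fraction of all-neutral loci reaching PO > 10 (prior-odds
calibration). Power for +2 spikes at 10 populations is intrinsically limited:
a locus's realized between-population variance is itself random, and roughly
a third of spiked loci draw frequency configurations whose differentiation is
not distinguishable from the neutral F_ST distribution — no scan statistic
can recover those. Measured power therefore sits near 0.5–0.7 depending on
the generator seed, while the same runs keep the realized FDR at ~0 and the
null PO > 10 rate at ~0%.

## Numerical details

* Quantiles are type-7 (linear interpolation), the numpy default, everywhere.
* Presence comparison is strict (>); a value exactly at 10% of Q95 is absent.
* Proportions are kept in (10⁻⁶, 1−10⁻⁶) by clipping on the logit scale.
* Pairs of individuals with no co-scored marker contribute nothing to
  diversity; missing intensities are excluded, never imputed.
* Negative AMOVA variance components are truncated at 0 *before* the F_CT
  ratio; an all-zero denominator returns F_CT = 0.
* All stochastic stages consume a single integer seed through
  `numpy.random.default_rng`; identical seeds give bit-identical output
  (generator, scan, annealing).
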