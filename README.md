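# aflpscan

Selection scans on dominant AFLP markers that exploit band intensities.

## The problem

AFLP genome scans score anonymous dominant markers: a band is present if an
individual carries at least one "present" allele, so heterozygotes are normally
indistinguishable from present homozygotes and allele frequencies must be
guessed from band frequencies. But fluorescence peak heights carry more
information — present homozygotes show roughly **twice** the band intensity of
heterozygotes — which makes AFLPs *nearly codominant* and, in particular, makes
the deficit-of-differentiation signature of **balancing selection** detectable
across many populations. `aflpscan` implements the full analysis pipeline of a
continental-scale vole survey of this kind:

1. **Scoring** (`aflpscan.scoring`): a band is present iff its intensity
   exceeds 10% of the marker's 95% intensity quantile; markers are informative
   when their band frequency lies in [0.05, 0.95], with a bimodality rescue for
   near-fixed markers; per-population diversity is the mean pairwise
   band-difference proportion.
2. **F-model scan** (`aflpscan.fmodel`): locus-by-population differentiation is
   decomposed on the logit scale, F_ST(i,j) = logistic(α_j + β_i), with
   population frequencies p_ij ~ Beta(a_j θ_ij, (1−a_j) θ_ij),
   θ_ij = (1−F_ST)/F_ST. A reversible-jump MCMC switches each locus effect α_j
   in or out; the posterior probability γ_j of the with-selection model gives
   posterior odds PO_j = γ_j/(1−γ_j), with PO > 10 ("strong evidence") as the
   outlier rule and q-values from the γ's for FDR control. Intensities enter
   through a truncated Gaussian mixture over latent genotypes with means
   0 / μ_j / 2μ_j, which also makes per-population inbreeding (F_IS) estimable.
   α_j > 0 reads as positive (excess differentiation), α_j < 0 as balancing
   selection (deficit).
3. **Triage** (`aflpscan.triage`): low-F_ST outliers are screened against the
   artifacts that mimic balancing selection — X-linkage (female intensity ≈ 2×
   male), PCR plate batch effects, low allele frequency — leaving prime
   balancing candidates with a heterozygote/homozygote double peak across
   populations.
4. **Geography** (`aflpscan.geo`): locus-by-locus two-group SAMOVA (the
   population bipartition maximizing F_CT, exhaustive or simulated annealing),
   PCA ordinations, and Holm-corrected pairwise correlations of population
   allele frequencies across outlier loci.
5. **Synthetic data** (`aflpscan.simulate`): a seeded generator emulating the
   survey's structure (21 populations × ~21 voles, population-specific F_ST
   0.16–0.44, F_IS 0.001–0.043, intensity peak geometry, X-linked and
   batch-artifact loci) with a complete truth table, so every stage is testable
   without the unpublished raw data.

The study's printed per-population, per-primer and low-F_ST outlier tables are
packaged as fixtures (`aflpscan.load_fixture_tables`).

## Worked example

```sh
python examples/02_selection_scan.py
```

```
78 informative loci scanned; PO > 10.0 = outlier

marker      gamma      PO   q-value   F_ST  call       truth
CCtt4       1.000     inf  0.0000  0.725  positive   positive
CGtt4       1.000     inf  0.0000  0.707  positive   positive
CTaa4       0.975    39.0  0.0083  0.019  balancing  positive
GCta4       0.950    19.0  0.0188  0.029  balancing  balancing
CCac4       0.940    15.7  0.0270  0.606  positive   positive
...
calls: 3 positive, 3 balancing, 72 neutral
```

γ is the posterior probability that the locus needs its own differentiation
level; loci with PO > 10 and high posterior-mean F_ST are positive-selection
candidates, PO > 10 with anomalously low F_ST are balancing candidates. (Note
the third row: a spiked locus whose island-model draw happened to produce
near-identical frequencies everywhere — the scan correctly reports what the
realized frequencies show, a deficit of differentiation.)
`examples/` contains one short script per capability (scoring, scan, triage,
SAMOVA/PCA/correlations, study-table arithmetic); a thin CLI (`aflpscan
simulate|score|scan|triage|geo`) wraps the same functions for shell use.

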