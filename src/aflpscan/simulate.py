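"""Seeded generator of AFLP band-intensity datasets with known truth.

The generator emulates the statistical structure of the continental vole
survey: an island model of 21 populations of ~21 diploid individuals whose
population-specific F_ST spans 0.16-0.44 and F_IS 0.001-0.043; ~biallelic
dominant loci whose population frequencies are Beta-distributed around an
ancestral frequency with precision set by the logit-scale locus x population
F_ST decomposition; and intensities drawn from truncated Gaussians with
homozygote mean twice the heterozygote mean.  Nuisance classes reproduce the
artifacts the triage stage screens for: X-linked loci (males hemizygous, so
female mean intensity is about twice the male mean), plate batch effects
(multiplicative intensity shift of whole PCR plates for one primer
combination), low-frequency loci, and monomorphic/near-fixed loci that the
informative filter must drop.

Every dataset comes with a truth table (class labels, true locus effects,
ancestral and population frequencies, individual copy numbers); identical
seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit, ndtr, ndtri

from .io import IntensityMatrix

#: locus classes in generation order
LOCUS_CLASSES = (
    "neutral",
    "positive",
    "balancing",
    "sex_linked",
    "batch_artifact",
    "low_frequency",
    "monomorphic",
)

#: the study's selective primer-combination names, reused for realistic marker IDs
PRIMER_COMBINATIONS = (
    "ACag", "ACtc", "ACtt", "AGaa", "AGac", "AGtg", "CAat", "CAta", "CCac",
    "CCta", "CCtt", "CGag", "CGtt", "CTaa", "CTag", "CTtg", "GCat", "GCta",
    "GCtc", "GGac", "GGtc",
)
BATCH_PRIMER = "GGtc"  # plate-affected primer combination, as in the study


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset."""

    n_pops: int = 21
    n_ind_per_pop: int = 21
    n_loci: int = 500
    beta_targets: np.ndarray | None = None   # per-population F_ST targets
    f_is_targets: np.ndarray | None = None
    fractions: dict[str, float] = field(
        default_factory=lambda: {
            "neutral": 0.90,
            "positive": 0.05,
            "balancing": 0.02,
            "sex_linked": 0.015,
            "batch_artifact": 0.005,
            "low_frequency": 0.01,
            "monomorphic": 0.0,
        }
    )
    alpha_magnitudes: dict[str, float] = field(
        default_factory=lambda: {"positive": 2.0, "balancing": 2.0}
    )
    mu_scale: float = 1000.0
    mu_cv: float = 0.25               # lognormal spread of per-locus single-copy means
    rel_sigma_abs: float = 0.06
    rel_sigma_het: float = 0.15
    rel_sigma_hom: float = 0.20
    female_male_ratio: float = 2.0
    plate_shift: float = 1.5
    plate_size: int = 96
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 2:
            raise ValueError("need at least 2 populations")
        if self.beta_targets is None:
            self.beta_targets = np.linspace(0.16, 0.44, self.n_pops)
        if self.f_is_targets is None:
            self.f_is_targets = np.linspace(0.001, 0.043, self.n_pops)
        self.beta_targets = np.asarray(self.beta_targets, dtype=float)
        self.f_is_targets = np.asarray(self.f_is_targets, dtype=float)
        if len(self.beta_targets) != self.n_pops or len(self.f_is_targets) != self.n_pops:
            raise ValueError("per-population targets must have length n_pops")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {total}")
        unknown = set(self.fractions) - set(LOCUS_CLASSES)
        if unknown:
            raise ValueError(f"unknown locus classes {sorted(unknown)}")

    def class_counts(self) -> dict[str, int]:
        counts = {c: int(round(self.fractions.get(c, 0.0) * self.n_loci)) for c in LOCUS_CLASSES}
        counts["neutral"] += self.n_loci - sum(counts.values())
        if counts["neutral"] < 0:
            raise ValueError("infeasible class fractions after rounding")
        return counts


def default_study_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Desk-scale stand-in for the study: 21 populations x 21 individuals,
    500 loci, per-population F_ST targets spanning 0.16-0.44 and F_IS
    0.001-0.043, with 90% neutral loci and small spiked nuisance classes."""
    return GeneratorConfig(seed=seed, **overrides)


@dataclass
class TruthTable:
    """Ground truth for a simulated dataset.

    ``loci``: per-locus DataFrame (marker_id, locus_class, alpha, ancestral_freq).
    ``pop_freq``: loci x populations true allele frequencies.
    ``copies``: individuals x loci true allele copy numbers (0/1/2; males carry
    0/1 at X-linked loci).
    """

    loci: pd.DataFrame
    pop_freq: pd.DataFrame
    copies: pd.DataFrame

    def markers_of_class(self, locus_class: str) -> list[str]:
        sel = self.loci["locus_class"] == locus_class
        return self.loci.loc[sel, "marker_id"].tolist()


def _truncated_normal(rng: np.random.Generator, mean: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Vectorized truncated-at-zero normal draws via inverse-CDF."""
    lo = ndtr(-mean / sigma)
    u = lo + (1.0 - lo) * rng.uniform(size=mean.shape)
    return mean + sigma * ndtri(np.clip(u, 1e-12, 1.0 - 1e-12))


def _marker_ids(classes: list[str]) -> list[str]:
    """Primer-combination + index IDs; batch-artifact loci all share one primer."""
    counters: dict[str, int] = {}
    ids = []
    non_batch = [p for p in PRIMER_COMBINATIONS if p != BATCH_PRIMER]
    k = 0
    for cls in classes:
        primer = BATCH_PRIMER if cls == "batch_artifact" else non_batch[k % len(non_batch)]
        k += cls != "batch_artifact"
        counters[primer] = counters.get(primer, 0) + 1
        ids.append(f"{primer}{counters[primer]}")
    return ids


def simulate(config: GeneratorConfig) -> tuple[IntensityMatrix, TruthTable]:
    """Generate one band-intensity dataset plus its truth table."""
    rng = np.random.default_rng(config.seed)
    P, K, L = config.n_pops, config.n_ind_per_pop, config.n_loci
    N = P * K

    counts = config.class_counts()
    classes: list[str] = []
    for cls in LOCUS_CLASSES:
        classes.extend([cls] * counts[cls])
    marker_ids = _marker_ids(classes)

    pop_ids = [f"pop{i+1:02d}" for i in range(P)]
    sample_pop = np.repeat(np.arange(P), K)
    sample_ids = [f"{pop_ids[i]}_{k+1:02d}" for i in range(P) for k in range(K)]
    sex = np.where(rng.uniform(size=N) < 0.5, "female", "male")
    n_plates = max(1, int(np.ceil(N / config.plate_size)))
    plate = rng.permutation(np.arange(N) % n_plates)
    shifted_plates = np.arange(n_plates) % 2 == 1  # half the plates carry the batch shift

    beta_logit = logit(config.beta_targets)

    alpha = np.zeros(L)
    ancestral = np.empty(L)
    pop_freq = np.empty((L, P))
    copies = np.zeros((N, L), dtype=np.int8)
    is_female = sex == "female"

    amag_pos = config.alpha_magnitudes.get("positive", 2.0)
    amag_bal = config.alpha_magnitudes.get("balancing", 2.0)

    for j, cls in enumerate(classes):
        if cls == "monomorphic":
            fixed_present = rng.uniform() < 0.5
            ancestral[j] = 1.0 if fixed_present else 0.0
            pop_freq[j] = ancestral[j]
            copies[:, j] = 2 if fixed_present else 0
            continue
        if cls == "low_frequency":
            a = rng.uniform(0.02, 0.2)
            alpha[j] = -amag_bal
        elif cls == "balancing":
            # intermediate ancestral frequencies: the balancing signature is
            # heterozygotes visible in (nearly) every population
            a = rng.uniform(0.45, 0.75)
            alpha[j] = -amag_bal
        elif cls == "positive":
            a = rng.uniform(0.05, 0.95)
            alpha[j] = amag_pos
        elif cls in ("sex_linked", "batch_artifact"):
            # surfaces as a low-F_ST outlier, as in the real scan
            a = rng.uniform(0.45, 0.75) if cls == "sex_linked" else rng.uniform(0.3, 0.7)
            alpha[j] = -amag_bal
        else:
            a = rng.uniform(0.05, 0.95)
        ancestral[j] = a
        fst_ij = expit(alpha[j] + beta_logit)
        theta = (1.0 - fst_ij) / fst_ij
        p = rng.beta(a * theta, (1.0 - a) * theta)
        p = np.clip(p, 1e-6, 1.0 - 1e-6)
        pop_freq[j] = p

        p_ind = p[sample_pop]
        f_ind = config.f_is_targets[sample_pop]
        if cls == "sex_linked":
            male = ~is_female
            c = np.zeros(N, dtype=np.int8)
            # females diploid with inbreeding-adjusted genotypes
            u = rng.uniform(size=N)
            hom = p_ind**2 + f_ind * p_ind * (1 - p_ind)
            het = 2 * p_ind * (1 - p_ind) * (1 - f_ind)
            c[is_female] = np.where(u[is_female] < hom[is_female], 2,
                                    np.where(u[is_female] < (hom + het)[is_female], 1, 0))
            c[male] = (rng.uniform(size=male.sum()) < p_ind[male]).astype(np.int8)
            copies[:, j] = c
        else:
            u = rng.uniform(size=N)
            hom = p_ind**2 + f_ind * p_ind * (1 - p_ind)
            het = 2 * p_ind * (1 - p_ind) * (1 - f_ind)
            copies[:, j] = np.where(u < hom, 2, np.where(u < hom + het, 1, 0))

    # intensities: truncated Gaussian mixture, means 0 / mu_j / 2 mu_j
    mu = config.mu_scale * np.exp(config.mu_cv * rng.standard_normal(L) - 0.5 * config.mu_cv**2)
    rel_sigma = np.array([config.rel_sigma_abs, config.rel_sigma_het, config.rel_sigma_hom])
    means = copies.astype(float) * mu[None, :]
    sigma = mu[None, :] * rel_sigma[copies]
    intensities = _truncated_normal(rng, means, sigma)

    # X-linked loci: male single-copy intensity rescaled so the raw female/male
    # mean-intensity ratio equals the configured value (2.0 reproduces the
    # hemizygosity signal: female mean 2p*mu vs male mean p*mu)
    xlinked_cols = np.array([c == "sex_linked" for c in classes])
    if xlinked_cols.any() and config.female_male_ratio != 2.0:
        male_rows = ~is_female
        block = intensities[:, xlinked_cols]
        block[male_rows] *= 2.0 / config.female_male_ratio
        intensities[:, xlinked_cols] = block

    batch_cols = np.array([c == "batch_artifact" for c in classes])
    if batch_cols.any():
        shifted_rows = shifted_plates[plate]
        block = intensities[:, batch_cols]
        block[shifted_rows] *= config.plate_shift
        intensities[:, batch_cols] = block

    samples = pd.DataFrame(
        {
            "population_id": [pop_ids[i] for i in sample_pop],
            "sex": sex,
            "plate_id": [f"plate{p+1}" for p in plate],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    values = pd.DataFrame(intensities, index=samples.index, columns=marker_ids)
    matrix = IntensityMatrix(values, samples)

    truth = TruthTable(
        loci=pd.DataFrame(
            {
                "marker_id": marker_ids,
                "locus_class": classes,
                "alpha": alpha,
                "ancestral_freq": ancestral,
            }
        ),
        pop_freq=pd.DataFrame(pop_freq, index=marker_ids, columns=pop_ids),
        copies=pd.DataFrame(copies, index=samples.index, columns=marker_ids),
    )
    return matrix, truth
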