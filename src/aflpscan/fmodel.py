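"""Bayesian F-model selection scan on AFLP band intensities.

The scan decomposes locus-by-population differentiation on the logit scale,
F_ST(i,j) = logistic(alpha_j + beta_i), into locus effects alpha_j shared
across populations and population effects beta_i shared across loci.
Population allele frequencies p_ij follow the multinomial-Dirichlet (biallelic:
Beta) distribution around an ancestral frequency a_j with precision
theta_ij = (1 - F_ST,ij)/F_ST,ij.  Selection at a locus is expressed by a
reversible-jump indicator delta_j that switches the locus effect in or out;
the posterior probability gamma_j of the with-selection model gives posterior
odds PO_j = gamma_j / (1 - gamma_j), with positive alpha (excess
differentiation) read as positive selection and negative alpha (deficit) as
balancing selection.

Band intensities give near-codominant information: an individual's intensity
is modelled as a truncated-at-zero Gaussian mixture over latent genotypes with
means 0 (absent/absent), mu_j (heterozygote) and 2*mu_j (present homozygote),
weighted by inbreeding-adjusted genotype probabilities, so heterozygotes are
implicitly distinguished from homozygotes and population-specific inbreeding
coefficients F_IS,i become estimable.  Genotypes are marginalized analytically
at every likelihood evaluation.

Proposal scales are adapted during pilot runs toward acceptance rates in
[0.25, 0.45]; identical settings and seed give bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln, log_ndtr, logit

from ._kernels import (
    component_logdens,
    component_logdens_one,
    marginal_loglik,
    marginal_loglik_swap,
)
from .io import AflpDataError, IntensityMatrix
from .scoring import PRESENCE_FRACTION, PRESENCE_QUANTILE

_LOGIT_BOUND = 13.8  # keeps proportions in ~(1e-6, 1-1e-6)
_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ScanSettings:
    """MCMC schedule and decision thresholds.

    Defaults follow the study schedule: 20 pilot runs of 5,000 iterations to
    tune proposals into the 0.25-0.45 acceptance window, 50,000 burn-in
    iterations, 50,000 estimation iterations thinned by 10, and a PO > 10
    ("strong evidence") outlier threshold.
    """

    pilot_runs: int = 20
    pilot_length: int = 5_000
    target_acceptance: tuple[float, float] = (0.25, 0.45)
    burn_in: int = 50_000
    samples: int = 50_000
    thinning: int = 10
    prior_odds_neutral: float = 10.0
    po_threshold: float = 10.0
    seed: int = 0
    alpha_prior_sd: float = 3.0
    beta_prior_mean: float = -1.0
    beta_prior_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("pilot_runs", "pilot_length", "burn_in", "samples", "thinning"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.samples % self.thinning != 0:
            raise ValueError("thinning must divide samples")
        if self.prior_odds_neutral <= 0 or self.po_threshold <= 0:
            raise ValueError("odds thresholds must be positive")

    @classmethod
    def reduced(cls, seed: int = 0, **overrides) -> "ScanSettings":
        """Desk-scale schedule: 5 pilots x 1,000, burn-in 5,000, 5,000 samples."""
        defaults = dict(pilot_runs=5, pilot_length=1_000, burn_in=5_000, samples=5_000)
        defaults.update(overrides)
        return cls(seed=seed, **defaults)


@dataclass
class MixtureParams:
    """Per-locus intensity mixture: single-copy mean and class spreads."""

    mu: float
    sigma_abs: float
    sigma_het: float
    sigma_hom: float

    def __post_init__(self) -> None:
        if min(self.sigma_abs, self.sigma_het, self.sigma_hom) <= 0:
            raise ValueError("spreads must be positive")
        if self.mu <= 0:
            raise ValueError("mu must be positive")


@dataclass
class LocusResult:
    """Per-locus scan output: selection probability, odds, q-value, F_ST, call."""

    marker_id: str
    gamma: float
    po: float
    q_value: float
    fst_mean: float
    call: str = "neutral"
    alpha_mean: float = 0.0


# ---------------------------------------------------------------------------
# model primitives


def fst_from_effects(alpha: float, beta: float) -> float:
    """F_ST(i,j) = logistic(alpha_j + beta_i), strictly inside (0, 1)."""
    f = float(expit(alpha + beta))
    return min(max(f, 1e-12), 1.0 - 1e-12)


def conditional_freq_density(p, a: float, fst: float):
    """Beta density of a population frequency given ancestral frequency and F_ST.

    p | a, F_ST ~ Beta(a*theta, (1-a)*theta) with theta = (1-F_ST)/F_ST, which
    has mean a and variance F_ST * a * (1-a).
    """
    if not 0.0 < a < 1.0:
        raise ValueError("ancestral frequency must be in (0, 1)")
    if not 0.0 < fst < 1.0:
        raise ValueError("fst must be in (0, 1); handle limits in the caller")
    theta = (1.0 - fst) / fst
    from scipy.stats import beta as beta_dist

    return beta_dist.pdf(p, a * theta, (1.0 - a) * theta)


def genotype_probs(p, f_is):
    """Inbreeding-adjusted genotype probabilities (AA, Aa, aa) for allele frequency p."""
    p = np.asarray(p, dtype=float)
    f = np.asarray(f_is, dtype=float)
    pq = p * (1.0 - p)
    aa_hom = p * p + f * pq
    het = 2.0 * pq * (1.0 - f)
    absent = (1.0 - p) ** 2 + f * pq
    return aa_hom, het, absent


_GENOTYPE_COPIES = {"aa": 0.0, "Aa": 1.0, "AA": 2.0}


def intensity_loglik(y: float, genotype: str, mixture: MixtureParams) -> float:
    """Log-density of an intensity under one genotype's truncated Gaussian component.

    Component means are 0, mu and 2*mu for aa, Aa and AA; each Gaussian is
    truncated to y >= 0 and renormalized.
    """
    if y < 0:
        raise ValueError("intensity must be >= 0")
    copies = _GENOTYPE_COPIES[genotype]
    mean = copies * mixture.mu
    sigma = {0.0: mixture.sigma_abs, 1.0: mixture.sigma_het, 2.0: mixture.sigma_hom}[copies]
    z = (y - mean) / sigma
    return float(-0.5 * z * z - np.log(sigma) - 0.5 * _LOG_2PI - log_ndtr(mean / sigma))


def qvalues(gammas) -> np.ndarray:
    """q-values from posterior selection probabilities.

    Loci are ranked by gamma (descending); the q-value at rank k is the mean of
    (1 - gamma) over the top k loci — the expected false-discovery proportion if
    the list were cut there — made monotone along the ranking.
    """
    g = np.asarray(gammas, dtype=float)
    if g.size == 0:
        return g.copy()
    if np.any((g < 0) | (g > 1)):
        raise ValueError("gammas must lie in [0, 1]")
    order = np.argsort(-g, kind="stable")
    csum = np.cumsum(1.0 - g[order])
    q_sorted = csum / np.arange(1, g.size + 1)
    q_sorted = np.maximum.accumulate(q_sorted)
    q = np.empty_like(g)
    q[order] = q_sorted
    return q


def classify_calls(results: list[LocusResult], po_threshold: float) -> dict[str, list[LocusResult]]:
    """Partition loci into positive / balancing / neutral and set each call.

    A locus is selected when PO exceeds the threshold; the sign of its
    posterior-mean locus effect splits excess differentiation (positive) from
    deficit (balancing).
    """
    out: dict[str, list[LocusResult]] = {"positive": [], "balancing": [], "neutral": []}
    for r in results:
        if r.po > po_threshold:
            r.call = "positive" if r.alpha_mean > 0 else "balancing"
        else:
            r.call = "neutral"
        out[r.call].append(r)
    return out


# ---------------------------------------------------------------------------
# the sampler


def _beta_logpdf(p: np.ndarray, a: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Elementwise log Beta(a*theta, (1-a)*theta) density at p (broadcasting)."""
    x1 = a * theta
    x2 = (1.0 - a) * theta
    return (
        (x1 - 1.0) * np.log(p)
        + (x2 - 1.0) * np.log1p(-p)
        - (gammaln(x1) + gammaln(x2) - gammaln(theta))
    )


class _ScanState:
    """Mutable MCMC state with cached likelihood terms."""

    def __init__(self, y: np.ndarray, obs: np.ndarray, gi: np.ndarray, n_pops: int,
                 settings: ScanSettings, rng: np.random.Generator):
        self.y = y            # (N, L) intensities, NaN-free (masked entries arbitrary)
        self.obs = obs        # (N, L) bool
        self.gi = gi          # (N,) population index
        self.P = n_pops
        self.N, self.L = y.shape
        self.s = settings
        self.rng = rng
        # population indicator for per-(pop, locus) likelihood sums
        self.Z = np.zeros((self.P, self.N))
        self.Z[gi, np.arange(self.N)] = 1.0

        self._init_params()
        self.logW = self._genotype_logw(self.p, self.fis)      # (P, L, 3)
        self.logD = self._component_logd(self.mu, self.kappa)  # (N, L, 3)
        self.ll = self._loglik(self.logW, self.logD)           # (N, L)
        self.Spop = self.Z @ self.ll                           # (P, L)

        self.scales = {"p": 0.5, "fis": 0.5, "mu": 0.1, "kappa": 0.1,
                       "a": 0.5, "beta": 0.3, "alpha": 0.5}
        self.acc: dict[str, list[int]] = {k: [0, 0] for k in self.scales}

    # -- initialization from moment estimates -------------------------------

    def _init_params(self) -> None:
        with np.errstate(invalid="ignore"):
            q95 = np.nanquantile(np.where(self.obs, self.y, np.nan), PRESENCE_QUANTILE, axis=0)
        present = np.where(self.obs, self.y, np.nan) > PRESENCE_FRACTION * q95
        n_pop = self.Z @ self.obs.astype(float)
        b_pop = (self.Z @ np.nan_to_num(present.astype(float))) / np.maximum(n_pop, 1.0)
        p0 = 1.0 - np.sqrt(np.clip(1.0 - b_pop, 0.0, 1.0))
        self.p = np.clip(p0, 0.02, 0.98)
        self.a = np.clip(self.p.mean(axis=0), 0.02, 0.98)
        denom = np.maximum((self.a * (1.0 - self.a)).mean(), 1e-6)
        fhat = np.clip(((self.p - self.a) ** 2).mean(axis=1) / denom, 0.05, 0.6)
        self.beta = logit(fhat)
        self.alpha = np.zeros(self.L)
        self.delta = np.zeros(self.L, dtype=bool)
        self.fis = np.full(self.P, 0.02)
        self.mu = np.maximum(q95 / 2.0, 1e-3)
        self.mu_prior_sd = 10.0 * float(np.median(self.mu))
        self.kappa = np.array([0.10, 0.15, 0.20])  # relative spreads: absent, het, hom

    # -- cached likelihood pieces -------------------------------------------

    def _genotype_logw(self, p: np.ndarray, fis: np.ndarray) -> np.ndarray:
        hom, het, absent = genotype_probs(p, fis[:, None])
        w = np.stack([absent, het, hom], axis=-1)  # order: 0, mu, 2mu copies
        return np.log(np.maximum(w, 1e-300))

    def _component_logd(self, mu: np.ndarray, kappa: np.ndarray) -> np.ndarray:
        """Truncated-normal log densities for 0/1/2 copies; (N, L, 3)."""
        out = np.empty((self.N, self.L, 3))
        component_logdens(self.y, self.obs, mu, kappa, out)
        return out

    def _loglik(self, logW: np.ndarray, logD: np.ndarray) -> np.ndarray:
        out = np.empty((self.N, self.L))
        marginal_loglik(np.ascontiguousarray(logW), logD, self.gi, self.obs, out)
        return out

    def _theta(self, alpha: np.ndarray) -> np.ndarray:
        f = np.clip(expit(alpha[None, :] + self.beta[:, None]), 1e-6, 1 - 1e-6)
        return (1.0 - f) / f

    def _theta_for(self, alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
        f = np.clip(expit(alpha[None, :] + beta[:, None]), 1e-6, 1 - 1e-6)
        return (1.0 - f) / f

    @property
    def effective_alpha(self) -> np.ndarray:
        return np.where(self.delta, self.alpha, 0.0)

    # -- update blocks -------------------------------------------------------

    def _record(self, block: str, accepted: float, proposed: float) -> None:
        self.acc[block][0] += int(round(accepted))
        self.acc[block][1] += int(round(proposed))

    def update_p(self) -> None:
        lo = logit(self.p)
        lo_new = np.clip(lo + self.scales["p"] * self.rng.standard_normal(self.p.shape),
                         -_LOGIT_BOUND, _LOGIT_BOUND)
        p_new = expit(lo_new)
        logW_new = self._genotype_logw(p_new, self.fis)
        ll_new = self._loglik(logW_new, self.logD)
        Spop_new = self.Z @ ll_new
        theta = self._theta(self.effective_alpha)
        x1 = self.a[None, :] * theta
        x2 = (1.0 - self.a[None, :]) * theta
        prior = ((x1 - 1.0) * (np.log(p_new) - np.log(self.p))
                 + (x2 - 1.0) * (np.log1p(-p_new) - np.log1p(-self.p)))
        jac = (np.log(p_new) + np.log1p(-p_new)) - (np.log(self.p) + np.log1p(-self.p))
        delta_lp = (Spop_new - self.Spop) + prior + jac
        accept = np.log(self.rng.uniform(size=delta_lp.shape)) < delta_lp
        self.p = np.where(accept, p_new, self.p)
        self.logW = np.where(accept[:, :, None], logW_new, self.logW)
        acc_n = accept[self.gi]
        self.ll = np.where(acc_n, ll_new, self.ll)
        self.Spop = np.where(accept, Spop_new, self.Spop)
        self._record("p", accept.sum(), accept.size)

    def update_fis(self) -> None:
        lo = logit(np.clip(self.fis, 1e-6, 1 - 1e-6))
        lo_new = np.clip(lo + self.scales["fis"] * self.rng.standard_normal(self.P),
                         -_LOGIT_BOUND, _LOGIT_BOUND)
        f_new = expit(lo_new)
        logW_new = self._genotype_logw(self.p, f_new)
        ll_new = self._loglik(logW_new, self.logD)
        Spop_new = self.Z @ ll_new
        jac = (np.log(f_new) + np.log1p(-f_new)) - (np.log(self.fis) + np.log1p(-self.fis))
        delta_lp = (Spop_new - self.Spop).sum(axis=1) + jac
        accept = np.log(self.rng.uniform(size=self.P)) < delta_lp
        self.fis = np.where(accept, f_new, self.fis)
        self.logW = np.where(accept[:, None, None], logW_new, self.logW)
        acc_n = accept[self.gi][:, None]
        self.ll = np.where(acc_n, ll_new, self.ll)
        self.Spop = np.where(accept[:, None], Spop_new, self.Spop)
        self._record("fis", accept.sum(), self.P)

    def update_mu(self) -> None:
        mu_new = self.mu * np.exp(self.scales["mu"] * self.rng.standard_normal(self.L))
        logD_new = self._component_logd(mu_new, self.kappa)
        ll_new = self._loglik(self.logW, logD_new)
        prior = -0.5 * (mu_new**2 - self.mu**2) / self.mu_prior_sd**2
        jac = np.log(mu_new) - np.log(self.mu)
        delta_lp = (ll_new - self.ll).sum(axis=0) + prior + jac
        accept = np.log(self.rng.uniform(size=self.L)) < delta_lp
        self.mu = np.where(accept, mu_new, self.mu)
        self.logD = np.where(accept[None, :, None], logD_new, self.logD)
        self.ll = np.where(accept[None, :], ll_new, self.ll)
        self.Spop = self.Z @ self.ll
        self._record("mu", accept.sum(), self.L)

    def update_kappa(self) -> None:
        """Per-component random walk on the log relative spreads."""
        logW = np.ascontiguousarray(self.logW)
        for c in range(3):
            k_new = float(self.kappa[c] * np.exp(self.scales["kappa"] * self.rng.standard_normal()))
            swap = np.empty((self.N, self.L))
            component_logdens_one(self.y, self.obs, self.mu, k_new, c, swap)
            ll_new = np.empty((self.N, self.L))
            marginal_loglik_swap(logW, self.logD, swap, c, self.gi, self.obs, ll_new)
            prior = -0.5 * (k_new**2 - self.kappa[c] ** 2)  # half-normal sd 1
            jac = np.log(k_new) - np.log(self.kappa[c])
            delta_lp = float((ll_new - self.ll).sum()) + prior + jac
            if np.log(self.rng.uniform()) < delta_lp:
                self.kappa = self.kappa.copy()
                self.kappa[c] = k_new
                self.logD[:, :, c] = swap
                self.ll = ll_new
                self.Spop = self.Z @ self.ll
                self._record("kappa", 1, 1)
            else:
                self._record("kappa", 0, 1)

    def update_a(self) -> None:
        lo = logit(self.a)
        lo_new = np.clip(lo + self.scales["a"] * self.rng.standard_normal(self.L),
                         -_LOGIT_BOUND, _LOGIT_BOUND)
        a_new = expit(lo_new)
        theta = self._theta(self.effective_alpha)
        lp_old = _beta_logpdf(self.p, self.a[None, :], theta).sum(axis=0)
        lp_new = _beta_logpdf(self.p, a_new[None, :], theta).sum(axis=0)
        jac = (np.log(a_new) + np.log1p(-a_new)) - (np.log(self.a) + np.log1p(-self.a))
        accept = np.log(self.rng.uniform(size=self.L)) < (lp_new - lp_old + jac)
        self.a = np.where(accept, a_new, self.a)
        self._record("a", accept.sum(), self.L)

    def update_beta(self) -> None:
        b_new = self.beta + self.scales["beta"] * self.rng.standard_normal(self.P)
        alpha_eff = self.effective_alpha
        lp_old = _beta_logpdf(self.p, self.a[None, :], self._theta_for(alpha_eff, self.beta)).sum(axis=1)
        lp_new = _beta_logpdf(self.p, self.a[None, :], self._theta_for(alpha_eff, b_new)).sum(axis=1)
        prior = (-0.5 * ((b_new - self.s.beta_prior_mean) / self.s.beta_prior_sd) ** 2
                 + 0.5 * ((self.beta - self.s.beta_prior_mean) / self.s.beta_prior_sd) ** 2)
        accept = np.log(self.rng.uniform(size=self.P)) < (lp_new - lp_old + prior)
        self.beta = np.where(accept, b_new, self.beta)
        self._record("beta", accept.sum(), self.P)

    def update_alpha(self) -> None:
        active = self.delta
        if not active.any():
            return
        a_new = self.alpha + self.scales["alpha"] * self.rng.standard_normal(self.L)
        lp_old = _beta_logpdf(self.p, self.a[None, :], self._theta(self.effective_alpha)).sum(axis=0)
        lp_new = _beta_logpdf(self.p, self.a[None, :], self._theta(np.where(active, a_new, 0.0))).sum(axis=0)
        prior = (-0.5 * (a_new / self.s.alpha_prior_sd) ** 2
                 + 0.5 * (self.alpha / self.s.alpha_prior_sd) ** 2)
        accept = active & (np.log(self.rng.uniform(size=self.L)) < (lp_new - lp_old + prior))
        self.alpha = np.where(accept, a_new, self.alpha)
        self._record("alpha", accept.sum(), int(active.sum()))

    def update_delta(self) -> None:
        """Reversible-jump toggle of the locus effect, alpha drawn from its prior.

        Proposal density and alpha prior cancel, leaving the frequency-prior
        likelihood ratio plus the log prior model odds.
        """
        alpha_star = self.s.alpha_prior_sd * self.rng.standard_normal(self.L)
        alpha_on = np.where(self.delta, self.alpha, alpha_star)
        lp_on = _beta_logpdf(self.p, self.a[None, :], self._theta(alpha_on)).sum(axis=0)
        lp_off = _beta_logpdf(self.p, self.a[None, :], self._theta(np.zeros(self.L))).sum(axis=0)
        log_prior_odds = np.log(self.s.prior_odds_neutral)
        # activation: lp_on - lp_off - log_prior_odds ; deactivation: the negative
        delta_lp = np.where(self.delta,
                            lp_off - lp_on + log_prior_odds,
                            lp_on - lp_off - log_prior_odds)
        accept = np.log(self.rng.uniform(size=self.L)) < delta_lp
        new_delta = np.where(accept, ~self.delta, self.delta)
        self.alpha = np.where(accept & ~self.delta, alpha_star,
                              np.where(accept & self.delta, 0.0, self.alpha))
        self.delta = new_delta

    def sweep(self) -> None:
        self.update_p()
        self.update_fis()
        self.update_mu()
        self.update_kappa()
        self.update_a()
        self.update_beta()
        self.update_alpha()
        self.update_delta()

    # -- adaptation ----------------------------------------------------------

    def adapt(self) -> dict[str, float]:
        lo, hi = self.s.target_acceptance
        rates = {}
        for block, (acc, prop) in self.acc.items():
            rate = acc / prop if prop else float("nan")
            rates[block] = rate
            if prop == 0 or np.isnan(rate):
                continue
            if rate > hi:
                self.scales[block] *= 1.3
            elif rate < lo:
                self.scales[block] /= 1.3
            self.acc[block] = [0, 0]
        return rates


def run_scan(
    matrix: IntensityMatrix,
    informative_ids: list[str],
    settings: ScanSettings,
) -> tuple[list[LocusResult], dict]:
    """Run the F-model scan on the informative markers of an intensity matrix.

    Returns per-locus results (posterior selection probability gamma, posterior
    odds, q-value, posterior-mean F_ST, call) and a run manifest with the
    schedule, seed, final proposal scales and acceptance rates.
    """
    if len(matrix.populations) < 2:
        raise AflpDataError("the scan needs at least 2 populations")
    if len(informative_ids) < 2:
        raise AflpDataError("the scan needs at least 2 informative loci")
    sub = matrix.subset_markers(informative_ids)
    raw = sub.values.to_numpy()
    obs = ~np.isnan(raw)
    y = np.nan_to_num(raw)
    pops = sub.populations
    pop_index = {p: k for k, p in enumerate(pops)}
    gi = np.array([pop_index[p] for p in sub.samples["population_id"]])

    rng = np.random.default_rng(settings.seed)
    state = _ScanState(y, obs, gi, len(pops), settings, rng)

    pilot_rates: list[dict[str, float]] = []
    for _ in range(settings.pilot_runs):
        for _ in range(settings.pilot_length):
            state.sweep()
        pilot_rates.append(state.adapt())
    lo, hi = settings.target_acceptance
    final_rates = pilot_rates[-1] if pilot_rates else {}
    unadapted = [b for b, r in final_rates.items() if not (lo <= r <= hi) and not np.isnan(r)]
    if unadapted:
        warnings.warn(
            f"proposal blocks outside acceptance window after pilots: {unadapted}",
            RuntimeWarning,
            stacklevel=2,
        )

    for _ in range(settings.burn_in):
        state.sweep()

    n_loci = state.L
    delta_sum = np.zeros(n_loci)
    alpha_sum = np.zeros(n_loci)
    alpha_count = np.zeros(n_loci)
    fst_sum = np.zeros(n_loci)
    pop_fst_sum = np.zeros(state.P)
    fis_sum = np.zeros(state.P)
    n_kept = 0
    for it in range(settings.samples):
        state.sweep()
        if (it + 1) % settings.thinning == 0:
            delta_sum += state.delta
            alpha_sum += np.where(state.delta, state.alpha, 0.0)
            alpha_count += state.delta
            fst_sum += expit(state.effective_alpha[None, :] + state.beta[:, None]).mean(axis=0)
            pop_fst_sum += expit(state.beta)
            fis_sum += state.fis
            n_kept += 1

    gamma = delta_sum / n_kept
    fst_mean = fst_sum / n_kept
    alpha_mean = np.where(alpha_count > 0, alpha_sum / np.maximum(alpha_count, 1.0), 0.0)
    q = qvalues(gamma)
    results = []
    for j, marker_id in enumerate(sub.marker_ids):
        g = float(gamma[j])
        po = float("inf") if g >= 1.0 else g / (1.0 - g)
        results.append(
            LocusResult(
                marker_id=marker_id,
                gamma=g,
                po=po,
                q_value=float(q[j]),
                fst_mean=float(fst_mean[j]),
                alpha_mean=float(alpha_mean[j]),
            )
        )
    classify_calls(results, settings.po_threshold)

    manifest = {
        "settings": {
            "pilot_runs": settings.pilot_runs,
            "pilot_length": settings.pilot_length,
            "burn_in": settings.burn_in,
            "samples": settings.samples,
            "thinning": settings.thinning,
            "prior_odds_neutral": settings.prior_odds_neutral,
            "po_threshold": settings.po_threshold,
            "seed": settings.seed,
        },
        "n_populations": len(pops),
        "n_loci": n_loci,
        "n_retained_samples": n_kept,
        "populations": pops,
        "pop_fst_mean": (pop_fst_sum / n_kept).tolist(),
        "pop_fis_mean": (fis_sum / n_kept).tolist(),
        "proposal_scales": dict(state.scales),
        "pilot_acceptance_rates": pilot_rates,
        "unadapted_blocks": unadapted,
    }
    return results, manifest
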