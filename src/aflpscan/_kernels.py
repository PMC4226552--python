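"""Compiled inner loops of the scan likelihood.

The genotype-marginal intensity likelihood touches every (individual, locus)
cell several times per MCMC sweep; these numba kernels fuse the gather,
mixture log-sum-exp and truncation normalization into single passes to keep
full-schedule scans tractable on one core.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_LOG_2PI = math.log(2.0 * math.pi)
_SQRT2 = math.sqrt(2.0)


@njit(cache=False, fastmath=True)
def component_logdens(y, obs, mu, kappa, out):
    """Truncated-at-zero Gaussian log densities for 0/1/2 allele copies.

    out[n, j, c] for component means c * mu[j] and spreads kappa[c] * mu[j].
    """
    N, L = y.shape
    for j in range(L):
        for c in range(3):
            mean = c * mu[j]
            sig = kappa[c] * mu[j]
            # log P(X > 0) for X ~ N(mean, sig); mean >= 0 so no underflow
            tail = math.log(0.5 * math.erfc(-mean / (sig * _SQRT2)))
            norm = -math.log(sig) - 0.5 * _LOG_2PI - tail
            for n in range(N):
                if obs[n, j]:
                    z = (y[n, j] - mean) / sig
                    out[n, j, c] = -0.5 * z * z + norm
                else:
                    out[n, j, c] = 0.0


@njit(cache=False, fastmath=True)
def component_logdens_one(y, obs, mu, kappa_c, c, out):
    """Single mixture component (allele copy number c) of component_logdens."""
    N, L = y.shape
    for j in range(L):
        mean = c * mu[j]
        sig = kappa_c * mu[j]
        tail = math.log(0.5 * math.erfc(-mean / (sig * _SQRT2)))
        norm = -math.log(sig) - 0.5 * _LOG_2PI - tail
        for n in range(N):
            if obs[n, j]:
                z = (y[n, j] - mean) / sig
                out[n, j] = -0.5 * z * z + norm
            else:
                out[n, j] = 0.0


@njit(cache=False, fastmath=True)
def marginal_loglik(logW, logD, gi, obs, out):
    """Genotype-marginalized log-likelihood per (individual, locus).

    logW: (P, L, 3) genotype log-probabilities per population;
    logD: (N, L, 3) component log-densities.  Missing cells contribute 0.
    """
    N, L = out.shape
    for n in range(N):
        g = gi[n]
        for j in range(L):
            if not obs[n, j]:
                out[n, j] = 0.0
                continue
            t0 = logW[g, j, 0] + logD[n, j, 0]
            t1 = logW[g, j, 1] + logD[n, j, 1]
            t2 = logW[g, j, 2] + logD[n, j, 2]
            m = t0
            if t1 > m:
                m = t1
            if t2 > m:
                m = t2
            out[n, j] = m + math.log(
                math.exp(t0 - m) + math.exp(t1 - m) + math.exp(t2 - m)
            )


@njit(cache=False, fastmath=True)
def marginal_loglik_swap(logW, logD, swap_col, c, gi, obs, out):
    """marginal_loglik with component ``c``'s log-density replaced by swap_col (N, L)."""
    N, L = out.shape
    for n in range(N):
        g = gi[n]
        for j in range(L):
            if not obs[n, j]:
                out[n, j] = 0.0
                continue
            d0 = swap_col[n, j] if c == 0 else logD[n, j, 0]
            d1 = swap_col[n, j] if c == 1 else logD[n, j, 1]
            d2 = swap_col[n, j] if c == 2 else logD[n, j, 2]
            t0 = logW[g, j, 0] + d0
            t1 = logW[g, j, 1] + d1
            t2 = logW[g, j, 2] + d2
            m = t0
            if t1 > m:
                m = t1
            if t2 > m:
                m = t2
            out[n, j] = m + math.log(
                math.exp(t0 - m) + math.exp(t1 - m) + math.exp(t2 - m)
            )
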