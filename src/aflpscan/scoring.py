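"""Presence calling, informative-marker filtering and population diversity.

A band is scored present when its intensity exceeds 10% of the marker's 95%
intensity quantile taken across all individuals; the comparison is strict, so
a value exactly at the threshold scores absent.  Markers enter the selection
scan only if their overall band frequency lies in [0.05, 0.95]; high-frequency
markers are rescued when their intensity distribution is bimodal across all
individuals (a high proportion of fixed plus heterozygous individuals is
informative for F_IS) and no intensity exceeds 3x the 95% quantile (machine
artifacts).

Diversity within a population is the average proportion of pairwise band
differences between its individuals, an analogue of Nei's gene diversity for
dominant markers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io import AflpDataError, BinaryMatrix, IntensityMatrix

PRESENCE_QUANTILE = 0.95
PRESENCE_FRACTION = 0.10
ARTIFACT_MULTIPLE = 3.0
BAND_FREQ_MIN = 0.05
BAND_FREQ_MAX = 0.95


@dataclass
class MarkerSummary:
    marker_id: str
    band_frequency: float
    q95: float
    informative: bool = False
    artifact_flagged: bool = False

    @property
    def presence_threshold(self) -> float:
        return PRESENCE_FRACTION * self.q95

    @property
    def artifact_cap(self) -> float:
        return ARTIFACT_MULTIPLE * self.q95


@dataclass
class PopulationDiversity:
    population_id: str
    variable_fraction: float
    diversity: float


def marker_q95(matrix: IntensityMatrix) -> pd.Series:
    """Per-marker 95% intensity quantile across all individuals (type-7)."""
    return matrix.values.quantile(PRESENCE_QUANTILE, interpolation="linear")


def call_presence(matrix: IntensityMatrix) -> BinaryMatrix:
    """Score each band present iff intensity > 10% of the marker's 95% quantile.

    Missing intensities propagate to missing calls.  A marker whose column is
    entirely missing, or with fewer than two scored individuals, is an error.
    """
    arr = matrix.values.to_numpy()
    n_obs = (~np.isnan(arr)).sum(axis=0)
    if (n_obs < 2).any():
        bad = [m for m, n in zip(matrix.marker_ids, n_obs) if n < 2]
        raise AflpDataError(f"markers with <2 scored intensities: {bad[:5]}")
    q95 = np.nanquantile(arr, PRESENCE_QUANTILE, axis=0)
    calls = np.where(arr > PRESENCE_FRACTION * q95, 1.0, 0.0)
    calls[np.isnan(arr)] = np.nan
    values = pd.DataFrame(calls, index=matrix.values.index, columns=matrix.values.columns)
    return BinaryMatrix(values, matrix.samples.copy())


def band_frequency(binary: BinaryMatrix, marker_id: str) -> float:
    """Fraction of scored (non-missing) individuals carrying the band."""
    if marker_id not in binary.values.columns:
        raise AflpDataError(f"unknown marker {marker_id!r}")
    col = binary.values[marker_id].to_numpy()
    n = (~np.isnan(col)).sum()
    if n == 0:
        raise AflpDataError(f"marker {marker_id!r} has no scored individuals")
    return float(np.nansum(col) / n)


def band_frequencies(binary: BinaryMatrix) -> pd.Series:
    arr = binary.values.to_numpy()
    n = (~np.isnan(arr)).sum(axis=0)
    return pd.Series(np.nansum(arr, axis=0) / n, index=binary.values.columns)


def summarize_marker(
    matrix: IntensityMatrix, binary: BinaryMatrix, marker_id: str
) -> MarkerSummary:
    col = matrix.values[marker_id].to_numpy()
    q95 = float(np.nanquantile(col, PRESENCE_QUANTILE))
    summary = MarkerSummary(marker_id, band_frequency(binary, marker_id), q95)
    summary.artifact_flagged = bool(np.nanmax(col) > summary.artifact_cap)
    return summary


def classify_informative(summary: MarkerSummary, bimodal_overall: bool) -> bool:
    """Apply the informative-marker rule.

    Band frequency in [0.05, 0.95] qualifies outright; above 0.95 a marker is
    rescued only if bimodal across all individuals and free of intensities
    beyond 3x its 95% quantile.
    """
    b = summary.band_frequency
    if BAND_FREQ_MIN <= b <= BAND_FREQ_MAX:
        return True
    if b > BAND_FREQ_MAX and bimodal_overall and not summary.artifact_flagged:
        return True
    return False


def informative_markers(matrix: IntensityMatrix, binary: BinaryMatrix | None = None) -> list[str]:
    """Marker IDs passing the informative filter (bimodality assessed where needed)."""
    from .triage import assess_bimodality  # deferred: triage depends on scoring

    if binary is None:
        binary = call_presence(matrix)
    freqs = band_frequencies(binary)
    kept: list[str] = []
    for marker_id, b in freqs.items():
        summary = summarize_marker(matrix, binary, str(marker_id))
        if BAND_FREQ_MIN <= b <= BAND_FREQ_MAX:
            kept.append(str(marker_id))
        elif b > BAND_FREQ_MAX and not summary.artifact_flagged:
            try:
                assessment = assess_bimodality(matrix, str(marker_id), per_population=False)
            except AflpDataError:
                continue
            if assessment.overall_bimodal:
                kept.append(str(marker_id))
    return kept


def population_diversity(binary: BinaryMatrix, population_id: str) -> PopulationDiversity:
    """Mean pairwise band-difference proportion and polymorphic-marker fraction.

    Each unordered pair of individuals contributes the fraction of markers, among
    those scored in both, at which their band states differ.  Pairs with no
    mutually scored marker are dropped from the mean.
    """
    mask = binary.samples["population_id"] == population_id
    sub = binary.values.loc[mask.to_numpy()].to_numpy()
    n_ind = sub.shape[0]
    if n_ind < 2:
        raise AflpDataError(f"population {population_id!r} has fewer than 2 individuals")

    obs = ~np.isnan(sub)
    x = np.nan_to_num(sub)
    # pairwise: diff counts via matrix algebra over 0/1 states restricted to co-observed markers
    diffs = []
    for i, j in combinations(range(n_ind), 2):
        both = obs[i] & obs[j]
        m = both.sum()
        if m == 0:
            continue
        diffs.append(float(np.sum(x[i, both] != x[j, both])) / m)
    if not diffs:
        raise AflpDataError(f"population {population_id!r}: no comparable pairs")

    col_obs = obs.sum(axis=0)
    present = np.nansum(sub, axis=0)
    scored = col_obs > 0
    variable = (present[scored] > 0) & (present[scored] < col_obs[scored])
    return PopulationDiversity(
        population_id=population_id,
        variable_fraction=float(variable.mean()) if scored.any() else 0.0,
        diversity=float(np.mean(diffs)),
    )


def all_population_diversities(binary: BinaryMatrix) -> list[PopulationDiversity]:
    return [population_diversity(binary, pid) for pid in binary.populations]


def allele_freq_from_band(b: float, f_is: float = 0.0) -> float:
    """Moment estimator of the dominant-allele frequency from a band frequency.

    Solves 1 - b = (1-p)^2 + f_is * p * (1-p) for p in [0, 1].  With no
    inbreeding this is p = 1 - sqrt(1 - b).  Used for initialization and by
    the synthetic generator; the scan itself estimates frequencies in the
    Bayesian model.
    """
    if not (0.0 <= b <= 1.0 and 0.0 <= f_is <= 1.0):
        raise ValueError("b and f_is must lie in [0, 1]")
    if b == 0.0:
        return 0.0
    if b == 1.0:
        return 1.0
    if f_is == 1.0:
        return b
    # (1-f)p^2 + f*p... rewrite with q = 1-p: (1-f)q^2 + f q - (1-b) = 0
    a2 = 1.0 - f_is
    disc = f_is * f_is + 4.0 * a2 * (1.0 - b)
    q = (-f_is + math.sqrt(disc)) / (2.0 * a2)
    p = 1.0 - q
    if not -1e-12 <= p <= 1.0 + 1e-12:
        raise ValueError(f"no root in [0,1] for b={b}, f_is={f_is}")
    return min(max(p, 0.0), 1.0)
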