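"""Post-hoc triage of low-F_ST outliers.

A marker genuinely under balancing selection should show intermediate allele
frequencies in (nearly) every population, hence heterozygotes, hence a bimodal
band-intensity distribution with the homozygote peak at about twice the
heterozygote peak.  But two artifacts mimic that signature: X-linked markers
(hemizygous males make female intensities about twice male intensities while
keeping inter-population differentiation low) and PCR plate batch effects
(whole 96-well plates amplify systematically stronger).  Triage therefore
classifies each low-F_ST outlier, in precedence order, as a batch artifact
(plate test p < 0.05), sex-linked (sex test p < 0.05), low frequency
(estimated allele frequency below a threshold), a prime balancing candidate
(bimodal overall and within at least half the populations), bimodal overall
only, or uni/multimodal.

Sex and plate tests are deliberately run without multiple-testing correction —
a liberal artifact screen is conservative for balancing-selection claims.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

from .io import AflpDataError, IntensityMatrix
from .scoring import PRESENCE_FRACTION, PRESENCE_QUANTILE, allele_freq_from_band

MIN_NONZERO = 10          # minimum present-band intensities per assessed unit
MIN_WEIGHT = 0.1          # minor mixture component weight for bimodality
MIN_SEPARATION_SD = 2.0   # component mean separation in pooled-spread units


@dataclass
class BimodalityAssessment:
    marker_id: str
    overall_bimodal: bool
    n_pops_bimodal: int = 0
    component_means: tuple[float, ...] = ()
    component_weights: tuple[float, ...] = ()


@dataclass
class TriageRecord:
    marker_id: str
    category: str
    sex_p: float
    plate_p: float
    allele_freq: float
    band_freq: float = float("nan")
    po: float = float("nan")
    fst: float = float("nan")


def _marker_column(matrix: IntensityMatrix, marker_id: str) -> np.ndarray:
    if marker_id not in matrix.values.columns:
        raise AflpDataError(f"unknown marker {marker_id!r}")
    return matrix.values[marker_id].to_numpy()


def sex_association_test(matrix: IntensityMatrix, marker_id: str) -> tuple[float, float]:
    """Welch t-test of raw band intensities between females and males.

    Returns (p-value, female/male mean-intensity ratio).  Individuals of
    unknown sex and missing intensities are excluded.  X-linkage predicts a
    ratio near 2.
    """
    col = _marker_column(matrix, marker_id)
    sex = matrix.samples["sex"].to_numpy()
    ok = ~np.isnan(col)
    f = col[ok & (sex == "female")]
    m = col[ok & (sex == "male")]
    if len(f) < 2 or len(m) < 2:
        raise AflpDataError(f"marker {marker_id!r}: need >= 2 individuals of each sex")
    t = stats.ttest_ind(f, m, equal_var=False)
    ratio = float(f.mean() / m.mean()) if m.mean() > 0 else float("inf")
    return float(t.pvalue), ratio


def plate_association_test(matrix: IntensityMatrix, marker_id: str) -> float:
    """Batch-effect test of raw intensities across PCR plates.

    Welch t-test for two plates, one-way analysis of variance for more.
    """
    col = _marker_column(matrix, marker_id)
    plates = matrix.samples["plate_id"].to_numpy()
    ok = ~np.isnan(col)
    groups = [col[ok & (plates == p)] for p in dict.fromkeys(plates[ok])]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        raise AflpDataError(f"marker {marker_id!r}: need >= 2 plates with >= 2 individuals")
    if len(groups) == 2:
        return float(stats.ttest_ind(groups[0], groups[1], equal_var=False).pvalue)
    return float(stats.f_oneway(*groups).pvalue)


def _fit_bimodal(x: np.ndarray) -> tuple[bool, np.ndarray, np.ndarray]:
    """1- vs 2-component Gaussian mixture comparison by small-sample AIC.

    Bimodal iff the 2-component fit wins on AICc, the minor weight is at least
    MIN_WEIGHT, and the means are separated by at least MIN_SEPARATION_SD
    pooled standard deviations.
    """
    n = len(x)
    X = x.reshape(-1, 1)

    def aicc(gm: GaussianMixture) -> float:
        k = gm._n_parameters()
        if n - k - 1 <= 0:
            return float("inf")
        return float(gm.aic(X) + 2.0 * k * (k + 1) / (n - k - 1))

    gm1 = GaussianMixture(1, random_state=0).fit(X)
    gm2 = GaussianMixture(2, random_state=0, n_init=3).fit(X)
    means = gm2.means_.ravel()
    weights = gm2.weights_.ravel()
    pooled_sd = float(np.sqrt(np.sum(weights * gm2.covariances_.ravel())))
    separated = abs(means[1] - means[0]) >= MIN_SEPARATION_SD * pooled_sd
    bimodal = aicc(gm2) < aicc(gm1) and weights.min() >= MIN_WEIGHT and separated
    order = np.argsort(means)
    return bimodal, means[order], weights[order]


def assess_bimodality(
    matrix: IntensityMatrix, marker_id: str, per_population: bool = False
) -> BimodalityAssessment:
    """Assess whether a marker's present-band intensities form two peaks.

    Works on intensities above the presence threshold (the zero/absent class is
    excluded so the test addresses heterozygote vs homozygote peaks, not
    presence vs absence).  With ``per_population`` the fit is repeated within
    each population; populations with fewer than MIN_NONZERO present bands
    count as not bimodal.
    """
    col = _marker_column(matrix, marker_id)
    ok = ~np.isnan(col)
    q95 = float(np.quantile(col[ok], PRESENCE_QUANTILE))
    present = ok & (col > PRESENCE_FRACTION * q95)
    x = col[present]
    if len(x) < MIN_NONZERO:
        raise AflpDataError(f"marker {marker_id!r}: fewer than {MIN_NONZERO} present bands")

    bimodal, means, weights = _fit_bimodal(x)
    assessment = BimodalityAssessment(
        marker_id=marker_id,
        overall_bimodal=bool(bimodal),
        component_means=tuple(float(v) for v in means),
        component_weights=tuple(float(v) for v in weights),
    )
    if per_population:
        pops = matrix.samples["population_id"].to_numpy()
        n_bimodal = 0
        for pid in dict.fromkeys(pops):
            xp = col[present & (pops == pid)]
            if len(xp) < MIN_NONZERO:
                continue
            ok_pop, _, _ = _fit_bimodal(xp)
            n_bimodal += ok_pop
        assessment.n_pops_bimodal = n_bimodal
    return assessment


def triage(
    low_fst_outliers: list,
    matrix: IntensityMatrix,
    freq_threshold: float = 0.25,
    sex_alpha: float = 0.05,
    plate_alpha: float = 0.05,
    min_bimodal_pops: int | None = None,
) -> list[TriageRecord]:
    """Assign each low-F_ST outlier exactly one category, in precedence order:
    batch artifact, sex-linked, low frequency, prime balancing candidate
    (bimodal overall and in at least ``min_bimodal_pops`` populations —
    default half), bimodal overall only, uni/multimodal.

    ``low_fst_outliers`` are scan results (or any objects with ``marker_id``,
    optionally ``po`` and ``fst_mean``).  The allele frequency is the moment
    estimate from the pooled band frequency.
    """
    if min_bimodal_pops is None:
        min_bimodal_pops = int(np.ceil(len(matrix.populations) / 2))

    records: list[TriageRecord] = []
    for r in low_fst_outliers:
        marker_id = r.marker_id if hasattr(r, "marker_id") else str(r)
        col = _marker_column(matrix, marker_id)
        ok = ~np.isnan(col)
        q95 = float(np.quantile(col[ok], PRESENCE_QUANTILE))
        band_freq = float((col[ok] > PRESENCE_FRACTION * q95).mean())
        allele_freq = allele_freq_from_band(band_freq, 0.0)
        try:
            sex_p, _ = sex_association_test(matrix, marker_id)
        except AflpDataError:
            sex_p = float("nan")
        try:
            plate_p = plate_association_test(matrix, marker_id)
        except AflpDataError:
            plate_p = float("nan")

        if plate_p < plate_alpha:
            category = "batch_artifact"
        elif sex_p < sex_alpha:
            category = "sex_linked"
        elif allele_freq < freq_threshold:
            category = "low_frequency"
        else:
            try:
                assessment = assess_bimodality(matrix, marker_id, per_population=True)
            except AflpDataError:
                assessment = BimodalityAssessment(marker_id, overall_bimodal=False)
            if assessment.overall_bimodal and assessment.n_pops_bimodal >= min_bimodal_pops:
                category = "bimodal_balancing"
            elif assessment.overall_bimodal:
                category = "bimodal_no_per_pop"
            else:
                category = "uni_multimodal"

        records.append(
            TriageRecord(
                marker_id=marker_id,
                category=category,
                sex_p=sex_p,
                plate_p=plate_p,
                allele_freq=allele_freq,
                band_freq=band_freq,
                po=getattr(r, "po", float("nan")),
                fst=getattr(r, "fst_mean", float("nan")),
            )
        )
    return records
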