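"""Geographic analysis of positive-selection outliers.

Three tools: principal component ordinations of individuals or populations;
a locus-by-locus two-group SAMOVA that searches population bipartitions for
the split maximizing the among-group fixation index F_CT; and pairwise
Pearson correlations of population allele frequencies across outlier loci
with Holm's step-down correction, to find loci sharing a geographic pattern.

F_CT comes from the standard hierarchical AMOVA decomposition of the allele
indicator variable into among-group, among-population-within-group and
within-population variance components estimated by expected mean squares;
negative component estimates are truncated to zero before the ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class Bipartition:
    """A two-group split of the population set."""

    group_a: frozenset[str]
    group_b: frozenset[str]

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise ValueError("both groups must be nonempty")
        if self.group_a & self.group_b:
            raise ValueError("groups must be disjoint")

    @classmethod
    def of(cls, group_a: Sequence[str], group_b: Sequence[str]) -> "Bipartition":
        return cls(frozenset(group_a), frozenset(group_b))


@dataclass
class SamovaResult:
    marker_id: str
    best: Bipartition
    fct: float
    method: str  # exhaustive | annealing


@dataclass
class AssociationMatrix:
    """All pairwise locus correlations with Holm-adjusted p-values."""

    pairs: pd.DataFrame          # locus_a, locus_b, r, p, p_adj, significant
    counts: pd.Series            # per-locus number of significant associations
    skipped: list[tuple[str, str]]  # pairs with an undefined correlation


Counts = Mapping[str, tuple[float, float]]  # pop -> (allele-A copies, total copies)


def allele_counts_from_freqs(freqs: Mapping[str, float], n_diploid: int = 21) -> dict[str, tuple[float, float]]:
    """Turn model-estimated population frequencies into diploid allele counts
    (2N copies per population) for the variance decomposition."""
    return {pid: (2.0 * n_diploid * f, 2.0 * n_diploid) for pid, f in freqs.items()}


def amova_fct(pop_allele_counts: Counts, grouping: Bipartition) -> float:
    """Among-group fixation index F_CT for one locus under a two-level grouping.

    The allele indicator (1 for allele A, 0 otherwise) is decomposed into
    among-group (sigma2_a), among-population-within-group (sigma2_b) and
    within-population (sigma2_c) components via expected mean squares;
    F_CT = sigma2_a / (sigma2_a + sigma2_b + sigma2_c).
    """
    groups = [sorted(grouping.group_a), sorted(grouping.group_b)]
    all_ids = groups[0] + groups[1]
    missing = [p for p in all_ids if p not in pop_allele_counts]
    if missing:
        raise ValueError(f"populations without counts: {missing}")
    c = np.array([pop_allele_counts[p][0] for p in all_ids], dtype=float)
    n = np.array([pop_allele_counts[p][1] for p in all_ids], dtype=float)
    if np.any(n <= 0):
        raise ValueError("total allele counts must be positive")
    sizes = np.array([len(groups[0]), len(groups[1])])
    gidx = np.repeat([0, 1], sizes)

    N = n.sum()
    C = c.sum()
    P, G = len(all_ids), 2
    Ng = np.array([n[gidx == g].sum() for g in range(G)])
    Cg = np.array([c[gidx == g].sum() for g in range(G)])

    ss_within = float(np.sum(c - c * c / n))
    pop_term = c * c / n
    ss_pop = float(sum(pop_term[gidx == g].sum() - Cg[g] ** 2 / Ng[g] for g in range(G)))
    ss_group = float(np.sum(Cg**2 / Ng) - C * C / N)

    df_c = N - P
    df_b = P - G
    df_a = G - 1

    sigma_c = ss_within / df_c if df_c > 0 else 0.0
    grp_n2 = float(sum((n[gidx == g] ** 2).sum() / Ng[g] for g in range(G)))
    if df_b > 0:
        n1 = (N - grp_n2) / df_b
        ms_b = ss_pop / df_b
        sigma_b = max((ms_b - sigma_c) / n1, 0.0)
    else:
        sigma_b = 0.0
    n2 = (grp_n2 - float(np.sum(n**2)) / N) / df_a
    n3 = (N - float(np.sum(Ng**2)) / N) / df_a
    ms_a = ss_group / df_a
    sigma_a = max((ms_a - sigma_c - n2 * sigma_b) / n3, 0.0)

    total = sigma_a + sigma_b + sigma_c
    return float(sigma_a / total) if total > 0 else 0.0


def _subset_sums(values: np.ndarray) -> np.ndarray:
    """sums[m] = sum of values[i] over bits i set in mask m, for all 2^P masks."""
    P = len(values)
    sums = np.zeros(1 << P)
    idx = np.arange(1 << P)
    for i in range(P):
        sums[(idx >> i) & 1 == 1] += values[i]
    return sums


def _fct_all_bipartitions(c: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """F_CT for every bipartition, vectorized over group-A bitmasks containing pop 0.

    Returns (masks, fct) where each mask encodes group A membership.
    """
    P = len(c)
    sc = _subset_sums(c)
    sn = _subset_sums(n)
    sq = _subset_sums(c * c / n)
    sn2 = _subset_sums(n * n)

    full = (1 << P) - 1
    idx = np.arange(1 << P)
    valid = ((idx & 1) == 1) & (idx != full)  # pop 0 anchored in group A; both nonempty
    mA = idx[valid]
    N, C = n.sum(), c.sum()
    snA, snB = sn[mA], N - sn[mA]
    scA, scB = sc[mA], C - sc[mA]
    sqA, sqB = sq[mA], sq[full] - sq[mA]
    sn2A, sn2B = sn2[mA], sn2[full] - sn2[mA]

    ss_within = float(np.sum(c - c * c / n))
    df_c = N - P
    sigma_c = ss_within / df_c if df_c > 0 else 0.0

    pop_between = scA**2 / snA + scB**2 / snB
    ss_pop = sqA + sqB - pop_between
    ss_group = pop_between - C * C / N
    grp_n2 = sn2A / snA + sn2B / snB

    df_b = P - 2
    if df_b > 0:
        n1 = (N - grp_n2) / df_b
        sigma_b = np.maximum((ss_pop / df_b - sigma_c) / n1, 0.0)
    else:
        sigma_b = np.zeros_like(ss_pop)
    n2c = grp_n2 - float(np.sum(n**2)) / N
    n3 = N - (snA**2 + snB**2) / N
    sigma_a = np.maximum((ss_group - sigma_c - n2c * sigma_b) / n3, 0.0)

    total = sigma_a + sigma_b + sigma_c
    with np.errstate(invalid="ignore", divide="ignore"):
        fct = np.where(total > 0, sigma_a / total, 0.0)
    return mA, fct


def _mask_to_bipartition(mask: int, pop_ids: Sequence[str]) -> Bipartition:
    a = [p for i, p in enumerate(pop_ids) if (mask >> i) & 1]
    b = [p for i, p in enumerate(pop_ids) if not (mask >> i) & 1]
    return Bipartition.of(a, b)


def samova_k2(
    pop_allele_counts: Counts,
    marker_id: str = "",
    mode: str = "exhaustive",
    seed: int = 0,
    n_steps: int = 2000,
) -> SamovaResult:
    """Two-group SAMOVA for one locus: the bipartition maximizing F_CT.

    Exhaustive mode enumerates all 2^(P-1) - 1 bipartitions and certifies the
    global optimum (ties broken by lexicographically smallest group A);
    annealing mode runs a seeded simulated-annealing search with
    single-population moves.
    """
    pop_ids = sorted(pop_allele_counts)
    P = len(pop_ids)
    if P < 3:
        raise ValueError("SAMOVA needs at least 3 populations")
    c = np.array([pop_allele_counts[p][0] for p in pop_ids], dtype=float)
    n = np.array([pop_allele_counts[p][1] for p in pop_ids], dtype=float)

    if mode == "exhaustive":
        masks, fct = _fct_all_bipartitions(c, n)
        best_val = fct.max()
        tied = masks[fct >= best_val - 1e-12]
        best_mask = min(
            (tuple(sorted(p for i, p in enumerate(pop_ids) if (m >> i) & 1)), int(m))
            for m in tied
        )[1]
        return SamovaResult(marker_id, _mask_to_bipartition(best_mask, pop_ids),
                            float(best_val), "exhaustive")

    if mode != "annealing":
        raise ValueError("mode must be 'exhaustive' or 'annealing'")

    rng = np.random.default_rng(seed)
    member = rng.integers(0, 2, size=P).astype(bool)
    if member.all() or not member.any():
        member[0] = ~member[0]

    def score(mem: np.ndarray) -> float:
        grouping = Bipartition.of(
            [p for p, m in zip(pop_ids, mem) if m],
            [p for p, m in zip(pop_ids, mem) if not m],
        )
        return amova_fct(pop_allele_counts, grouping)

    current = score(member)
    best_mem, best_val = member.copy(), current
    t0, t1 = 0.2, 1e-3
    for step in range(n_steps):
        temp = t0 * (t1 / t0) ** (step / max(n_steps - 1, 1))
        k = int(rng.integers(P))
        trial = member.copy()
        trial[k] = ~trial[k]
        if trial.all() or not trial.any():
            continue
        val = score(trial)
        if val >= current or rng.uniform() < np.exp((val - current) / temp):
            member, current = trial, val
            if current > best_val:
                best_mem, best_val = member.copy(), current
    return SamovaResult(
        marker_id,
        Bipartition.of(
            [p for p, m in zip(pop_ids, best_mem) if m],
            [p for p, m in zip(pop_ids, best_mem) if not m],
        ),
        float(best_val),
        "annealing",
    )


def samova_scan(
    pop_freqs: pd.DataFrame, n_diploid: int = 21, mode: str = "exhaustive", seed: int = 0
) -> list[SamovaResult]:
    """Locus-by-locus two-group SAMOVA over a loci x populations frequency table."""
    results = []
    for k, (marker_id, row) in enumerate(pop_freqs.iterrows()):
        counts = allele_counts_from_freqs(row.to_dict(), n_diploid)
        results.append(samova_k2(counts, str(marker_id), mode=mode, seed=seed + k))
    return results


def pca_ordination(table: pd.DataFrame, scaled: bool = False) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered (optionally unit-scaled) principal component ordination.

    Constant columns are dropped; returns row coordinates and the explained
    variance fractions.
    """
    X = table.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    keep = X.std(axis=0) > 0
    if not keep.any():
        raise ValueError("all columns are constant")
    X = X[:, keep]
    if scaled:
        X = (X - X.mean(axis=0)) / X.std(axis=0)
    pca = PCA(svd_solver="full")
    coords = pca.fit_transform(X)
    cols = [f"PC{k+1}" for k in range(coords.shape[1])]
    return pd.DataFrame(coords, index=table.index, columns=cols), pca.explained_variance_ratio_


def outlier_correlations(pop_freqs: pd.DataFrame, alpha: float = 0.05) -> AssociationMatrix:
    """Pairwise Pearson correlation of population allele frequencies across loci.

    All unordered locus pairs are tested and Holm-adjusted jointly; pairs with
    a constant frequency vector have no defined correlation and are skipped.
    """
    if pop_freqs.shape[1] < 3:
        raise ValueError("need at least 3 populations")
    if pop_freqs.shape[0] < 2:
        raise ValueError("need at least 2 loci")
    loci = list(pop_freqs.index.astype(str))
    X = pop_freqs.to_numpy(dtype=float)
    rows = []
    skipped: list[tuple[str, str]] = []
    for i in range(len(loci)):
        for j in range(i + 1, len(loci)):
            if X[i].std() == 0 or X[j].std() == 0:
                skipped.append((loci[i], loci[j]))
                continue
            r, p = stats.pearsonr(X[i], X[j])
            rows.append((loci[i], loci[j], float(r), float(p)))
    if skipped:
        warnings.warn(f"{len(skipped)} pairs skipped (constant frequencies)", stacklevel=2)
    pairs = pd.DataFrame(rows, columns=["locus_a", "locus_b", "r", "p"])
    if len(pairs):
        reject, p_adj, _, _ = multipletests(pairs["p"], alpha=alpha, method="holm")
        pairs["p_adj"] = p_adj
        pairs["significant"] = reject
    else:
        pairs["p_adj"] = pairs["significant"] = []
    counts = pd.Series(0, index=loci, dtype=int)
    for _, row in pairs[pairs["significant"] == True].iterrows():  # noqa: E712
        counts[row["locus_a"]] += 1
        counts[row["locus_b"]] += 1
    return AssociationMatrix(pairs=pairs, counts=counts, skipped=skipped)
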