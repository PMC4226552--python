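import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import aflpscan as a
from aflpscan.geo import (
    Bipartition,
    _fct_all_bipartitions,
    allele_counts_from_freqs,
    amova_fct,
    outlier_correlations,
    pca_ordination,
    samova_k2,
)


def _indicator_oracle_fct(counts, grouping):
    """F_CT from explicit 0/1 allele vectors via textbook nested sums of squares."""
    ys, pop_of, grp_of = [], [], []
    ordered = sorted(grouping.group_a) + sorted(grouping.group_b)
    for pid in ordered:
        c, n = counts[pid]
        y = [1.0] * int(round(c)) + [0.0] * int(round(n - c))
        ys.extend(y)
        pop_of.extend([pid] * len(y))
        grp_of.extend([pid in grouping.group_a] * len(y))
    y = np.array(ys)
    pop_of, grp_of = np.array(pop_of), np.array(grp_of)
    grand = y.mean()
    pops = list(dict.fromkeys(pop_of))
    groups = [True, False]
    ss_a = sum(
        (grp_of == g).sum() * (y[grp_of == g].mean() - grand) ** 2 for g in groups
    )
    ss_b = sum(
        (pop_of == p).sum() * (y[pop_of == p].mean() - y[grp_of == grp_of[pop_of == p][0]].mean()) ** 2
        for p in pops
    )
    ss_c = sum(((y[pop_of == p] - y[pop_of == p].mean()) ** 2).sum() for p in pops)
    N, P, G = len(y), len(pops), 2
    n_sizes = np.array([(pop_of == p).sum() for p in pops], dtype=float)
    g_sizes = np.array([(grp_of == g).sum() for g in groups], dtype=float)
    grp_n2 = sum(
        (n_sizes[[pops.index(p) for p in pops if (p in grouping.group_a) == g]] ** 2).sum()
        / g_sizes[groups.index(g)]
        for g in groups
    )
    sigma_c = ss_c / (N - P)
    n1 = (N - grp_n2) / (P - G)
    sigma_b = max((ss_b / (P - G) - sigma_c) / n1, 0.0)
    n2 = grp_n2 - (n_sizes**2).sum() / N
    n3 = N - (g_sizes**2).sum() / N
    sigma_a = max((ss_a - sigma_c - n2 * sigma_b) / n3, 0.0)
    tot = sigma_a + sigma_b + sigma_c
    return sigma_a / tot if tot > 0 else 0.0


class TestAmovaFct:
    def test_fixed_difference_between_groups(self):
        counts = {"p1": (0, 20), "p2": (0, 20), "p3": (20, 20), "p4": (20, 20)}
        split = Bipartition.of(["p1", "p2"], ["p3", "p4"])
        assert amova_fct(counts, split) == pytest.approx(1.0)

    def test_identical_populations_truncate_to_zero(self):
        counts = {f"p{i}": (10, 20) for i in range(4)}
        split = Bipartition.of(["p0", "p1"], ["p2", "p3"])
        assert amova_fct(counts, split) == 0.0

    def test_matches_indicator_vector_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            counts = {f"p{i}": (int(rng.integers(0, 21)), 20 + int(rng.integers(0, 10)))
                      for i in range(6)}
            k = int(rng.integers(1, 5))
            ids = list(counts)
            split = Bipartition.of(ids[:k], ids[k:])
            assert amova_fct(counts, split) == pytest.approx(
                _indicator_oracle_fct(counts, split), abs=1e-10
            )

    def test_invariant_under_group_swap_and_relabel(self):
        rng = np.random.default_rng(8)
        counts = {f"p{i}": (int(rng.integers(1, 20)), 20) for i in range(5)}
        split = Bipartition.of(["p0", "p3"], ["p1", "p2", "p4"])
        swapped = Bipartition.of(["p1", "p2", "p4"], ["p0", "p3"])
        assert amova_fct(counts, split) == pytest.approx(amova_fct(counts, swapped))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            Bipartition.of([], ["p1"])


class TestSamovaK2:
    def test_enumeration_count_four_pops(self):
        counts = {f"p{i}": (5 + i, 20) for i in range(4)}
        c = np.array([counts[f"p{i}"][0] for i in range(4)], dtype=float)
        n = np.array([counts[f"p{i}"][1] for i in range(4)], dtype=float)
        masks, fct = _fct_all_bipartitions(c, n)
        assert len(masks) == 7  # 2^(4-1) - 1 bipartitions

    def test_forced_split_recovered(self):
        counts = {"p1": (0, 20), "p2": (0, 20), "p3": (20, 20), "p4": (20, 20)}
        res = samova_k2(counts, "toy")
        assert res.fct == pytest.approx(1.0)
        assert res.best.group_a in ({"p1", "p2"}, {"p3", "p4"})

    def test_exhaustive_matches_brute_force(self):
        rng = np.random.default_rng(17)
        for trial in range(5):
            P = 7
            counts = {f"p{i}": (int(rng.integers(0, 25)), 24) for i in range(P)}
            res = samova_k2(counts, mode="exhaustive")
            best = -1.0
            ids = sorted(counts)
            for k in range(1, P):
                for combo in itertools.combinations(ids, k):
                    rest = [p for p in ids if p not in combo]
                    if not rest:
                        continue
                    best = max(best, amova_fct(counts, Bipartition.of(combo, rest)))
            assert res.fct == pytest.approx(best, abs=1e-12)

    def test_annealing_finds_exhaustive_optimum(self):
        rng = np.random.default_rng(23)
        hits = 0
        for trial in range(10):
            counts = {f"p{i}": (int(rng.integers(0, 21)), 20) for i in range(8)}
            exh = samova_k2(counts, mode="exhaustive")
            ann = samova_k2(counts, mode="annealing", seed=trial)
            hits += ann.fct == pytest.approx(exh.fct, abs=1e-9)
        assert hits == 10

    def test_too_few_populations_rejected(self):
        with pytest.raises(ValueError):
            samova_k2({"p1": (1, 2), "p2": (1, 2)})

    def test_annealing_is_seeded(self):
        counts = {f"p{i}": (i, 20) for i in range(6)}
        r1 = samova_k2(counts, mode="annealing", seed=4)
        r2 = samova_k2(counts, mode="annealing", seed=4)
        assert r1.fct == r2.fct and r1.best == r2.best


class TestPcaOrdination:
    def test_two_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 0.1, size=(20, 5))
        X[10:, 0] += 5.0
        coords, evr = pca_ordination(pd.DataFrame(X))
        pc1 = coords["PC1"].to_numpy()
        assert (pc1[:10].mean() < pc1[10:].mean()) or (pc1[:10].mean() > pc1[10:].mean())
        assert abs(pc1[:10].mean() - pc1[10:].mean()) > 3.0

    def test_explained_variance_sums_to_one(self):
        rng = np.random.default_rng(2)
        _, evr = pca_ordination(pd.DataFrame(rng.normal(size=(10, 4))))
        assert evr.sum() == pytest.approx(1.0)

    def test_matches_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 6))
        coords, _ = pca_ordination(pd.DataFrame(X))
        Xc = X - X.mean(axis=0)
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        expected = U * S
        for k in range(coords.shape[1]):
            col = coords.iloc[:, k].to_numpy()
            assert np.allclose(col, expected[:, k]) or np.allclose(col, -expected[:, k])

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pca_ordination(pd.DataFrame(np.ones((5, 3))))


class TestOutlierCorrelations:
    def test_duplicated_locus_perfectly_correlated(self):
        rng = np.random.default_rng(5)
        row = rng.uniform(size=8)
        freqs = pd.DataFrame([row, row, rng.uniform(size=8)], index=["L1", "L2", "L3"])
        assoc = outlier_correlations(freqs)
        pair = assoc.pairs.set_index(["locus_a", "locus_b"]).loc[("L1", "L2")]
        assert pair["r"] == pytest.approx(1.0)
        assert pair["significant"]

    def test_rejection_set_invariant_under_locus_reordering(self):
        rng = np.random.default_rng(21)
        freqs = pd.DataFrame(rng.uniform(size=(8, 9)), index=[f"L{i}" for i in range(8)])
        assoc = outlier_correlations(freqs, alpha=0.05)
        perm = freqs.sample(frac=1.0, random_state=3)
        assoc_perm = outlier_correlations(perm, alpha=0.05)

        def rejected(am):
            return {
                frozenset((row.locus_a, row.locus_b))
                for row in am.pairs.itertuples()
                if row.significant
            }

        assert rejected(assoc) == rejected(assoc_perm)

    def test_counts_match_pairwise_oracle(self):
        rng = np.random.default_rng(9)
        freqs = pd.DataFrame(rng.uniform(size=(20, 10)),
                             index=[f"L{i}" for i in range(20)])
        assoc = outlier_correlations(freqs, alpha=0.05)
        from scipy.stats import pearsonr
        from statsmodels.stats.multitest import multipletests

        pvals, pairs = [], []
        for i in range(20):
            for j in range(i + 1, 20):
                pvals.append(pearsonr(freqs.iloc[i], freqs.iloc[j]).pvalue)
                pairs.append((f"L{i}", f"L{j}"))
        reject, _, _, _ = multipletests(pvals, alpha=0.05, method="holm")
        expected = {f"L{i}": 0 for i in range(20)}
        for (la, lb), rej in zip(pairs, reject):
            if rej:
                expected[la] += 1
                expected[lb] += 1
        assert assoc.counts.to_dict() == expected

    def test_constant_rows_skipped_with_warning(self):
        freqs = pd.DataFrame(
            [[0.5] * 6, np.linspace(0.1, 0.9, 6), np.linspace(0.9, 0.1, 6)],
            index=["flat", "up", "down"],
        )
        with pytest.warns(UserWarning):
            assoc = outlier_correlations(freqs)
        assert ("flat", "up") in assoc.skipped

    def test_adjusted_p_not_below_raw(self):
        rng = np.random.default_rng(13)
        freqs = pd.DataFrame(rng.uniform(size=(6, 7)), index=[f"L{i}" for i in range(6)])
        assoc = outlier_correlations(freqs)
        assert (assoc.pairs["p_adj"] >= assoc.pairs["p"] - 1e-12).all()


@given(seed=st.integers(0, 1000))
def test_fct_between_zero_and_one(seed):
    rng = np.random.default_rng(seed)
    counts = {f"p{i}": (int(rng.integers(0, 21)), 20) for i in range(5)}
    split = Bipartition.of(["p0", "p1"], ["p2", "p3", "p4"])
    fct = amova_fct(counts, split)
    assert 0.0 <= fct <= 1.0


def test_allele_counts_from_freqs():
    counts = allele_counts_from_freqs({"p1": 0.5, "p2": 0.25}, n_diploid=10)
    assert counts["p1"] == (10.0, 20.0)
    assert counts["p2"] == (5.0, 20.0)
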