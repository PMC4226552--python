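import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate
from scipy.special import expit, logit

import aflpscan as a
from aflpscan.fmodel import (
    MixtureParams,
    ScanSettings,
    conditional_freq_density,
    fst_from_effects,
    genotype_probs,
    intensity_loglik,
    qvalues,
)
from aflpscan.io import AflpDataError


class TestFstFromEffects:
    def test_zero_effects_give_half(self):
        assert fst_from_effects(0.0, 0.0) == pytest.approx(0.5)

    def test_inverse_identity_at_study_mean(self):
        assert fst_from_effects(0.0, logit(0.31)) == pytest.approx(0.31)

    def test_matches_high_precision_logistic(self):
        assert fst_from_effects(-2.0, -2.0) == pytest.approx(float(expit(-4.0)), rel=1e-12)

    @given(alpha=st.floats(-30, 30), beta=st.floats(-30, 30))
    def test_always_in_open_interval(self, alpha, beta):
        f = fst_from_effects(alpha, beta)
        assert 0.0 < f < 1.0


class TestConditionalFreqDensity:
    def test_moments_match_beta_identities(self):
        a_, fst = 0.3, 0.2
        mean, _ = integrate.quad(lambda p: p * conditional_freq_density(p, a_, fst), 0, 1)
        ex2, _ = integrate.quad(lambda p: p * p * conditional_freq_density(p, a_, fst), 0, 1)
        assert mean == pytest.approx(a_, abs=1e-6)
        assert ex2 - mean**2 == pytest.approx(fst * a_ * (1 - a_), abs=1e-6)

    def test_integrates_to_one(self):
        total, _ = integrate.quad(lambda p: conditional_freq_density(p, 0.4, 0.3), 0, 1)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_small_fst_concentrates_at_ancestral(self):
        # theta -> infinity: nearly all mass within a narrow band around a
        mass, _ = integrate.quad(lambda p: conditional_freq_density(p, 0.3, 1e-4), 0.28, 0.32)
        assert mass > 0.99

    def test_degenerate_fst_rejected(self):
        with pytest.raises(ValueError):
            conditional_freq_density(0.5, 0.3, 0.0)


class TestGenotypeProbs:
    def test_hardy_weinberg(self):
        assert genotype_probs(0.5, 0.0) == pytest.approx((0.25, 0.5, 0.25))

    def test_full_inbreeding_removes_heterozygotes(self):
        hom, het, absent = genotype_probs(0.5, 1.0)
        assert het == 0.0 and hom == pytest.approx(0.5) and absent == pytest.approx(0.5)

    @given(p=st.floats(0, 1), f=st.floats(0, 1))
    def test_sums_to_one(self, p, f):
        assert sum(genotype_probs(p, f)) == pytest.approx(1.0, abs=1e-12)


class TestIntensityLoglik:
    MIX = MixtureParams(mu=1000.0, sigma_abs=60.0, sigma_het=150.0, sigma_hom=200.0)

    def test_component_mode_at_genotype_mean(self):
        at_mode = intensity_loglik(2000.0, "AA", self.MIX)
        assert at_mode > intensity_loglik(1800.0, "AA", self.MIX)
        assert at_mode > intensity_loglik(2200.0, "AA", self.MIX)

    def test_zero_intensity_prefers_absent_genotype(self):
        assert intensity_loglik(0.0, "aa", self.MIX) > intensity_loglik(0.0, "AA", self.MIX)

    @pytest.mark.parametrize("genotype", ["aa", "Aa", "AA"])
    def test_truncated_components_integrate_to_one(self, genotype):
        # all mass lies well below 5000 for these parameters
        total, _ = integrate.quad(
            lambda y: np.exp(intensity_loglik(y, genotype, self.MIX)),
            0,
            5000,
            points=[1000.0, 2000.0],
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_spread_rejected(self):
        with pytest.raises(ValueError):
            MixtureParams(mu=1000.0, sigma_abs=0.0, sigma_het=1.0, sigma_hom=1.0)


class TestQvalues:
    def test_worked_example(self):
        q = qvalues([0.99, 0.95, 0.5])
        assert q[1] == pytest.approx(0.03)  # mean of (0.01, 0.05) at rank 2
        assert q[0] == pytest.approx(0.01)

    def test_all_certain_gives_zero(self):
        assert np.all(qvalues([1.0, 1.0, 1.0]) == 0.0)

    def test_matches_cumulative_mean_oracle(self):
        rng = np.random.default_rng(7)
        g = rng.uniform(size=200)
        q = qvalues(g)
        order = np.argsort(-g)
        running, best = 0.0, []
        for k, idx in enumerate(order, start=1):
            running += 1.0 - g[idx]
            best.append(running / k)
        expected = np.maximum.accumulate(best)
        assert np.allclose(q[order], expected)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_output_in_unit_interval(self, gammas):
        q = qvalues(gammas)
        assert np.all((q >= 0) & (q <= 1))


class TestPosteriorOddsBijection:
    @given(g=st.floats(0.0, 0.999999))
    def test_round_trip(self, g):
        po = g / (1.0 - g)
        back = po / (1.0 + po)
        assert back == pytest.approx(g, abs=1e-6)

    def test_strong_evidence_boundary(self):
        # 10 of 11 retained samples in the selection model sits exactly at PO = 10
        g = 10 / 11
        assert g / (1 - g) == pytest.approx(10.0)
        # 4999 of 5000 retained samples gives the largest finite PO at this resolution
        g = 4999 / 5000
        assert g / (1 - g) == pytest.approx(4999.0)


class TestClassifyCalls:
    def _result(self, po, alpha_mean):
        g = po / (1 + po)
        return a.LocusResult("m", g, po, 0.0, 0.3, alpha_mean=alpha_mean)

    def test_threshold_and_sign_rules(self):
        results = [self._result(9.9, 2.0), self._result(12.0, 1.3), self._result(12.0, -0.8)]
        parts = a.classify_calls(results, po_threshold=10.0)
        assert [r.call for r in results] == ["neutral", "positive", "balancing"]
        assert len(parts["positive"]) == 1 and len(parts["balancing"]) == 1


class TestScanSettings:
    def test_defaults_follow_study_schedule(self):
        s = ScanSettings()
        assert (s.pilot_runs, s.pilot_length) == (20, 5000)
        assert (s.burn_in, s.samples, s.thinning) == (50000, 50000, 10)
        assert s.po_threshold == 10.0

    def test_thinning_must_divide_samples(self):
        with pytest.raises(ValueError):
            ScanSettings(samples=5001, thinning=10)


@pytest.fixture(scope="module")
def tiny_scan(small_matrix):
    ids = a.informative_markers(small_matrix)[:25]
    settings = ScanSettings(
        pilot_runs=2, pilot_length=150, burn_in=400, samples=600, thinning=10, seed=9
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return a.run_scan(small_matrix, ids, settings), ids, settings


class TestRunScan:
    def test_gamma_po_consistency(self, tiny_scan):
        (results, _), _, _ = tiny_scan
        for r in results:
            if r.gamma < 1:
                assert r.po == pytest.approx(r.gamma / (1 - r.gamma), abs=1e-9)
            else:
                assert np.isinf(r.po)
            assert 0 <= r.q_value <= 1
            assert 0 < r.fst_mean < 1

    def test_identical_seed_identical_output(self, small_matrix, tiny_scan):
        (results, _), ids, settings = tiny_scan
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            again, _ = a.run_scan(small_matrix, ids, settings)
        assert [r.gamma for r in again] == [r.gamma for r in results]
        assert [r.fst_mean for r in again] == [r.fst_mean for r in results]

    def test_single_population_rejected(self, small_matrix):
        mask = (small_matrix.samples["population_id"] == small_matrix.populations[0]).to_numpy()
        sub = a.IntensityMatrix(
            small_matrix.values.loc[mask].copy(), small_matrix.samples.loc[mask].copy()
        )
        with pytest.raises(AflpDataError):
            a.run_scan(sub, small_matrix.marker_ids[:5], ScanSettings.reduced())

    def test_manifest_records_schedule(self, tiny_scan):
        (_, manifest), _, settings = tiny_scan
        assert manifest["settings"]["seed"] == settings.seed
        assert manifest["n_retained_samples"] == settings.samples // settings.thinning
        assert len(manifest["pop_fst_mean"]) == manifest["n_populations"]
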