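"""Synthetic cohort generator: marginals, dependence, reproducibility."""

import numpy as np
import pytest
from scipy import stats

from comorbscreen import (SimulationDesign, simulate_cohort,
                          simulate_discordant_counts, synthetic_sample_table)
from comorbscreen.paired import mcnemar_pvalues


class TestDesignValidation:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SimulationDesign(n_pairs=10, pi1=1.0)
        with pytest.raises(ValueError):
            SimulationDesign(n_pairs=10, rho=1.0)
        with pytest.raises(ValueError):
            SimulationDesign(n_pairs=10, prevalence_range=(0.0, 0.1))
        with pytest.raises(ValueError):
            SimulationDesign(n_pairs=10, m_codes=0)

    def test_shortcut_requires_independence(self):
        with pytest.raises(ValueError, match="rho"):
            simulate_discordant_counts(SimulationDesign(n_pairs=10, rho=0.5))


class TestReproducibility:
    def test_same_seed_identical_cohort_bytes(self):
        d = SimulationDesign(n_pairs=100, m_codes=50, pi1=0.2, seed=13)
        c1, t1 = simulate_cohort(d)
        c2, t2 = simulate_cohort(d)
        assert c1.case_exposures.tobytes() == c2.case_exposures.tobytes()
        assert c1.control_exposures.tobytes() == c2.control_exposures.tobytes()
        assert np.array_equal(t1.psi, t2.psi)

    def test_different_seed_differs(self):
        d = SimulationDesign(n_pairs=100, m_codes=50, seed=13)
        d2 = SimulationDesign(n_pairs=100, m_codes=50, seed=14)
        assert simulate_cohort(d)[0].case_exposures.tobytes() != \
            simulate_cohort(d2)[0].case_exposures.tobytes()


class TestNullSymmetry:
    def test_null_codes_have_balanced_discordant_cells(self):
        d = SimulationDesign(n_pairs=20_000, m_codes=200, pi1=0.0,
                             prevalence_range=(0.02, 0.1), seed=5)
        n10, n01, _ = simulate_discordant_counts(d)
        ratio = n10.sum() / n01.sum()
        assert ratio == pytest.approx(1.0, rel=0.05)

    def test_zero_pairs_gives_zero_counts(self):
        d = SimulationDesign(n_pairs=0, m_codes=10, seed=1)
        n10, n01, _ = simulate_discordant_counts(d)
        assert n10.sum() == 0 and n01.sum() == 0


class TestParameterRecovery:
    def test_discordant_ratio_estimates_planted_psi(self):
        d = SimulationDesign(n_pairs=100_000, m_codes=1, pi1=0.9,
                             log_or=np.log(60.0),
                             prevalence_range=(0.01, 0.0100001), seed=3)
        n10, n01, truth = simulate_discordant_counts(d)
        assert truth.psi[0] == pytest.approx(60.0)
        assert n10[0] / n01[0] == pytest.approx(60.0, rel=0.2)

    def test_relative_error_shrinks_with_sample_size(self):
        def median_rel_error(n_pairs, seed):
            d = SimulationDesign(n_pairs=n_pairs, m_codes=400, pi1=0.5,
                                 log_or=np.log(3.0),
                                 prevalence_range=(0.05, 0.1), seed=seed)
            n10, n01, truth = simulate_discordant_counts(d)
            eff = ~truth.is_null & (n01 > 0)
            est = n10[eff] / n01[eff]
            return np.median(np.abs(est - 3.0) / 3.0)

        err_small = median_rel_error(1_000, seed=21)
        err_big = median_rel_error(10_000, seed=21)
        assert err_big < err_small / 2 + 0.01


class TestDependence:
    def test_rho_zero_cross_code_correlations_vanish(self):
        d = SimulationDesign(n_pairs=10_000, m_codes=30, rho=0.0,
                             prevalence_range=(0.2, 0.4), seed=8)
        cohort, _ = simulate_cohort(d)
        r = np.corrcoef(cohort.control_exposures.T)
        off = r[np.triu_indices_from(r, k=1)]
        assert np.abs(off).max() < 0.04

    def test_block_rho_induces_within_block_correlation(self):
        d = SimulationDesign(n_pairs=10_000, m_codes=20, block_size=10,
                             rho=0.7, prevalence_range=(0.2, 0.4), seed=8)
        cohort, _ = simulate_cohort(d)
        r = np.corrcoef(cohort.control_exposures.T)
        within = r[:10, :10][np.triu_indices(10, k=1)]
        across = r[:10, 10:]
        assert within.mean() > 0.15
        assert abs(across.mean()) < 0.03

    def test_fast_path_distributionally_matches_full_path(self):
        """Mean discordant counts agree within Monte-Carlo error."""
        base = dict(n_pairs=1_000, m_codes=100, pi1=0.3, log_or=np.log(2.5),
                    prevalence_range=(0.05, 0.1))
        sums_fast = np.zeros(2)
        sums_full = np.zeros(2)
        reps = 60
        for r in range(reps):
            n10f, n01f, _ = simulate_discordant_counts(
                SimulationDesign(**base, seed=1000 + r))
            cohort, _ = simulate_cohort(SimulationDesign(**base, seed=1000 + r))
            n10c, n01c = cohort.discordant_counts()
            sums_fast += (n10f.mean(), n01f.mean())
            sums_full += (n10c.mean(), n01c.mean())
        assert np.allclose(sums_fast / reps, sums_full / reps, rtol=0.05)


def test_null_mcnemar_pvalues_approximately_uniform():
    """KS distance of null p-values from U(0,1) stays below 0.05."""
    d = SimulationDesign(n_pairs=2_000, m_codes=1_000, pi1=0.0,
                         prevalence_range=(0.02, 0.1), seed=17)
    n10, n01, _ = simulate_discordant_counts(d)
    _, p = mcnemar_pvalues(n10, n01, mode="auto")
    ks = stats.kstest(p, "uniform").statistic
    assert ks < 0.05


class TestSyntheticSampleTable:
    def test_planted_significance_structure(self):
        df = synthetic_sample_table(seed=0)
        assert len(df) == 1239
        assert df["p_value"].between(0, 1).all()
        assert (df["odds_ratio"] > 0).all()
        assert df["code_group"].is_unique

    def test_structure_parameters_respected(self):
        df = synthetic_sample_table(seed=3, n_codes=50, n_significant=20,
                                    n_relevant=12)
        from comorbscreen.multtest import PValueSet, by
        res = by(PValueSet(df["code_group"], df["p_value"]), 0.05)
        assert res.n_rejected == 20
        assert int((res.rejected & (df["odds_ratio"].to_numpy() > 1)).sum()) == 12
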