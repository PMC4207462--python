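"""Telegraph turnover model: parameterization, moments, ACF, exact simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from teleflux.turnover import (
    GeneExpressionState,
    HorizonError,
    InvalidObservableError,
    NoStationaryStateError,
    TurnoverObservables,
    TurnoverParams,
    UnreachableMeanError,
    half_autocorrelation_time,
    params_from_observables,
    protein_acf,
    sample_stationary_state,
    simulate_expression,
    stationary_moments,
)

LN2 = math.log(2.0)


class TestParamsFromObservables:
    def test_standard_model_rates(self, standard_observables):
        p = params_from_observables(standard_observables)
        assert p.k_off == pytest.approx(10.0)
        assert p.k_on == pytest.approx(1 / 2.6)
        assert p.gamma_m == pytest.approx(LN2 / 9.0)
        assert p.gamma_p == pytest.approx(LN2 / 27.0)
        # synthesis rates solve the stationary-mean identities
        assert p.k_m == pytest.approx(35.35, rel=1e-3)
        assert p.k_p == pytest.approx(1.510, rel=1e-3)

    def test_roundtrip_reproduces_means(self, standard_observables):
        mom = stationary_moments(params_from_observables(standard_observables))
        assert mom.mean_mrna == pytest.approx(17.0)
        assert mom.mean_protein == pytest.approx(1000.0)

    def test_symmetric_switching_gives_half_on_fraction(self):
        obs = TurnoverObservables(
            mean_protein=10.0, mean_mrna=2.0, protein_half_life=1.0,
            mrna_half_life=1.0, t_on=3.0, t_off=3.0,
        )
        assert params_from_observables(obs).on_fraction == pytest.approx(0.5)

    def test_never_on_gene_with_positive_mean_is_unreachable(self):
        obs = TurnoverObservables(
            mean_protein=10.0, mean_mrna=2.0, protein_half_life=1.0,
            mrna_half_life=1.0, t_on=1.0, t_off=math.inf,
        )
        with pytest.raises(UnreachableMeanError):
            params_from_observables(obs)

    @pytest.mark.parametrize("bad", ["mean_protein", "mrna_half_life", "t_on"])
    def test_nonpositive_observable_rejected(self, bad):
        kwargs = dict(
            mean_protein=10.0, mean_mrna=2.0, protein_half_life=1.0,
            mrna_half_life=1.0, t_on=1.0, t_off=1.0,
        )
        kwargs[bad] = 0.0
        with pytest.raises(InvalidObservableError):
            TurnoverObservables(**kwargs)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        mean_p=st.floats(1.0, 1e5),
        mean_m=st.floats(0.5, 100.0),
        hl_p=st.floats(0.1, 100.0),
        hl_m=st.floats(0.1, 50.0),
        t_on=st.floats(0.05, 30.0),
        t_off=st.floats(0.05, 30.0),
    )
    def test_roundtrip_property(self, mean_p, mean_m, hl_p, hl_m, t_on, t_off):
        obs = TurnoverObservables(mean_p, mean_m, hl_p, hl_m, t_on, t_off)
        p = params_from_observables(obs)
        assert 0.0 <= p.on_fraction <= 1.0
        mom = stationary_moments(p)
        assert mom.mean_protein == pytest.approx(mean_p, rel=1e-9)
        assert mom.mean_mrna == pytest.approx(mean_m, rel=1e-9)
        assert mom.var_mrna >= 0 and mom.var_protein >= 0


class TestStationaryMoments:
    def test_zero_transcription_gives_zero_moments(self):
        p = TurnoverParams(1.0, 1.0, 0.0, 1.0, 1.0, 1.0)
        mom = stationary_moments(p)
        assert mom.mean_mrna == 0 and mom.var_mrna == 0
        assert mom.mean_protein == 0 and mom.var_protein == 0

    def test_standard_model_mrna_cv(self, standard_params):
        # 1/<m> + ((1-f)/f) * gamma_m / (k_on + k_off + gamma_m)
        assert stationary_moments(standard_params).cv_mrna == pytest.approx(0.50, abs=0.005)

    def test_standard_model_protein_cv_pinned_by_ssa(self, standard_params):
        # value pinned by the Gillespie oracle (and printed for this model)
        assert stationary_moments(standard_params).cv_protein == pytest.approx(
            0.2508, abs=0.002
        )

    def test_no_stationary_state_without_degradation(self):
        with pytest.raises(NoStationaryStateError):
            stationary_moments(TurnoverParams(1.0, 1.0, 1.0, 0.0, 1.0, 1.0))
        with pytest.raises(NoStationaryStateError):
            stationary_moments(TurnoverParams(1.0, 1.0, 1.0, 1.0, 1.0, 0.0))

    def test_locked_on_promoter_mrna_is_poissonian(self):
        # k_off = 0, promoter ON: Fano factor of mRNA equals 1
        p = TurnoverParams(5.0, 0.0, 8.0, 0.5, 1.0, 0.1)
        mom = stationary_moments(p)
        assert mom.var_mrna / mom.mean_mrna == pytest.approx(1.0, abs=1e-9)


def _acf_closed_form(p: TurnoverParams, tau: float) -> float:
    """Independent three-exponential closed form (distinct rates assumed)."""
    lam = p.k_on + p.k_off
    mom = stationary_moments(p)
    c_g, c_m, c_p = mom.cov_promoter_protein, mom.cov_mrna_protein, mom.var_protein
    A = p.k_m * c_g / (p.gamma_m - lam)
    B = c_m - A
    a = p.k_p * A / (p.gamma_p - lam)
    b = p.k_p * B / (p.gamma_p - p.gamma_m)
    c = c_p - a - b
    val = a * math.exp(-lam * tau) + b * math.exp(-p.gamma_m * tau) + c * math.exp(-p.gamma_p * tau)
    return val / c_p


class TestProteinAcf:
    def test_normalization_and_decay(self, standard_params):
        assert protein_acf(standard_params, 0.0) == pytest.approx(1.0)
        assert protein_acf(standard_params, 2000.0) == pytest.approx(0.0, abs=1e-6)

    def test_negative_lag_rejected(self, standard_params):
        with pytest.raises(ValueError):
            protein_acf(standard_params, -1.0)

    def test_matches_independent_closed_form(self, standard_params, short_lived_slow_switching):
        for p in (standard_params, short_lived_slow_switching,
                  TurnoverParams(0.8, 1.3, 20.0, 0.4, 2.0, 0.05)):
            for tau in (0.5, 2.0, 10.0, 40.0):
                assert protein_acf(p, tau) == pytest.approx(
                    _acf_closed_form(p, tau), rel=1e-8
                )

    def test_single_exponential_limit(self):
        # instantaneous mRNA and fast switching: ACF -> exp(-gamma_p t)
        p = TurnoverParams(500.0, 500.0, 5e4, 200.0, 10.0, 0.1)
        for tau in (1.0, 5.0, 20.0):
            assert protein_acf(p, tau) == pytest.approx(math.exp(-0.1 * tau), abs=0.01)

    def test_monotone_decay_on_grid(self, standard_params):
        lags = np.linspace(0, 200, 60)
        acf = protein_acf(standard_params, lags)
        assert np.all(np.diff(acf) <= 1e-12)
        assert np.all(acf <= 1.0) and np.all(acf >= -1.0)


class TestHalfAutocorrelationTime:
    def test_single_exponential_limit_equals_protein_half_life(self):
        p = TurnoverParams(500.0, 500.0, 5e4, 200.0, 10.0, LN2 / 8.0)
        assert half_autocorrelation_time(p) == pytest.approx(8.0, abs=0.1)

    def test_standard_long_lived_model(self, standard_params):
        # numeric root of the derived ACF for the 27 h / 9 h model
        assert half_autocorrelation_time(standard_params) == pytest.approx(41.2, abs=0.1)

    def test_short_lived_fast_switching_is_fast(self):
        p = params_from_observables(
            TurnoverObservables(1000.0, 17.0, 0.4, 1.0, 0.1, 2.6)
        )
        t_half = half_autocorrelation_time(p)
        assert 0.3 < t_half < 3.0

    def test_horizon_error(self, standard_params):
        with pytest.raises(HorizonError):
            half_autocorrelation_time(standard_params, horizon=1.0)


class TestSimulateExpression:
    def test_pure_decay_without_transcription(self):
        p = TurnoverParams(0.0, 0.0, 0.0, 1.0, 2.0, 0.5)
        traj = simulate_expression(p, GeneExpressionState(False, 0, 100.0), 4.0, seed=1)
        assert traj["protein"].iloc[-1] == pytest.approx(100.0 * math.exp(-0.5 * 4.0))
        assert (traj["mrna"] == 0).all()

    def test_seeded_determinism(self, standard_params):
        init = GeneExpressionState(False, 17, 1000.0)
        a = simulate_expression(standard_params, init, 50.0, seed=7)
        b = simulate_expression(standard_params, init, 50.0, seed=7)
        assert a.equals(b)
        c = simulate_expression(standard_params, init, 50.0, seed=8)
        assert not a.equals(c)

    def test_locked_on_promoter_mrna_poisson_distribution(self):
        # k_off = 0: stationary mRNA ~ Poisson(k_m / gamma_m)
        p = TurnoverParams(100.0, 0.0, 8.0, 1.0, 0.0, 1.0)
        n = 3000
        ends = [
            simulate_expression(p, GeneExpressionState(True, 8, 0.0), 15.0, seed=s)[
                "mrna"
            ].iloc[-1]
            for s in range(n)
        ]
        ends = np.asarray(ends)
        lam = 8.0
        assert ends.mean() == pytest.approx(lam, abs=3 * math.sqrt(lam / n))
        # goodness of fit against the Poisson pmf
        kmax = int(ends.max())
        observed = np.bincount(ends.astype(int), minlength=kmax + 1)
        expected = stats.poisson.pmf(np.arange(kmax + 1), lam) * n
        keep = expected > 5
        chi2 = np.sum((observed[keep] - expected[keep]) ** 2 / expected[keep])
        dof = keep.sum() - 1
        assert chi2 < stats.chi2.ppf(0.999, dof)


class TestSampleStationaryState:
    def test_permanently_off_gene(self):
        p = TurnoverParams(0.0, 1.0, 5.0, 1.0, 1.0, 0.5)
        for s in sample_stationary_state(p, 10, seed=0):
            assert not s.promoter_on and s.mrna == 0 and s.protein == 0.0

    def test_on_fraction_within_binomial_ci(self, standard_params):
        n = 4000
        states = sample_stationary_state(standard_params, n, seed=11)
        on = np.mean([s.promoter_on for s in states])
        f = standard_params.on_fraction
        assert abs(on - f) < 3.5 * math.sqrt(f * (1 - f) / n)

    def test_protein_cv_matches_moments(self, standard_params):
        n = 3000
        states = sample_stationary_state(standard_params, n, seed=3)
        prot = np.array([s.protein for s in states])
        mom = stationary_moments(standard_params)
        se_mean = math.sqrt(mom.var_protein / n)
        assert abs(prot.mean() - mom.mean_protein) < 3 * se_mean
        cv_emp = prot.std() / prot.mean()
        # CV standard error approx cv/sqrt(2n), generous factor for skewness
        assert abs(cv_emp - mom.cv_protein) < 5 * mom.cv_protein / math.sqrt(2 * n)
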