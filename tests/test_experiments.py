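"""Experiment protocols and quantifications (on synthetic records and toy networks)."""

import numpy as np
import pandas as pd
import pytest

from teleflux.earm import FateDetectorConfig
from teleflux.experiments import (
    BinningError,
    EmptyInputError,
    MissingReferenceError,
    MompStatistics,
    RepeatedTrailConfig,
    SisterExperimentConfig,
    UndefinedAnalysisError,
    UndefinedCurveError,
    agreement_score,
    determinants_analysis,
    grid_scan,
    momp_statistics,
    recovery_curve,
    run_repeated_trail,
    run_sister_experiment,
    sister_correlation_curve,
)
from teleflux.fixtures import cascade_network
from teleflux.hybrid import SolverConfig


def _records(momp_times, division_times=None):
    """Synthetic paired records: momp_times is a list of (t1, t2) per pair."""
    division_times = division_times or [0.0] * len(momp_times)
    rows = []
    for i, ((t1, t2), td) in enumerate(zip(momp_times, division_times)):
        for j, t in enumerate((t1, t2)):
            rows.append(
                {
                    "cell_id": 2 * i + j,
                    "pair_id": i,
                    "sister_id": 2 * i + 1 - j,
                    "division_time": td,
                    "momp_time": t,
                    "death_time": t,
                    "fate": "survived" if t is None or np.isnan(t) else "died",
                }
            )
    return pd.DataFrame(rows)


def _cz_death(frame):
    """Death detector for the cascade toy: half the substrate pool cleaved."""
    frac = frame["cZ"] / (frame["cZ"] + frame["Z"])
    above = frac >= 0.5
    if not above.any():
        return None
    k = int(np.argmax(above.to_numpy()))
    return float(frame["time"].iloc[k])


class TestMompStatistics:
    def test_all_cells_momp(self):
        recs = _records([(1.0, 2.0), (3.0, 4.0)])
        stats = momp_statistics(recs, bin_width=1.0, observation=8.0)
        assert stats.surviving_fraction == 0.0
        assert stats.counts.sum() == 4

    def test_no_cell_momp(self):
        recs = _records([(np.nan, np.nan)])
        stats = momp_statistics(recs, bin_width=1.0, observation=8.0)
        assert stats.surviving_fraction == 1.0
        assert stats.counts.sum() == 0

    def test_counts_sum_to_momp_positive_cells(self):
        recs = _records([(1.0, np.nan), (2.5, 3.5), (np.nan, 7.9)])
        stats = momp_statistics(recs, bin_width=0.5, observation=8.0)
        assert stats.counts.sum() == 4
        assert stats.surviving_fraction == pytest.approx(2 / 6)

    def test_empty_input(self):
        with pytest.raises(EmptyInputError):
            momp_statistics(pd.DataFrame(columns=["momp_time"]))


class TestSisterCorrelationCurve:
    def test_identical_sisters_give_unit_correlation(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(2, 6, size=300)
        recs = _records(list(zip(t, t)), division_times=list(rng.uniform(-20, 0, 300)))
        curve = sister_correlation_curve(recs, min_pairs=20)
        assert (curve["correlation"] > 0.999).all()

    def test_independent_sisters_give_near_zero_correlation(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(2, 6, 4000), rng.uniform(2, 6, 4000)
        recs = _records(list(zip(a, b)), division_times=list(rng.uniform(-20, 0, 4000)))
        curve = sister_correlation_curve(recs, min_pairs=100)
        # edge bins carry a selection artifact (conditioning on the pair mean),
        # so the check targets the central tendency of the curve
        assert np.median(np.abs(curve["correlation"])) < 0.08
        assert np.abs(curve["correlation"]).mean() < 0.12

    def test_no_complete_pairs_is_undefined(self):
        recs = _records([(1.0, np.nan), (np.nan, 2.0)])
        with pytest.raises(UndefinedCurveError):
            sister_correlation_curve(recs)


class TestAgreementScore:
    def _stats(self, counts, surviving, n):
        edges = np.arange(len(counts) + 1, dtype=float)
        return MompStatistics(edges, np.asarray(counts), surviving, n)

    def test_identity_and_symmetry(self):
        a = self._stats([5, 3, 2], 0.2, 10)
        b = self._stats([4, 4, 2], 0.3, 10)
        assert agreement_score(a, a) == 0.0
        assert agreement_score(a, b) == agreement_score(b, a) > 0.0

    def test_single_bin_perturbation_increases_score(self):
        a = self._stats([5, 3, 2], 0.2, 10)
        for k in range(3):
            counts = [5, 3, 2]
            counts[k] += 1
            assert agreement_score(a, self._stats(counts, 0.2, 10)) > 0.0

    def test_mismatched_binning_rejected(self):
        a = self._stats([5, 3], 0.2, 10)
        b = self._stats([5, 3, 2], 0.2, 10)
        with pytest.raises(BinningError):
            agreement_score(a, b)


class TestDeterminants:
    def test_survivors_equal_population_gives_unit_ratios(self):
        rng = np.random.default_rng(2)
        pop = pd.DataFrame({"level_A": rng.lognormal(1, 0.5, 200),
                            "promoter_A": rng.random(200) < 0.3})
        res = determinants_analysis(pop, np.ones(200, dtype=bool), seed=0,
                                    n_permutations=200)
        assert res["ratio"].to_numpy() == pytest.approx(1.0)
        assert not res["significant"].any()

    def test_constructed_doubled_level_is_detected(self):
        rng = np.random.default_rng(3)
        n = 400
        mask = np.zeros(n, dtype=bool)
        mask[:100] = True
        base = rng.lognormal(2.0, 0.3, n)
        level_a = np.where(mask, 2 * base, base)
        pop = pd.DataFrame({"level_A": level_a, "level_B": rng.lognormal(2, 0.3, n)})
        res = determinants_analysis(pop, mask, seed=1, n_permutations=2000).set_index("feature")
        assert res.loc["level_A", "ratio"] == pytest.approx(
            level_a[mask].mean() / level_a.mean(), rel=1e-9
        )
        assert 1.5 < res.loc["level_A", "ratio"] < 2.0
        assert res.loc["level_A", "significant_bh"]
        assert not res.loc["level_B", "significant"]

    def test_empty_survivor_set_rejected(self):
        pop = pd.DataFrame({"level_A": [1.0, 2.0]})
        with pytest.raises(UndefinedAnalysisError):
            determinants_analysis(pop, np.zeros(2, dtype=bool))

    def test_null_calibration_flag_rate(self):
        """Fate independent of state: per-feature flags fire at ~alpha."""
        rng = np.random.default_rng(4)
        n, k = 300, 40
        pop = pd.DataFrame(
            {f"level_{i}": rng.lognormal(0, 1, n) for i in range(k)}
        )
        mask = rng.random(n) < 0.4
        res = determinants_analysis(pop, mask, seed=5, n_permutations=800)
        rate = res["significant"].mean()
        # 3 binomial SDs around 5% for k=40 features
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / k)


class TestRecoveryCurve:
    def _net(self):
        return cascade_network()

    def test_reference_at_mean_gives_flat_expectation(self):
        net = self._net()
        naive = pd.DataFrame({"level_I": [300.0] * 10, "level_pX": [500.0] * 10,
                              "level_Z": [1000.0] * 10})
        days = {0: naive.copy(), 1.0: naive.copy()}
        curve = recovery_curve(days, naive, net)
        assert curve["expected_ratio"].to_numpy() == pytest.approx(1.0)

    def test_half_life_relaxation_from_zero(self):
        net = self._net()
        naive = pd.DataFrame({"level_I": [300.0] * 5, "level_pX": [500.0] * 5,
                              "level_Z": [1000.0] * 5})
        zero = naive.copy()
        zero["level_pX"] = 0.0
        # one protein half-life after a full depletion: expectation = mean/2
        hl_days = 27.0 / 24.0
        curve = recovery_curve({0: zero, hl_days: zero}, naive, net)
        px = curve[(curve.protein == "pX") & (curve.day == hl_days)]
        assert px["expected_ratio"].iloc[0] == pytest.approx(0.5, abs=1e-9)

    def test_missing_reference_day(self):
        net = self._net()
        naive = pd.DataFrame({"level_I": [300.0]})
        with pytest.raises(MissingReferenceError):
            recovery_curve({1.0: naive}, naive, net)


@pytest.fixture(scope="module")
def cascade_records():
    """Small sister experiment on the cascade toy (synthesis blocked)."""
    net = cascade_network()
    cfg = SisterExperimentConfig(dose=100.0, chx=True, division_window=0.0,
                                 n_pairs=12, observation=6.0)
    return run_sister_experiment(
        net, cfg, seed=17, momp_detector=_cz_death, death_detector=_cz_death,
        solver=SolverConfig(grid=0.1),
    )


class TestProtocols:
    def test_blocked_duplicates_have_identical_fates(self, cascade_records):
        """Division at treatment + synthesis blockade: sisters are deterministic
        copies, so MOMP-analog times must coincide exactly."""
        for _, pair in cascade_records.groupby("pair_id"):
            t = pair["momp_time"].to_numpy()
            assert (np.isnan(t).all()) or t[0] == pytest.approx(t[1], rel=1e-5)

    def test_shuffled_pairing_destroys_correlation(self):
        """Correct pairing yields the sister correlation; random re-pairing
        (a permutation null) destroys it."""
        rng = np.random.default_rng(0)
        t = rng.uniform(2, 6, size=400)
        a, b = t, t + rng.normal(0, 0.05, size=400)  # near-identical sisters
        paired = np.corrcoef(a, b)[0, 1]
        shuffled = np.corrcoef(a, rng.permutation(b))[0, 1]
        assert paired > 0.99
        assert abs(shuffled) < 0.15

    def test_cascade_inhibitor_raises_survival(self):
        """Ten-fold higher inhibitor mean: survivor-analog fraction goes up."""
        results = {}
        for mean in (30.0, 3000.0):
            net = cascade_network(inhibitor_mean=mean)
            cfg = SisterExperimentConfig(dose=100.0, chx=False, division_window=0.0,
                                         n_pairs=10, observation=6.0)
            recs = run_sister_experiment(
                net, cfg, seed=23, momp_detector=_cz_death,
                death_detector=_cz_death, solver=SolverConfig(grid=0.1),
            )
            results[mean] = np.mean(recs["fate"] == "survived")
        assert results[3000.0] > results[30.0]

    def test_repeated_trail_zero_second_dose(self):
        """No second treatment: both survivals 1, gain 1."""
        net = cascade_network(inhibitor_mean=3000.0)  # benign first dose
        cfg = RepeatedTrailConfig(first_dose=0.0, second_dose=0.0,
                                  intervals=(1.0,), n_cells=4, assay_window=4.0)
        res = run_repeated_trail(net, cfg, seed=3, death_detector=_cz_death,
                                 solver=SolverConfig(grid=0.1))
        row = res.iloc[0]
        assert row["pretreated_survival"] == 1.0
        assert row["naive_survival"] == 1.0
        assert row["resistance_gain"] == pytest.approx(1.0)

    def test_grid_scan_is_seed_deterministic_and_self_consistent(self, cascade_records):
        data_stats = momp_statistics(cascade_records, bin_width=1.0, observation=6.0)
        cfg = SisterExperimentConfig(dose=100.0, chx=True, division_window=0.0,
                                     n_pairs=6, observation=6.0)

        def factory(inhibitor_mean):
            return cascade_network(inhibitor_mean=inhibitor_mean)

        grid = [{"inhibitor_mean": 300.0}, {"inhibitor_mean": 3000.0}]
        kwargs = dict(momp_detector=_cz_death, death_detector=_cz_death,
                      bin_width=1.0, solver=SolverConfig(grid=0.1))
        a = grid_scan(factory, grid, data_stats, cfg, seed=41, **kwargs)
        b = grid_scan(factory, grid, data_stats, cfg, seed=41, **kwargs)
        assert (a["error"] == "").all()
        assert np.isfinite(a["both"]).all()
        assert a["both"].to_numpy() == pytest.approx(b["both"].to_numpy())
        # the matched condition scores better than the mismatched one
        assert a.loc[0, "both"] <= a.loc[1, "both"]

    def test_grid_scan_empty_grid_rejected(self, cascade_records):
        data_stats = momp_statistics(cascade_records, bin_width=1.0, observation=6.0)
        cfg = SisterExperimentConfig(dose=100.0, chx=True, n_pairs=2, observation=6.0)
        with pytest.raises(ValueError):
            grid_scan(lambda: None, [], data_stats, cfg, seed=0)
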