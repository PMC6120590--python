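"""Kinship similarity, partition ratios, turnover math and the R^2 decomposition."""

import numpy as np
import pandas as pd
import pytest

from oct4lineage.inheritance import (
    AlignedPairSet,
    DecayModel,
    align_mother_daughter,
    asymmetry_contribution,
    autocorrelation_mixing_time,
    dapi_vs_oct4_ratios,
    division_distance_correlation,
    fit_half_life,
    kinship_differences,
    maternal_fraction,
    mixing_rank_plot,
    r2_decomposition,
    ratio_extremity_fractions,
    ratio_persistence,
    sister_ratios,
)
from oct4lineage.lineage import build_forest, summarize_cells
from oct4lineage.simulate import (
    GeneratorConfig,
    calibrate_partition_distribution,
    simulate_lineages,
    sister_endpoint_table,
)

from conftest import make_track_df

NO_PARTITION = ((5 / 6, 0.0), (3 / 4, 0.0), (1 / 2, 0.0))


def quiet_config(**overrides):
    """Generator with all division-introduced and dynamic noise disabled."""
    base = dict(
        partition_targets=NO_PARTITION,
        setpoint_drift_sd=0.0,
        partition_setpoint_coupling=0.0,
        ou_sd_afu=0.0,
        pulser_fraction=0.0,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


class TestKinshipDifferences:
    def test_identical_levels_give_zero_diffs(self):
        cells = {
            "A": (None, 0, [1000] * 2), "B": ("A", 2, [1000] * 2), "C": ("A", 2, [1000] * 2),
            "D": ("B", 4, [1000]), "E": ("B", 4, [1000]),
            "X": (None, 0, [1000] * 2), "Y": ("X", 2, [1000]), "Z": ("X", 2, [1000]),
        }
        f = build_forest(make_track_df(cells))
        kd = kinship_differences(f, summarize_cells(f), seed=0)
        for cat, vals in kd.diffs.items():
            assert np.all(vals == 0), cat

    def test_two_generation_manual_enumeration(self):
        cells = {
            "A": (None, 0, [1] * 2),
            "B": ("A", 2, [1100] * 2), "C": ("A", 2, [1400] * 2),
            "D": ("B", 4, [1000]), "E": ("B", 4, [1200]),
            "F": ("C", 4, [1500]), "G": ("C", 4, [1300]),
        }
        f = build_forest(make_track_df(cells))
        kd = kinship_differences(f, summarize_cells(f), seed=0)
        # complete cells: B (1100) and C (1400) only -> one sister pair
        assert list(kd.diffs["sister"]) == [300.0]
        assert len(kd.diffs["cousin"]) == 0  # D..G are censored leaves

    def test_similarity_ordering_on_heritable_synthetic(
        self, undisturbed_forest
    ):
        kd = kinship_differences(
            undisturbed_forest, summarize_cells(undisturbed_forest), seed=0
        )
        med = kd.medians()
        assert med["sister"] < med["cousin"] < med["second_cousin"] < med["random"]
        assert not kd.ks_report.empty


class TestDivisionDistanceCorrelation:
    def test_degenerate_levels_return_zero_with_diagnostic(self):
        cells = {
            "A": (None, 0, [5] * 2), "B": ("A", 2, [5] * 2), "C": ("A", 2, [5] * 2),
            "D": ("B", 4, [5]), "E": ("B", 4, [5]),
        }
        f = build_forest(make_track_df(cells))
        rho, p, n = division_distance_correlation(f, summarize_cells(f))
        assert rho == 0.0 and np.isnan(p)

    def test_generational_drift_gives_positive_correlation(self, undisturbed_forest):
        rho, p, n = division_distance_correlation(
            undisturbed_forest, summarize_cells(undisturbed_forest)
        )
        assert rho > 0.05
        assert p < 1e-4

    def test_no_drift_gives_null_correlation(self):
        """With setpoint drift, partition asymmetry and coupling disabled,
        and protein memory made short (so the inherited birth level decays
        before contributing to the lifetime mean), relatedness carries no
        level information."""
        cfg = quiet_config(ou_sd_afu=60.0, half_life_h=0.5)
        ds = simulate_lineages(cfg, 20, seed=7, design="undisturbed")
        f = ds.forest()
        rho, p, n = division_distance_correlation(f, summarize_cells(f))
        assert abs(rho) < 0.05


class TestSisterRatios:
    def test_first_frame_arithmetic(self):
        cells = {
            "M": (None, 0, [1100] * 3),
            "A": ("M", 3, [500] * 3),
            "B": ("M", 3, [600] * 3),
        }
        f = build_forest(make_track_df(cells))
        out = sister_ratios(f, windows=(5.0,))
        assert sorted(out["ratio"]) == pytest.approx([5 / 6, 1.2])

    def test_symmetric_noise_free_partitioning_gives_unit_ratios(self):
        ds = simulate_lineages(quiet_config(), 10, seed=2, design="undisturbed")
        out = sister_ratios(ds.forest())
        np.testing.assert_allclose(out["ratio"], 1.0, atol=1e-3)

    def test_pooled_distribution_symmetric_under_reciprocal(self, undisturbed_forest):
        out = sister_ratios(undisturbed_forest, windows=(5.0,))
        r = np.sort(out["ratio"].to_numpy())
        np.testing.assert_allclose(r, np.sort(1.0 / r), rtol=1e-9)

    def test_calibrated_quantiles_reproduced_at_1e5_draws(self, rng):
        dist = calibrate_partition_distribution()
        p = dist.sample(rng, 100_000)
        fracs = ratio_extremity_fractions(p / (1 - p))
        for name, target in (("5:6", 0.38), ("3:4", 0.12), ("1:2", 0.03)):
            mc_sd = np.sqrt(target * (1 - target) / 100_000)
            assert abs(fracs[name] - target) < 4 * mc_sd, name


class TestRatioPersistence:
    def test_constant_traces_give_perfect_persistence(self):
        cells = {}
        for i, (la, lb) in enumerate([(500, 600), (800, 700), (900, 1000), (1100, 900)]):
            cells[f"M{i}"] = (None, 0, [la + lb] * 3)
            cells[f"A{i}"] = (f"M{i}", 3, [la] * 100)
            cells[f"B{i}"] = (f"M{i}", 3, [lb] * 100)
        f = build_forest(make_track_df(cells))
        r, p, n = ratio_persistence(f)
        assert n == 4
        assert r == pytest.approx(1.0)

    def test_rerandomized_levels_give_null_persistence(self, rng):
        cells = {}
        for i in range(60):
            early = rng.uniform(400, 1600, 2)
            late = rng.uniform(400, 1600, 2)
            ramp_a = np.r_[np.full(6, early[0]), np.full(94, late[0])]
            ramp_b = np.r_[np.full(6, early[1]), np.full(94, late[1])]
            cells[f"M{i}"] = (None, 0, [2000] * 3)
            cells[f"A{i}"] = (f"M{i}", 3, ramp_a)
            cells[f"B{i}"] = (f"M{i}", 3, ramp_b)
        f = build_forest(make_track_df(cells))
        r, p, n = ratio_persistence(f)
        assert abs(r) < 0.25
        assert p > 0.01

    def test_heritable_synthetic_is_significantly_positive(self, undisturbed_forest):
        r, p, n = ratio_persistence(undisturbed_forest)
        assert r > 0.2
        assert p < 1e-6


class TestDapiVsOct4:
    def test_identical_sets_not_significant(self):
        ratios = np.array([0.9, 1.0, 1.1, 0.95, 1.05, 1.2])
        df = pd.DataFrame({"dapi_ratio": ratios, "oct4_ratio": ratios})
        cmp_ = dapi_vs_oct4_ratios(df)
        assert cmp_.ks_d == 0.0
        assert cmp_.p_value == pytest.approx(1.0)

    def test_wider_oct4_spread_is_significant(self, undisturbed_forest):
        table = sister_endpoint_table(undisturbed_forest)
        assert len(table) >= 20
        cmp_ = dapi_vs_oct4_ratios(table)
        assert cmp_.p_value < 0.05
        # DNA content is tightly controlled; OCT4 partitioning is not
        assert table["oct4_ratio"].std() > table["dapi_ratio"].std()

    def test_densities_integrate_to_one(self, rng):
        df = pd.DataFrame(
            {
                "dapi_ratio": rng.normal(1.0, 0.02, 150),
                "oct4_ratio": rng.normal(1.0, 0.15, 150).clip(0.3),
            }
        )
        cmp_ = dapi_vs_oct4_ratios(df)
        for dens in (cmp_.dapi_density, cmp_.oct4_density):
            assert np.trapezoid(dens, cmp_.grid) == pytest.approx(1.0, abs=1e-6)

    def test_missing_entries_are_error(self):
        df = pd.DataFrame({"dapi_ratio": [1.0, np.nan], "oct4_ratio": [1.0, 1.1]})
        with pytest.raises(ValueError, match="mismatched"):
            dapi_vs_oct4_ratios(df)


class TestHalfLife:
    @pytest.mark.parametrize("t_half", [7.34, 1.0])
    def test_exact_exponential_recovery(self, t_half):
        t = np.arange(0.0, 12.1, 1.0)
        levels = 1000.0 * 0.5 ** (t / t_half)
        model = fit_half_life(t, levels)
        assert model.half_life == pytest.approx(t_half, rel=1e-4)

    def test_noisy_recovery_median_within_5pct(self, rng):
        t = np.arange(0.0, 12.1, 1.0)
        estimates = []
        for _ in range(100):
            levels = 1000.0 * 0.5 ** (t / 7.34) * np.exp(rng.normal(0, 0.05, len(t)))
            estimates.append(fit_half_life(t, levels).half_life)
        assert np.median(estimates) == pytest.approx(7.34, rel=0.05)

    def test_non_decaying_series_is_error(self):
        t = np.arange(0.0, 5.0)
        with pytest.raises(ValueError, match="not decaying"):
            fit_half_life(t, 100.0 * np.exp(0.1 * t))

    def test_maternal_fraction_landmarks(self):
        model = DecayModel(half_life=7.34)
        assert maternal_fraction(model, 5.0) == pytest.approx(99.22, abs=0.005)
        assert maternal_fraction(model, 30.0) == pytest.approx(95.39, abs=0.005)
        assert maternal_fraction(model, 7.34 * 60.0) == pytest.approx(50.0)
        assert maternal_fraction(model, 0.0) == 100.0
        with pytest.raises(ValueError):
            maternal_fraction(model, -1.0)

    def test_maternal_fraction_strictly_decreasing_and_halving(self):
        model = DecayModel(half_life=7.34)
        t = np.linspace(0, 2000, 50)
        vals = np.array([maternal_fraction(model, x) for x in t])
        assert np.all(np.diff(vals) < 0)
        for k in range(1, 4):
            assert maternal_fraction(model, k * 7.34 * 60) == pytest.approx(100 / 2**k)


def constant_pair_forest(levels, n_daughter=100):
    """Mothers and daughters with constant traces at the given levels."""
    cells = {}
    for i, lvl in enumerate(levels):
        cells[f"M{i}"] = (None, 0, [lvl] * 30)
        cells[f"A{i}"] = (f"M{i}", 30, [lvl] * n_daughter)
        cells[f"B{i}"] = (f"M{i}", 30, [lvl] * n_daughter)
    return build_forest(make_track_df(cells))


class TestR2Decomposition:
    def test_constant_daughters_have_unit_r2(self, rng):
        f = constant_pair_forest(rng.uniform(500, 3000, 15))
        pairs = align_mother_daughter(f)
        curve = r2_decomposition(pairs)
        post = curve[curve["time_min"] >= 0]
        np.testing.assert_allclose(post["r2"], 1.0, atol=1e-9)
        assert curve["r2"].iloc[-1] == pytest.approx(1.0)

    def test_permuted_finals_destroy_r2(self, aligned_pairs, rng):
        perm = AlignedPairSet(
            grid=aligned_pairs.grid,
            matrix=aligned_pairs.matrix,
            mother_ids=aligned_pairs.mother_ids,
            daughter_ids=aligned_pairs.daughter_ids,
            final_levels=rng.permutation(aligned_pairs.final_levels),
        )
        curve = r2_decomposition(perm)
        assert np.nanmax(curve["r2"]) < 0.05

    def test_maternal_below_inherited_with_sharp_rise(self, aligned_pairs):
        curve = r2_decomposition(aligned_pairs)
        maternal = curve.loc[curve["period"] == "maternal", "r2"]
        inherited = curve.loc[curve["period"] == "inherited", "r2"]
        assert maternal.mean() < inherited.mean()
        assert inherited.max() - maternal.mean() > 0.15  # the division-time jump
        assert curve["r2"].iloc[-1] == pytest.approx(1.0)

    def test_affine_rescaling_invariance(self, aligned_pairs):
        curve0 = r2_decomposition(aligned_pairs)
        scaled = AlignedPairSet(
            grid=aligned_pairs.grid,
            matrix=aligned_pairs.matrix * 2.5 + 300.0,
            mother_ids=aligned_pairs.mother_ids,
            daughter_ids=aligned_pairs.daughter_ids,
            final_levels=aligned_pairs.final_levels * 2.5 + 300.0,
        )
        curve1 = r2_decomposition(scaled)
        np.testing.assert_allclose(curve0["r2"], curve1["r2"], atol=1e-9)

    def test_cumulative_mode_runs_and_differs(self, aligned_pairs):
        inst = r2_decomposition(aligned_pairs, mode="instantaneous")
        cum = r2_decomposition(aligned_pairs, mode="cumulative")
        assert len(cum) > 0
        assert not np.allclose(
            inst["r2"].to_numpy()[: len(cum)], cum["r2"].to_numpy()[: len(inst)]
        )


class TestAsymmetryContribution:
    def test_identical_sisters_give_null_difference(self, rng):
        f = constant_pair_forest(rng.uniform(500, 3000, 30))
        pairs = align_mother_daughter(f)
        res = asymmetry_contribution(pairs, n_resamples=10, seed=0)
        assert np.nanmax(np.abs(res.difference)) < 1e-9

    def test_default_fixture_weakened_before_division_jump_after(self, aligned_pairs):
        res = asymmetry_contribution(aligned_pairs, n_resamples=100, seed=0)
        pre = np.nanmean(res.difference_smoothed[res.grid < 0])
        post = np.nanmean(res.difference_smoothed[res.grid > 0])
        assert pre < 0  # duplicated mother traces weaken R^2 pre-division
        assert post > pre  # partitioning signal appears at division

    @staticmethod
    def _controlled_duos(rng, sig_d, n_duos=80, sig_s=1.0, kappa=0.9, sig_e=0.2):
        """Aligned duos with known partition noise and full heritability:
        daughters carry a persistent partitioned offset +/- d around the
        shared maternal level, plus autonomous noise."""
        n_pre, n_post = 12, 97
        grid = np.arange(-n_pre, n_post) * 5.0
        s = rng.normal(0, sig_s, n_duos)
        d = rng.normal(0, sig_d, n_duos)
        mat = np.empty((2 * n_duos, n_pre + n_post))
        mothers, daughters = [], []
        for i in range(n_duos):
            m_trace = s[i] + rng.normal(0, 0.1, n_pre)
            for j, sign in enumerate((1, -1)):
                row = np.empty(n_pre + n_post)
                row[:n_pre] = m_trace
                row[n_pre:] = (
                    s[i]
                    + sign * d[i] * np.linspace(1, kappa, n_post)
                    + rng.normal(0, sig_e, n_post)
                )
                mat[2 * i + j] = row
                mothers.append(f"m{i}")
                daughters.append(f"d{i}_{j}")
        return AlignedPairSet(
            grid=grid, matrix=mat, mother_ids=mothers,
            daughter_ids=daughters, final_levels=mat[:, -1].copy(),
        )

    def test_difference_monotone_in_partition_noise(self):
        """Increasing partition noise strictly increases the post-division
        both-vs-one sister difference (averaged over replicate datasets:
        the per-dataset statistic is noisy, its expectation is monotone
        because the persistent within-duo signal grows with the noise)."""
        means = []
        for sig_d in (0.0, 0.4, 0.8):
            rng = np.random.default_rng(1000)
            posts = []
            for rep in range(60):
                pairs = self._controlled_duos(rng, sig_d)
                res = asymmetry_contribution(pairs, n_resamples=5, seed=rep)
                posts.append(np.nanmean(res.difference_smoothed[res.grid > 0]))
            means.append(np.mean(posts))
        assert means[0] < means[1] < means[2]

    def test_too_few_duos_is_error(self, rng):
        f = constant_pair_forest(rng.uniform(500, 3000, 3))
        pairs = align_mother_daughter(f)
        with pytest.raises(ValueError, match="duos"):
            asymmetry_contribution(pairs)


class TestMixingRank:
    def test_constant_traces_have_constant_ranks(self, rng):
        f = constant_pair_forest(rng.uniform(500, 3000, 20))
        pairs = align_mother_daughter(f)
        out = mixing_rank_plot(pairs, n_cells=10, seed=0)
        for _, cell in out.groupby("daughter_id"):
            assert cell["rank_at_time"].nunique() == 1
            assert (cell["rank_at_time"] == cell["rank_at_final"]).all()

    def test_row_count_shape(self, rng):
        f = constant_pair_forest(rng.uniform(500, 3000, 20), n_daughter=97)
        pairs = align_mother_daughter(f)
        out = mixing_rank_plot(pairs, n_cells=10, seed=0)
        # every selected pair covers the full aligned window (equal lifetimes)
        assert len(out) == 10 * len(pairs.grid)

    def test_fewer_pairs_than_requested_warns(self, rng):
        f = constant_pair_forest(rng.uniform(500, 3000, 6))
        pairs = align_mother_daughter(f)
        with pytest.warns(UserWarning, match="using all"):
            out = mixing_rank_plot(pairs, n_cells=500, seed=0)
        assert out["daughter_id"].nunique() == pairs.n_pairs


class TestMixingTime:
    def test_white_noise_mixes_within_one_interval(self, rng):
        traces = [rng.normal(0, 1, 200) for _ in range(20)]
        hours, frac, curve = autocorrelation_mixing_time(traces, mean_cycle_h=14.6)
        assert hours <= 5.0 / 60.0

    def test_ou_traces_recover_correlation_time(self, rng):
        """Long stationary OU traces: the 1/e lag estimates the known
        correlation time (traces much longer than tau to keep the
        mean-subtraction bias of the autocorrelation small)."""
        from scipy.signal import lfilter

        tau_h = 3.0
        n = 4000
        alpha = np.exp(-5.0 / (tau_h * 60))
        traces = []
        for _ in range(40):
            innov = rng.normal(0, np.sqrt(1 - alpha**2), n)
            x = lfilter([1.0], [1.0, -alpha], innov)
            traces.append(1000 + 200 * x)
        hours, frac, curve = autocorrelation_mixing_time(traces, mean_cycle_h=14.6)
        assert hours == pytest.approx(tau_h, rel=0.15)

    def test_offset_invariance(self, rng):
        traces = [rng.normal(0, 1, 150) for _ in range(15)]
        h1, f1, _ = autocorrelation_mixing_time(traces, 14.6)
        h2, f2, _ = autocorrelation_mixing_time([t + 5000 for t in traces], 14.6)
        assert h1 == h2 and f1 == f2

    def test_requires_enough_traces(self, rng):
        with pytest.raises(ValueError, match="10 traces"):
            autocorrelation_mixing_time([rng.normal(0, 1, 50)], 14.6)
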