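import itertools
import math

import numpy as np
import pytest

from zcomp.io_formats import SamSettings
from zcomp.sam_stats import (
    call_at_delta,
    choose_s0,
    label_arrangements,
    permutation_null,
    pooled_scatter,
    relative_difference,
    sam_test,
)
from zcomp.synthetic_data import SimulationConfig, simulate_dataset

from conftest import make_dataset


class TestRelativeDifference:
    def test_hand_evaluation(self):
        # males (3,5), females (1,3): mean diff 2, s = sqrt(2), d = sqrt(2)
        x_m = np.array([[3.0, 5.0]])
        x_f = np.array([[1.0, 3.0]])
        s = pooled_scatter(x_m, x_f)
        assert s[0] == pytest.approx(math.sqrt(2))
        d = relative_difference(x_m.mean(1), x_f.mean(1), s, s0=0.0)
        assert d[0] == pytest.approx(math.sqrt(2))

    def test_equal_means_give_zero(self):
        x_m = np.array([[1.0, 3.0]])
        x_f = np.array([[0.0, 4.0]])
        d = relative_difference(
            x_m.mean(1), x_f.mean(1), pooled_scatter(x_m, x_f), 0.0
        )
        assert d[0] == 0.0

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        x_m = rng.normal(5, 1, (20, 4))
        x_f = rng.normal(4, 1, (20, 5))
        d0 = relative_difference(x_m.mean(1), x_f.mean(1),
                                 pooled_scatter(x_m, x_f), 0.1)
        d1 = relative_difference((x_m + 3).mean(1), (x_f + 3).mean(1),
                                 pooled_scatter(x_m + 3, x_f + 3), 0.1)
        np.testing.assert_allclose(d0, d1, rtol=1e-10)

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            relative_difference(np.array([1.0]), np.array([1.0]),
                                np.array([0.0]), 0.0)


def _reference_s0(numerator, s):
    """Independent plain-loop re-implementation of the cv-minimization rule."""
    candidates = [np.percentile(s, p) for p in range(0, 100, 5)]
    order = np.argsort(s, kind="stable")
    windows = np.array_split(order, 100)
    best = (np.inf, None)
    for cand in candidates:
        spreads = []
        for w in windows:
            if len(w) == 0:
                continue
            d = numerator[w] / (s[w] + cand)
            med = np.median(d)
            spreads.append(np.median(np.abs(d - med)))
        spreads = np.array(spreads)
        if spreads.mean() == 0:
            continue
        cv = spreads.std() / spreads.mean()
        if cv < best[0] - 1e-15:
            best = (cv, cand)
    return best[1] if best[1] is not None else 0.0


class TestChooseS0:
    def test_fixed_percentile_zero_is_min(self):
        s = np.linspace(0.1, 2.0, 200)
        assert choose_s0(np.ones(200), s, "fixed_percentile", 0.0) == pytest.approx(
            s.min()
        )

    def test_degenerate_scatter_falls_back_to_zero(self):
        s = np.full(200, 0.5)
        assert choose_s0(np.ones(200), s, "cv_minimization") == 0.0

    def test_matches_independent_reimplementation(self):
        rng = np.random.default_rng(42)
        s = rng.gamma(2.0, 0.2, 500)
        numerator = rng.normal(0, 0.3, 500) * (s + 0.1)
        mine = choose_s0(numerator, s, "cv_minimization")
        assert mine == pytest.approx(_reference_s0(numerator, s))

    def test_too_few_probesets_rejected(self):
        with pytest.raises(ValueError):
            choose_s0(np.ones(50), np.linspace(0.1, 1, 50), "cv_minimization")


class TestArrangements:
    def test_2v2_exhaustive_count(self):
        masks, exhaustive = label_arrangements(
            4, np.array([0, 1]), SamSettings(), np.random.default_rng(0)
        )
        assert exhaustive and masks.shape == (6, 4)
        assert (masks.sum(1) == 2).all()
        assert len({tuple(m) for m in map(tuple, masks)}) == 6

    def test_4v4_dbar_matches_brute_force(self):
        rng = np.random.default_rng(1)
        x = rng.normal(7, 1, (30, 8))
        settings = SamSettings()
        masks, exhaustive = label_arrangements(
            8, np.arange(4), settings, np.random.default_rng(0)
        )
        assert exhaustive and masks.shape[0] == math.comb(8, 4) == 70
        _, d_bar = permutation_null(x, masks, s0=0.1)

        # brute force: loop over all combinations with scalar arithmetic
        all_sorted = []
        for combo in itertools.combinations(range(8), 4):
            male = list(combo)
            female = [i for i in range(8) if i not in combo]
            d = []
            for row in x:
                m, f = row[male], row[female]
                ss = ((m - m.mean()) ** 2).sum() + ((f - f.mean()) ** 2).sum()
                s = math.sqrt((1 / 4 + 1 / 4) * ss / 6)
                d.append((m.mean() - f.mean()) / (s + 0.1))
            all_sorted.append(sorted(d))
        np.testing.assert_allclose(d_bar, np.mean(all_sorted, axis=0), rtol=1e-10)

    def test_sampling_distinct_and_seeded(self):
        settings = SamSettings(n_permutations=100, exhaustive_cap=10, seed=0)
        masks, exhaustive = label_arrangements(
            18, np.arange(9), settings, np.random.default_rng(5)
        )
        assert not exhaustive and masks.shape == (100, 18)
        assert len({tuple(m) for m in map(tuple, masks)}) == 100
        masks2, _ = label_arrangements(
            18, np.arange(9), settings, np.random.default_rng(5)
        )
        np.testing.assert_array_equal(masks, masks2)

    def test_original_labeling_flag(self):
        original = np.arange(2)
        with_orig, _ = label_arrangements(
            4, original, SamSettings(include_original=True), np.random.default_rng(0)
        )
        without, _ = label_arrangements(
            4, original, SamSettings(include_original=False), np.random.default_rng(0)
        )
        orig_mask = np.array([True, True, False, False])
        assert any((m == orig_mask).all() for m in with_orig)
        assert not any((m == orig_mask).all() for m in without)


class TestCallAtDelta:
    # binary-exact values so the hand-computed diffs are exact
    D = np.array([-3.0, -2.0, -1.0, 0.0, 0.5, 1.0, 1.5, 2.5, 3.0, 4.0])
    DBAR = np.array([-2.5, -2.25, -1.25, -0.125, 0.375, 0.875, 1.375, 2.375,
                     2.75, 3.0])

    def test_hand_trace(self):
        # diffs: -0.5, 0.25, 0.25, 0.125, 0.125, 0.125, 0.125, 0.125, 0.25, 1.0
        cut_low, cut_up = call_at_delta(self.D, self.DBAR, delta=0.25)
        assert cut_up == -2.0  # smallest d with diff >= 0.25
        assert cut_low == -3.0  # largest d with diff <= -0.25
        cut_low, cut_up = call_at_delta(self.D, self.DBAR, delta=0.6)
        assert cut_up == 4.0 and cut_low == -np.inf

    def test_delta_zero_boundary(self):
        cut_low, cut_up = call_at_delta(self.D, self.DBAR, delta=0.0)
        assert cut_up == min(d for d, b in zip(self.D, self.DBAR) if d - b >= 0)

    def test_oversized_delta_no_calls(self):
        cut_low, cut_up = call_at_delta(self.D, self.DBAR, delta=99.0)
        assert cut_up == np.inf and cut_low == -np.inf


def _toy_dataset(seed=0, n=150, n_per_sex=4, effect_frac=0.2):
    cfg = SimulationConfig(
        seed=seed, n_per_sex=n_per_sex, n_autosomal=n - int(n * effect_frac),
        n_z=int(n * effect_frac), n_w=0, frac_z_compensated=0.0,
        noise_log2_sd=0.3, baseline_log2_mean=8.0,
    )
    ds, _, truth = simulate_dataset(cfg)
    return ds, truth


class TestSamTest:
    def test_label_swap_negates_d_and_exchanges_calls(self):
        ds, _ = _toy_dataset(seed=4)
        settings = SamSettings(seed=0)  # 4v4 -> exhaustive, deterministic
        res = sam_test(ds, settings)
        res_sw = sam_test(ds.swap_sexes(), settings)
        np.testing.assert_allclose(
            res_sw.table["d"], -res.table["d"], rtol=1e-10
        )
        assert set(res_sw.called_male) == set(res.called_female)
        assert set(res_sw.called_female) == set(res.called_male)

    def test_power_on_spiked_probesets(self):
        """50 two-fold spikes among 1000 probesets are nearly all recovered."""
        cfg = SimulationConfig(
            seed=8, n_autosomal=950, n_z=50, n_w=0, frac_z_compensated=0.0,
            noncompensated_mf=2.0, noise_log2_sd=0.25, n_per_sex=9,
            baseline_log2_mean=8.0,
        )
        ds, _, truth = simulate_dataset(cfg)
        settings = SamSettings(n_permutations=300, exhaustive_cap=300, seed=1)
        res = sam_test(ds, settings)
        spikes = truth.classes.index[truth.classes == "z_noncompensated"]
        called_spikes = set(res.called_male) & set(spikes)
        assert len(called_spikes) >= 45
        # false calls among the null probesets stay near the FDR target
        false_calls = set(res.called_male) - set(spikes)
        assert len(false_calls) <= 0.05 * 1000

    def test_q_value_rank_monotonicity_in_positive_tail(self):
        ds, _ = _toy_dataset(seed=2, n=200, n_per_sex=5)
        res = sam_test(ds, SamSettings(seed=0))
        tab = res.table.sort_values("d")
        q = tab["q_value"].to_numpy()
        d = tab["d"].to_numpy()
        pos = d > np.median(d)
        # within the positive tail, larger d never has a larger q
        q_pos = q[pos]
        assert (np.diff(q_pos) <= 1e-12).all()

    def test_weak_effect_has_large_q(self):
        """A mildly dimorphic probeset keeps a large q-value, as for genes
        around 1.3-fold in real data."""
        rng = np.random.default_rng(3)
        arr = 2.0 ** rng.normal(8, 0.3, (200, 8))
        arr[0, :4] *= 1.15  # weak male excess on one probeset
        ds = make_dataset(arr, sexes=["male"] * 4 + ["female"] * 4)
        res = sam_test(ds, SamSettings(seed=0))
        assert res.table["q_value"].iloc[0] > 0.2

    def test_delta_table_schema_and_fold_change(self):
        ds, _ = _toy_dataset(seed=5)
        res = sam_test(ds, SamSettings(seed=0))
        assert set(res.delta_table.columns) == {
            "delta", "n_called", "fdr", "cut_low", "cut_up"
        }
        assert (res.delta_table["delta"].diff().dropna() > 0).all()
        assert (res.table["fold_change"] > 0).all()
        assert res.table["q_value"].between(0, 1).all()
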