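"""Lectin-array background handling, NFI normalization, differential calls."""

import numpy as np
import pytest

from chipglyco.lectin import (
    SpotMeasurement,
    aggregate,
    differential_call,
    flag_effective,
    normalize_block,
    process_condition,
    subtract_background,
)
from chipglyco.simulate import gen_lectin_dataset


def _spot(lectin, fg, bg, slide="s1", block="b1"):
    return SpotMeasurement(slide, block, lectin, fg, bg)


class TestSubtractBackground:
    def test_block_mean_subtracted(self):
        spots = [_spot("L1", 300, 90), _spot("L1", 250, 110)]
        out = subtract_background(spots)
        assert out[0].corrected == pytest.approx(200)  # 300 - mean(90, 110)
        assert out[1].corrected == pytest.approx(150)

    def test_zero_background_identity(self):
        out = subtract_background([_spot("L1", 42.0, 0.0), _spot("L2", 7.0, 0.0)])
        assert [s.corrected for s in out] == [42.0, 7.0]

    def test_slide_vs_block_scope_differ_by_block_mean_difference(self):
        # two blocks with background means 100 and 200; slide mean is 150
        spots = [
            _spot("L1", 500, 90, block="b1"), _spot("L1", 500, 110, block="b1"),
            _spot("L1", 500, 190, block="b2"), _spot("L1", 500, 210, block="b2"),
        ]
        per_block = subtract_background(spots, scope="block")
        per_slide = subtract_background(spots, scope="slide")
        for b, s in zip(per_block, per_slide):
            block_mean = 100 if b.block_id == "b1" else 200
            assert s.corrected - b.corrected == pytest.approx(block_mean - 150)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            subtract_background([])


class TestFlagEffective:
    def test_threshold_at_mean_plus_k_sd(self):
        # engineered block background: mean 100, sample SD 10
        bg = [90.0, 110.0, 100.0, 100.0, 90.0, 110.0, 100.0]
        sd = float(np.std(bg, ddof=1))
        spots = [_spot("L1", 100 + 2 * sd - 1, bg[0]), _spot("L2", 100 + 2 * sd + 1, bg[1])]
        spots += [_spot("Lpad", 5000, b) for b in bg[2:]]
        flagged = flag_effective(subtract_background(spots), k=2.0)
        assert flagged[0].effective is False
        assert flagged[1].effective is True

    def test_single_background_point_warns_sd_zero(self):
        with pytest.warns(UserWarning, match="SD undefined"):
            flagged = flag_effective([_spot("L1", 150, 100)], k=2.0)
        assert flagged[0].effective is True  # threshold collapses to mean_bg

    def test_raising_k_is_monotone(self):
        rng = np.random.default_rng(2)
        spots = [
            _spot(f"L{i}", float(rng.uniform(50, 300)), float(rng.uniform(80, 120)))
            for i in range(60)
        ]
        counts = []
        for k in (0.0, 1.0, 2.0, 3.0):
            flagged = flag_effective(subtract_background(spots), k=k)
            counts.append(sum(s.effective for s in flagged))
        assert counts == sorted(counts, reverse=True)


class TestNormalizeBlock:
    def test_two_lectin_medians(self):
        spots = [_spot("A", 130, 100), _spot("B", 170, 100)]
        flagged = flag_effective(subtract_background(spots), k=0.0)
        prof = normalize_block(flagged)
        assert prof.normalized == pytest.approx({"A": 0.3, "B": 0.7})

    def test_single_lectin_block(self):
        flagged = flag_effective(subtract_background([_spot("A", 200, 0), _spot("A", 300, 0)]), k=0.0)
        assert normalize_block(flagged).normalized == {"A": 1.0}

    def test_sums_to_one_on_random_blocks(self):
        rng = np.random.default_rng(9)
        for _ in range(1000):
            n_lec = int(rng.integers(2, 12))
            spots = [
                _spot(f"L{i}", float(rng.uniform(200, 5000)), float(rng.uniform(50, 150)))
                for i in range(n_lec)
                for _ in range(int(rng.integers(1, 4)))
            ]
            prof = normalize_block(flag_effective(subtract_background(spots), k=0.0))
            assert sum(prof.normalized.values()) == pytest.approx(1.0, abs=1e-12)

    def test_scaling_invariance(self):
        rng = np.random.default_rng(13)
        spots = [_spot(f"L{i}", float(rng.uniform(500, 3000)), 0.0) for i in range(8)]
        scaled = [_spot(s.lectin_id, s.foreground * 17.0, 0.0) for s in spots]
        p1 = normalize_block(flag_effective(subtract_background(spots), k=0.0))
        p2 = normalize_block(flag_effective(subtract_background(scaled), k=0.0))
        for lec in p1.normalized:
            assert p1.normalized[lec] == pytest.approx(p2.normalized[lec])

    def test_block_without_effective_spots_dropped(self):
        # bg mean 100, sd 10 -> validity threshold 120; all foregrounds below
        spots = flag_effective(subtract_background(
            [_spot("A", 115, 90), _spot("B", 110, 110), _spot("C", 105, 100)]), k=2.0)
        with pytest.warns(UserWarning, match="zero effective"):
            assert normalize_block(spots) is None

    def test_mixed_blocks_rejected(self):
        spots = flag_effective(subtract_background(
            [_spot("A", 300, 0, block="b1"), _spot("A", 300, 0, block="b2")]), k=0.0)
        with pytest.raises(ValueError, match="multiple blocks"):
            normalize_block(spots)


class TestAggregate:
    def _profiles(self, values):
        from chipglyco.lectin import BlockProfile
        return [
            BlockProfile("s1", f"b{i}", {"A": v}, {"A": v}) for i, v in enumerate(values)
        ]

    def test_identical_blocks_sd_zero(self):
        out = aggregate(self._profiles([0.2] * 9), "ctl")
        assert out[0].sd_nfi == 0.0 and out[0].n_blocks == 9

    def test_mean_of_two(self):
        out = aggregate(self._profiles([0.1, 0.2]))
        assert out[0].mean_nfi == pytest.approx(0.15)

    def test_single_block_rejected(self):
        with pytest.raises(ValueError):
            aggregate(self._profiles([0.5]))


class TestDifferentialCall:
    def test_planted_up_down_called_at_strict_tier(self):
        spots, truth = gen_lectin_dataset(
            true_folds={"UEA-I": 0.4, "WFA": 2.5}, noise_cv=0.05, seed=101
        )
        calls = differential_call(
            process_condition(spots["control"]),
            process_condition(spots["treatment"]),
            tiers=("STRICT",),
        )
        hits = {c.lectin_id: c.call for c in calls if c.call != "UNCHANGED"}
        assert hits == {"UEA-I": "DOWN", "WFA": "UP"}

    def test_nine_blocks_per_lectin(self):
        spots, _ = gen_lectin_dataset(seed=5)
        summaries = aggregate(process_condition(spots["control"]), "control")
        assert all(s.n_blocks == 9 for s in summaries)

    def test_zero_noise_identity_folds(self):
        spots, truth = gen_lectin_dataset(noise_cv=0.0, seed=7)
        calls = differential_call(
            process_condition(spots["control"]),
            process_condition(spots["treatment"]),
            tiers=("STRICT",),
        )
        assert all(c.call == "UNCHANGED" for c in calls)
        for c in calls:
            assert c.fold_change == pytest.approx(1.0, abs=1e-9)

    def test_zero_noise_planted_folds_recovered_exactly(self):
        spots, truth = gen_lectin_dataset(
            true_folds={"UEA-I": 0.4, "WFA": 2.5}, noise_cv=0.0, seed=7
        )
        calls = differential_call(
            process_condition(spots["control"]),
            process_condition(spots["treatment"]),
            tiers=("STRICT",),
        )
        for c in calls:
            assert c.fold_change == pytest.approx(truth.expected_nfi_fold[c.lectin_id], abs=1e-9)

    def test_fold_thresholds_and_tiers(self):
        # fold 1.8 is UP at REPORTED (>1.5) but not at STRICT (>=2.0)
        from chipglyco.lectin import BlockProfile
        ctl = [BlockProfile("s1", f"b{i}", {}, {"A": 0.10, "B": 0.90}) for i in range(3)]
        trt = [
            BlockProfile("s1", f"b{i}", {}, {"A": 0.10 * 1.8 + 0.001 * i, "B": 0.82})
            for i in range(3)
        ]
        calls = {c.tier: c.call for c in differential_call(ctl, trt) if c.lectin_id == "A"}
        assert calls["REPORTED"] == "UP" and calls["STRICT"] == "UNCHANGED"

    def test_fold_without_significance_is_unchanged(self):
        from chipglyco.lectin import BlockProfile
        rng = np.random.default_rng(3)
        # fold ~2.5 but wildly variable across blocks: p stays high
        ctl = [BlockProfile("s1", f"b{i}", {}, {"A": 0.1}) for i in range(4)]
        trt = [
            BlockProfile("s1", f"b{i}", {}, {"A": float(rng.uniform(0.02, 0.6))})
            for i in range(4)
        ]
        calls = differential_call(ctl, trt, tiers=("STRICT",))
        if calls[0].p_value >= 0.05:
            assert calls[0].call == "UNCHANGED"

    def test_monte_carlo_call_rate_at_cv5(self):
        """Planted UEA-I down (0.4) and WFA up (2.5) at 5% CV are both
        called, with correct direction and nothing else flagged, in at
        least 95% of 100 seeds."""
        ok = 0
        for seed in range(100):
            spots, _ = gen_lectin_dataset(
                true_folds={"UEA-I": 0.4, "WFA": 2.5}, noise_cv=0.05, seed=seed
            )
            calls = differential_call(
                process_condition(spots["control"]),
                process_condition(spots["treatment"]),
                tiers=("STRICT",),
            )
            hits = {c.lectin_id: c.call for c in calls if c.call != "UNCHANGED"}
            ok += hits == {"UEA-I": "DOWN", "WFA": "UP"}
        assert ok >= 95
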