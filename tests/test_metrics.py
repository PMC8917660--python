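"""Usage histograms, habituation, spatial occupancy, grooming modes."""

import numpy as np
import pandas as pd
import pytest

from mousefield.metrics import (
    ZoneConfig,
    cohens_d,
    episode_runs,
    grooming_modes,
    habituation_summary,
    spatial_occupancy,
    usage,
    usage_over_time,
)
from mousefield.synthetic import SyntheticTrialSpec, generate_trial, truth_ethogram
from mousefield.types import Ethogram


def eth_from_labels(labels, xy=None, fs=80.0):
    labels = np.asarray(labels)
    n = len(labels)
    if xy is None:
        xy = np.full((n, 2), 0.2)
    return Ethogram(
        fine_labels=labels,
        coarse_labels=labels,
        speed=np.zeros(n),
        arena_xy=np.asarray(xy, dtype=float),
        frame_rate=fs,
    )


class TestUsage:
    def test_single_class_is_one(self):
        u = usage(eth_from_labels(np.full(100, 8)))
        assert u[8] == 1.0
        assert u.drop(8).sum() == 0.0

    def test_quarter_groom(self):
        labels = np.r_[np.full(24000, 2), np.full(72000, 8)]
        u = usage(eth_from_labels(labels))
        assert u[2] == pytest.approx(0.25)

    def test_rows_sum_to_one(self, mixed_trial):
        eth = truth_ethogram(mixed_trial)
        for level in ("coarse", "fine"):
            assert usage(eth, level).sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_generator_dwell_fractions(self):
        """Usage recovers the programmed state mix within binomial error."""
        probs = {"idle": 0.3, "groom": 0.2, "locomotion": 0.5}
        spec = SyntheticTrialSpec(
            duration_s=300.0, state_probs=probs, mean_dwell_s=2.0, seed=3
        )
        eth = truth_ethogram(generate_trial(spec))
        u = usage(eth)
        # dwell sampling: tolerance ~3 sigma of the segment-level binomial
        assert u[1] == pytest.approx(0.3, abs=0.1)
        assert u[8] == pytest.approx(0.5, abs=0.1)


class TestUsageOverTime:
    def test_stationary_process_flat_curve(self):
        rng = np.random.default_rng(0)
        eths = {
            f"m{i}": eth_from_labels(rng.integers(1, 9, size=48000))
            for i in range(4)
        }
        df = usage_over_time(eths, window_s=180.0, step_s=60.0, seed=0)
        for _, sub in df.groupby("label"):
            assert np.ptp(sub["mean"].values) < 0.02

    def test_identical_mice_zero_ci_width(self):
        labels = np.tile(np.r_[np.full(80, 1), np.full(80, 8)], 200)
        eths = {"a": eth_from_labels(labels), "b": eth_from_labels(labels.copy())}
        df = usage_over_time(eths, window_s=60.0, step_s=60.0, seed=0)
        np.testing.assert_allclose(df["ci_hi"] - df["ci_lo"], 0.0, atol=1e-12)

    def test_ci_contains_mean(self, mixed_trial):
        spec2 = SyntheticTrialSpec(duration_s=120.0, seed=8, mean_dwell_s=2.5)
        eths = {
            "a": truth_ethogram(mixed_trial),
            "b": truth_ethogram(generate_trial(spec2)),
        }
        df = usage_over_time(eths, window_s=60.0, step_s=30.0, seed=1)
        assert np.all(df["ci_lo"] <= df["mean"] + 1e-12)
        assert np.all(df["mean"] <= df["ci_hi"] + 1e-12)

    def test_window_longer_than_trial_errors(self):
        eths = {"a": eth_from_labels(np.ones(100)), "b": eth_from_labels(np.ones(100))}
        with pytest.raises(ValueError, match="window"):
            usage_over_time(eths, window_s=600.0)

    def test_decreasing_locomotion_hazard_gives_decreasing_curve(self):
        """Within-session habituation shows up in the sliding usage."""
        rng = np.random.default_rng(5)
        eths = {}
        n = 48000
        for m in range(4):
            p = np.linspace(0.6, 0.1, n)  # locomotion probability decays
            labels = np.where(rng.random(n) < p, 8, 1)
            eths[f"m{m}"] = eth_from_labels(labels)
        df = usage_over_time(eths, window_s=120.0, step_s=60.0, seed=0)
        loco = df[df["label"] == 8].sort_values("time_s")["mean"].values
        assert np.all(np.diff(loco) < 0)


class TestSpatialOccupancy:
    def test_fixed_in_corner(self):
        zones = ZoneConfig(arena_side=0.457)
        xy = np.full((1000, 2), 0.01)
        occ = spatial_occupancy(eth_from_labels(np.ones(1000), xy), zones)
        assert occ["corner_fraction"] == 1.0
        assert occ["center_crossings"] == 0

    def test_single_pass_through_center(self):
        zones = ZoneConfig(arena_side=0.457)
        t = np.linspace(0, 1, 400)
        xy = np.column_stack([0.457 * t, 0.457 * t])  # corner-to-corner diagonal
        occ = spatial_occupancy(eth_from_labels(np.ones(400), xy), zones)
        assert occ["center_crossings"] == 1

    def test_zone_fractions_partition(self, mixed_trial):
        zones = ZoneConfig(arena_side=mixed_trial.spec.arena_side)
        eth = truth_ethogram(mixed_trial)
        total = (
            spatial_occupancy(eth, zones)["corner_fraction"]
            + spatial_occupancy(eth, zones)["center_fraction"]
            + spatial_occupancy(eth, zones)["edge_fraction"]
            + spatial_occupancy(eth, zones)["remainder_fraction"]
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_entries_and_exits_differ_by_at_most_one(self, mixed_trial):
        zones = ZoneConfig(arena_side=mixed_trial.spec.arena_side)
        occ = spatial_occupancy(truth_ethogram(mixed_trial), zones)
        assert abs(occ["center_crossings"] - occ["center_exits"]) <= 1

    def test_corner_bias_increases_corner_fraction(self):
        """Simulation oracle: biased random walks toward a corner."""
        zones = ZoneConfig(arena_side=0.457)
        fracs = []
        for bias in (0.0, 0.3, 0.7):
            rng = np.random.default_rng(11)
            pos = np.empty((4000, 2))
            p = np.array([0.22, 0.22])
            target = np.array([0.02, 0.02])
            for i in range(4000):
                step = rng.normal(0, 0.004, 2) + bias * 0.004 * np.sign(target - p)
                p = np.clip(p + step, 0, 0.457)
                pos[i] = p
            occ = spatial_occupancy(eth_from_labels(np.ones(4000), pos), zones)
            fracs.append(occ["corner_fraction"])
        assert fracs[0] < fracs[1] < fracs[2]

    def test_hysteresis_suppresses_boundary_jitter(self):
        zones = ZoneConfig(arena_side=0.457)
        edge = (0.457 - zones.center_side) / 2.0
        rng = np.random.default_rng(3)
        # jitter back and forth across the center boundary every frame
        xy = np.column_stack(
            [edge + rng.choice([-0.002, 0.002], 2000), np.full(2000, 0.23)]
        )
        occ = spatial_occupancy(eth_from_labels(np.ones(2000), xy), zones)
        assert occ["center_crossings"] <= 1


class TestGroomingModes:
    def submap(self):
        return {10: "body", 11: "face_paw", 12: "small_quick"}

    def eth(self, fine):
        fine = np.asarray(fine)
        coarse = np.where(np.isin(fine, list(self.submap())), 2, 1)
        n = len(fine)
        return Ethogram(
            fine_labels=fine,
            coarse_labels=coarse,
            speed=np.zeros(n),
            arena_xy=np.zeros((n, 2)),
            frame_rate=80.0,
        )

    def test_single_mode_fraction_one(self):
        fine = np.r_[np.full(200, 10), np.full(100, 1)]
        row = grooming_modes(self.eth(fine), self.submap())
        assert row["frac_body"] == 1.0
        assert row["total_episodes"] == 1

    def test_alternating_modes_half_half(self):
        fine = np.tile(np.r_[np.full(40, 10), np.full(40, 11)], 10)
        row = grooming_modes(self.eth(fine), self.submap())
        assert row["frac_body"] == pytest.approx(0.5)
        assert row["frac_face_paw"] == pytest.approx(0.5)

    def test_blip_absorbed_into_surrounding_episode(self):
        """Run-length oracle: a 3-frame blip must not split the episode."""
        fine = np.r_[np.full(100, 10), np.full(3, 11), np.full(100, 10)]
        row = grooming_modes(self.eth(fine), self.submap())
        assert row["n_body"] == 1
        assert row["n_face_paw"] == 0

    def test_zero_grooming_flagged_nan(self):
        row = grooming_modes(self.eth(np.full(100, 1)), self.submap())
        assert np.isnan(row["frac_body"])
        assert row["total_episodes"] == 0


class TestEpisodeRuns:
    def test_brute_force_runs(self):
        labels = np.array(list("aaabbbaaa"))
        runs = episode_runs(labels, min_len=2)
        assert [(v, s, e) for v, s, e in runs] == [("a", 0, 3), ("b", 3, 6), ("a", 6, 9)]

    def test_short_run_merges_into_longer_neighbor(self):
        labels = np.array(list("aaaabaa"))
        runs = episode_runs(labels, min_len=2)
        assert runs == [("a", 0, 7)]


class TestHabituation:
    def tidy(self, day1, day2):
        rows = []
        for d, vals in ((1, day1), (2, day2)):
            for m, v in enumerate(vals):
                rows.append({"mouse": f"m{m}", "day": d, "label": 8, "fraction": v})
        return pd.DataFrame(rows)

    def test_identical_days_d_zero(self):
        vals = [0.2, 0.3, 0.25, 0.28]
        out = habituation_summary(self.tidy(vals, vals))
        assert out.loc[8, "cohens_d"] == 0.0

    def test_unit_shift_unit_sd_gives_d_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 200)
        a = (a - a.mean()) / a.std(ddof=1)  # exact sample mean 0, sd 1
        assert cohens_d(a + 1.0, a) == pytest.approx(1.0, abs=1e-9)

    def test_recovers_programmed_effect_size(self):
        """Across-day decrease of 1.5 pooled SDs -> d = 1.5 +- 0.3 at n=20.

        Averaged over replicates so the check reflects the estimator, not
        one sampling draw.
        """
        ds = []
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            day1 = rng.normal(0.5, 0.05, 20)
            day2 = rng.normal(0.5 - 1.5 * 0.05, 0.05, 20)
            out = habituation_summary(self.tidy(day1, day2))
            ds.append(out.loc[8, "cohens_d"])
        assert np.mean(ds) == pytest.approx(-1.5, abs=0.3)

    def test_single_day_errors(self):
        df = self.tidy([0.1, 0.2], [0.3, 0.4])
        with pytest.raises(ValueError, match="two days"):
            habituation_summary(df[df["day"] == 1])
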