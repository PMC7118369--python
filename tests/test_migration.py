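"""Migration metrics: displacement/velocity arithmetic, the strict
half-diameter rule, single-vs-cluster mode, and per-animal aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import match_tracks_to_truth
from intravital.migration import (
    aggregate_by_animal,
    classify_migratory,
    classify_mode,
    compute_metrics,
)
from intravital.pipeline import analyze_movie
from intravital.synthetic import SimConfig, generate_movie


def _track(positions, diameter=20.0, lgr5=False, track_id=0):
    pos = np.asarray(positions, dtype=float)
    return pd.DataFrame(
        {
            "track_id": track_id,
            "frame": np.arange(len(pos)),
            "x_um": pos[:, 0],
            "y_um": pos[:, 1],
            "diameter_um": diameter,
            "lgr5": lgr5,
        }
    )


class TestComputeMetrics:
    def test_static_track_all_zero(self):
        m = compute_metrics(_track([(5, 5)] * 5), frame_interval_h=1.0)
        assert m.net_displacement_um == 0.0
        assert m.path_length_um == 0.0
        assert m.velocity_um_per_h == 0.0

    def test_straight_line_arithmetic(self):
        pos = [(10.0 * t, 0.0) for t in range(5)]
        m = compute_metrics(_track(pos), frame_interval_h=1.0)
        assert m.net_displacement_um == pytest.approx(40.0)
        assert m.path_length_um == pytest.approx(40.0)
        assert m.velocity_um_per_h == pytest.approx(10.0)

    def test_square_path_returns_to_start(self):
        pos = [(0, 0), (10, 0), (10, 10), (0, 10), (0, 0)]
        m = compute_metrics(_track(pos), frame_interval_h=1.0)
        assert m.net_displacement_um == pytest.approx(0.0)
        assert m.path_length_um == pytest.approx(40.0)

    def test_track_shorter_than_window_excluded(self):
        m = compute_metrics(_track([(0, 0)] * 3), frame_interval_h=1.0)
        assert m is None

    def test_path_at_least_net(self, default_movie):
        stack, _ = default_movie
        metrics, _, _ = analyze_movie(stack)
        assert (
            metrics["path_length_um"] >= metrics["net_displacement_um"] - 1e-9
        ).all()


class TestMigratoryRule:
    def test_exactly_half_diameter_is_not_migratory(self):
        assert not classify_migratory(10.0, 20.0)

    def test_just_above_half_is_migratory(self):
        assert classify_migratory(10.1, 20.0)

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            classify_migratory(5.0, 0.0)

    def test_boundary_sweep_switches_at_half_diameter(self):
        """Sweep of displacements: the rule flips strictly above 0.5 d."""
        diameter = 20.0
        disp = np.linspace(0.0, 20.0, 201)  # includes exactly 10.0
        calls = np.array([classify_migratory(d, diameter) for d in disp])
        assert np.array_equal(calls, disp > 0.5 * diameter)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        d1=st.floats(0.0, 100.0),
        d2=st.floats(0.0, 100.0),
        diameter=st.floats(1.0, 50.0),
    )
    def test_monotone_in_displacement(self, d1, d2, diameter):
        lo, hi = sorted([d1, d2])
        if classify_migratory(lo, diameter):
            assert classify_migratory(hi, diameter)


class TestMode:
    def test_single_migratory_cell_is_single(self):
        linked = _track([(0, 0), (6, 0), (12, 0), (18, 0), (24, 0)])
        modes = classify_mode(linked, [0], frame_interval_h=1.0)
        assert modes == {0: "single"}

    def test_co_moving_pair_at_half_contact_distance_is_cluster(self):
        a = _track([(0.0 + 6 * t, 0.0) for t in range(5)], track_id=0)
        b = _track([(10.0 + 6 * t, 0.0) for t in range(5)], track_id=1)
        linked = pd.concat([a, b], ignore_index=True)
        # separation 10 um = 0.5 x (r_i + r_j) for 20 um cells: contact
        modes = classify_mode(linked, [0, 1], frame_interval_h=1.0)
        assert modes == {0: "cluster", 1: "cluster"}

    def test_modes_exhaustive_and_exclusive(self, default_movie):
        stack, _ = default_movie
        metrics, _, _ = analyze_movie(stack)
        mig = metrics[metrics["migratory"]]
        assert set(mig["mode"]) <= {"single", "cluster"}
        assert (metrics.loc[~metrics["migratory"], "mode"]
                == "not_migratory").all()

    def test_synthetic_modes_match_ground_truth(self):
        cfg = SimConfig(seed=31, n_static_cells=5, n_migratory_cells=5,
                        n_cluster_events=3)
        stack, truth = generate_movie(cfg)
        metrics, linked, _ = analyze_movie(stack)
        matched = match_tracks_to_truth(
            metrics[metrics["migratory"]], linked, truth
        )
        assert len(matched) == truth.migratory_label.sum()
        assert (matched["mode"] == matched["true_mode"]).all()


class TestAggregation:
    def test_all_negative_gives_mean_one_sem_zero(self):
        metrics = pd.DataFrame(
            {
                "animal_id": ["m1"] * 3 + ["m2"] * 3,
                "migratory": [True] * 6,
                "lgr5": [False] * 6,
                "mode": ["single"] * 6,
            }
        )
        _, summary = aggregate_by_animal(metrics)
        assert summary["mean_fraction_lgr5neg"] == 1.0
        assert summary["sem_fraction_lgr5neg"] == 0.0

    def test_two_animal_fractions_hand_computed(self):
        # animal fractions 0.8 and 1.0: mean 0.9, SEM = sd/sqrt(2) = 0.1
        metrics = pd.DataFrame(
            {
                "animal_id": ["a"] * 5 + ["b"] * 4,
                "migratory": [True] * 9,
                "lgr5": [False] * 4 + [True] + [False] * 4,
                "mode": ["single"] * 9,
            }
        )
        per_animal, summary = aggregate_by_animal(metrics)
        assert sorted(per_animal["fraction_lgr5neg"]) == [0.8, 1.0]
        assert summary["mean_fraction_lgr5neg"] == pytest.approx(0.9)
        assert summary["sem_fraction_lgr5neg"] == pytest.approx(0.1)

    def test_animal_without_migratory_tracks_excluded(self):
        metrics = pd.DataFrame(
            {
                "animal_id": ["a", "a", "b"],
                "migratory": [True, True, False],
                "lgr5": [False, False, True],
            }
        )
        per_animal, summary = aggregate_by_animal(metrics)
        assert list(per_animal["animal_id"]) == ["a"]
        assert summary["n_animals"] == 1

    def test_fractions_partition_migratory(self):
        metrics = pd.DataFrame(
            {
                "animal_id": ["a"] * 4,
                "migratory": [True] * 4,
                "lgr5": [False] * 4,
                "mode": ["single", "single", "cluster", "cluster"],
            }
        )
        per_animal, _ = aggregate_by_animal(metrics)
        row = per_animal.iloc[0]
        assert row["fraction_single"] + row["fraction_cluster"] == 1.0
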