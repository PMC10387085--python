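"""Generator contracts: determinism, wash semantics, geometry, monotonicity."""

import numpy as np
import pytest

from nanocoloc import (
    ConditionLabel,
    GroundTruth,
    PlacementError,
    SyntheticConfig,
    ValidationError,
    apply_wash,
    generate_experiment,
    generate_fov,
)
from nanocoloc.synthetic import Cell


def make_gt(n_int=10, n_adh=5, n_free=3):
    """Tiny hand-built ground truth with one cell at the center."""
    cell = Cell((50.0, 50.0), 10.0, 5.0)
    n = n_int + n_adh + n_free
    rng = np.random.default_rng(0)
    pos = np.empty((n, 2))
    status = np.array(
        ["internalized"] * n_int + ["adhered"] * n_adh + ["free"] * n_free, dtype="U12"
    )
    owner = np.array([0] * (n_int + n_adh) + [-1] * n_free)
    pos[:n_int] = 50.0 + rng.uniform(-4, 4, (n_int, 2))
    theta = rng.uniform(0, 2 * np.pi, n_adh)
    pos[n_int : n_int + n_adh] = np.column_stack(
        [50.0 + 9.5 * np.sin(theta), 50.0 + 9.5 * np.cos(theta)]
    )
    pos[n_int + n_adh :] = rng.uniform(0, 99, (n_free, 2))
    return GroundTruth(cells=[cell], positions=pos, status=status, cell_index=owner)


class TestApplyWash:
    def test_trypsin_keeps_internalized_only(self):
        gt = apply_wash(make_gt(), "trypsin", 0.0)
        assert gt.count("internalized") == 10
        assert gt.n_particles == 10

    def test_pbs_keeps_internalized_and_adhered(self):
        gt = apply_wash(make_gt(), "pbs", 0.0)
        assert gt.count("internalized") == 10
        assert gt.count("adhered") == 5
        assert gt.n_particles == 15

    def test_none_is_identity(self):
        gt0 = make_gt()
        assert apply_wash(gt0, "none", 0.0) is gt0

    def test_washes_agree_when_no_adhered(self):
        t = apply_wash(make_gt(n_adh=0), "trypsin", 0.0)
        p = apply_wash(make_gt(n_adh=0), "pbs", 0.0)
        np.testing.assert_array_equal(t.positions, p.positions)
        np.testing.assert_array_equal(t.status, p.status)

    def test_carryover_retains_fraction_of_free(self):
        gt = apply_wash(make_gt(n_free=10), "trypsin", 0.5)
        assert gt.count("free") == 5
        assert gt.count("adhered") == 0

    def test_invalid_carryover_rejected(self):
        with pytest.raises(ValidationError):
            apply_wash(make_gt(), "trypsin", 1.5)

    def test_unknown_wash_rejected(self):
        with pytest.raises(ValidationError):
            apply_wash(make_gt(), "soap", 0.0)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_wash_monotonicity(self, seed):
        """|after trypsin| <= |after pbs| <= |before| for any ground truth."""
        rng = np.random.default_rng(seed)
        gt = make_gt(
            n_int=int(rng.integers(0, 30)),
            n_adh=int(rng.integers(0, 30)),
            n_free=int(rng.integers(0, 30)),
        )
        c = float(rng.random())
        n_t = apply_wash(gt, "trypsin", c, np.random.default_rng(seed)).n_particles
        n_p = apply_wash(gt, "pbs", c, np.random.default_rng(seed)).n_particles
        assert n_t <= n_p <= gt.n_particles


class TestGenerateFov:
    def test_bit_identical_reproduction(self):
        cfg = SyntheticConfig(image_shape=(128, 128), seed=7)
        cond = ConditionLabel("HM", "pbs", 200, 37)
        fov1, gt1 = generate_fov(cfg, cond)
        fov2, gt2 = generate_fov(cfg, cond)
        np.testing.assert_array_equal(fov1.nuclei_channel, fov2.nuclei_channel)
        np.testing.assert_array_equal(fov1.particle_channel, fov2.particle_channel)
        np.testing.assert_array_equal(gt1.positions, gt2.positions)
        np.testing.assert_array_equal(gt1.status, gt2.status)

    def test_particles_only_control_has_spots_but_no_nuclei(self, small_config):
        cond = ConditionLabel("control_particles_only", "none", 100, 37)
        fov, gt = generate_fov(small_config, cond)
        assert len(gt.cells) == 0
        assert gt.n_particles > 0
        assert set(gt.status) == {"free"}
        # nuclei channel is background only: no pixel anywhere near nuclear
        # amplitude, while the particle channel carries planted signal
        cfg = small_config
        assert fov.nuclei_channel.max() < cfg.nucleus_intensity_mean / 2

    def test_cells_only_control_has_no_particles(self, small_config):
        cond = ConditionLabel("control_cells_only", "none", 100, 37)
        fov, gt = generate_fov(small_config, cond)
        assert gt.n_particles == 0
        assert len(gt.cells) > 0
        assert fov.particle_channel.shape == fov.nuclei_channel.shape

    def test_internalized_particles_lie_inside_their_cell(self, hm_fov):
        _, gt = hm_fov
        inside = gt.status == "internalized"
        assert inside.any()
        for pos, idx in zip(gt.positions[inside], gt.cell_index[inside]):
            cell = gt.cells[idx]
            d = np.hypot(pos[0] - cell.center[0], pos[1] - cell.center[1])
            assert d <= cell.cell_radius + 1e-9

    def test_adhered_particles_lie_on_boundary_annulus(self, hm_fov):
        _, gt = hm_fov
        adhered = gt.status == "adhered"
        assert adhered.any()
        for pos, idx in zip(gt.positions[adhered], gt.cell_index[adhered]):
            cell = gt.cells[idx]
            d = np.hypot(pos[0] - cell.center[0], pos[1] - cell.center[1])
            assert 0.8 * cell.cell_radius <= d <= 1.0 * cell.cell_radius + 1e-9

    def test_counts_per_cell_sum_to_non_free_particles(self, hm_fov):
        _, gt = hm_fov
        counts = gt.counts_per_cell
        assert counts.sum() == gt.count("internalized") + gt.count("adhered")

    def test_raster_values_within_bit_depth(self, hm_fov):
        fov, _ = hm_fov
        for ch in (fov.nuclei_channel, fov.particle_channel):
            assert ch.min() >= 0
            assert ch.max() <= 2**16 - 1

    def test_crowded_fov_raises_placement_error(self):
        cfg = SyntheticConfig(image_shape=(64, 64), n_cells_mean=500, n_cells_sd=0)
        with pytest.raises(PlacementError, match="cell"):
            generate_fov(cfg, ConditionLabel("HM", "pbs", 100, 37))

    @pytest.mark.parametrize(
        "bad",
        [
            {"internalized_fraction": 0.8, "adhered_fraction": 0.5},
            {"image_shape": (32, 200)},
            {"nucleus_to_cell_ratio": 1.5},
            {"pixel_size": -1.0},
            {"edge_bias": -0.5},
            {"wash_carryover": 2.0},
        ],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValidationError):
            generate_fov(SyntheticConfig(**bad), ConditionLabel("HM", "pbs", 100, 37))

    def test_invalid_condition_rejected(self):
        with pytest.raises(ValidationError):
            ConditionLabel("immortal", "pbs", 100, 37)
        with pytest.raises(ValidationError):
            ConditionLabel("HM", "pbs", 150, 37)


class TestGenerateExperiment:
    def _design(self, n_fovs=3):
        cfg = SyntheticConfig(image_shape=(96, 96), n_cells_mean=8, n_cells_sd=2)
        return {
            ConditionLabel("HM", "pbs", 100, 37): (cfg, n_fovs),
            ConditionLabel("LM", "pbs", 100, 37): (cfg, n_fovs),
        }

    def test_counts_and_distinct_ids(self):
        batch = generate_experiment(self._design(3), master_seed=5)
        assert len(batch) == 6
        ids = [fov.fov_id for fov, _ in batch]
        assert len(set(ids)) == 6

    def test_rerun_reproduces_batch(self):
        b1 = generate_experiment(self._design(2), master_seed=5)
        b2 = generate_experiment(self._design(2), master_seed=5)
        for (f1, _), (f2, _) in zip(b1, b2):
            np.testing.assert_array_equal(f1.particle_channel, f2.particle_channel)

    def test_duplicate_condition_rejected(self):
        cfg = SyntheticConfig()
        cond = ConditionLabel("HM", "pbs", 100, 37)
        with pytest.raises(ValidationError, match="duplicate"):
            generate_experiment([(cond, cfg, 2), (cond, cfg, 2)], master_seed=1)

    def test_zero_fovs_rejected(self):
        cfg = SyntheticConfig()
        with pytest.raises(ValidationError):
            generate_experiment({ConditionLabel("HM", "pbs", 100, 37): (cfg, 0)}, 1)

    def test_higher_uptake_multiplier_plants_more_particles(self):
        """HM (multiplier 2.5) must plant more particles per cell than LM
        (1.3) on average across a batch."""
        batch = generate_experiment(self._design(12), master_seed=9)
        per_phen = {"HM": [], "LM": []}
        for fov, gt in batch:
            if gt.cells:
                per_phen[fov.condition.phenotype].append(gt.n_particles / len(gt.cells))
        assert np.mean(per_phen["HM"]) > np.mean(per_phen["LM"])


def test_planted_signal_monotone_in_dose():
    """Total above-background particle intensity rises with the per-cell dose."""
    totals = []
    for dose in (500.0, 2000.0, 8000.0):
        acc = 0.0
        for s in range(20):
            cfg = SyntheticConfig(
                image_shape=(96, 96),
                n_cells_mean=8,
                n_cells_sd=0,
                particles_per_cell_mean=dose,
                seed=1000 + s,
            )
            fov, _ = generate_fov(cfg, ConditionLabel("HM", "pbs", 100, 37))
            acc += float(fov.particle_channel.sum()) - cfg.background_level * fov.particle_channel.size
        totals.append(acc / 20)
    assert totals[0] < totals[1] < totals[2]
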