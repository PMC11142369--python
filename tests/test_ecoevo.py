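import numpy as np
import pytest

import phagehab as ph
from phagehab.ecoevo import EcoParams, StepSizeError, detect_hotspots, occupancy_map, run_experiment
from phagehab.geometry import build_hex_array
from phagehab.kinetics import MutationParams
from phagehab.transport import ConcentrationField


def flat_field(layout, c):
    return ConcentrationField(
        times_s=np.array([0.0]),
        values=np.full((1, layout.n_chambers), float(c)),
        chamber_ids=[ch.id for ch in layout.chambers],
    )


@pytest.fixture()
def mini_layout():
    return build_hex_array(3, 3, target_area_mm2=0.9)


class TestRunExperiment:
    def test_decoupled_limit_is_nutrient_limited_growth(self, mini_layout):
        # no phage, no mutation, no migration: pure logistic-like growth
        eco = EcoParams(
            adsorption_constant_ml_h=0.0,
            migration_rate_per_h=0.0,
            nutrient_exchange=False,
            nutrient_influx_per_h=0.0,
            nutrient_initial=5e4,
        )
        rec = run_experiment(
            mini_layout, flat_field(mini_layout, 0.0), eco, MutationParams(theta_D=0.0),
            duration_h=20.0, seed=4, dt_h=0.01, initial_cells=1000,
        )
        inlet = rec.chamber_ids.index(mini_layout.inlet.chamber)
        final = rec.S[-1, inlet]
        # each division costs one nutrient unit: plateau ~ inoculum + budget
        # (the last step may overdraw the remaining nutrient by one batch)
        assert final <= 1000 + 5e4 + 2500
        assert final > 0.8 * 5e4
        assert rec.R[-1].sum() == 0

    def test_zero_field_identical_to_phage_free_run(self, mini_layout):
        mut = MutationParams(theta_D=1e-6)
        kw = dict(duration_h=5.0, seed=9, dt_h=0.01, initial_cells=500)
        with_ka = run_experiment(
            mini_layout, flat_field(mini_layout, 0.0), EcoParams(), mut, **kw
        )
        without_ka = run_experiment(
            mini_layout, flat_field(mini_layout, 0.0), EcoParams(adsorption_constant_ml_h=0.0), mut, **kw
        )
        np.testing.assert_array_equal(with_ka.S, without_ka.S)
        np.testing.assert_array_equal(with_ka.R, without_ka.R)

    def test_bookkeeping_births_minus_lysis(self, mini_layout):
        # ΔS+ΔI+ΔR between frames must equal births − lysis deaths exactly
        eco = EcoParams(couple_lysis_to_transport=True)
        rec = run_experiment(
            mini_layout, flat_field(mini_layout, 5e6), eco, MutationParams(theta_L=1e-4),
            duration_h=8.0, seed=12, dt_h=0.005, initial_cells=2000,
        )
        totals = (rec.S + rec.I + rec.R).sum(axis=1)
        expected = totals[0] + (rec.cum_births - rec.cum_lysed)
        np.testing.assert_array_equal(totals, expected)

    def test_migration_conserves_cells(self, mini_layout):
        eco = EcoParams(mu_max_per_h=0.0, adsorption_constant_ml_h=0.0, migration_rate_per_h=0.3)
        rec = run_experiment(
            mini_layout, flat_field(mini_layout, 0.0), eco, MutationParams(theta_D=0.0),
            duration_h=10.0, seed=2, dt_h=0.01, initial_cells=5000,
        )
        totals = rec.S.sum(axis=1)
        assert np.all(totals == 5000)
        assert rec.S[-1].max() < 5000  # cells actually moved

    def test_exposure_gated_mutation(self, mini_layout):
        # concentration below c*: only the (zero) spontaneous pathway remains
        mut = MutationParams(theta_D=0.0, theta_L=1e-3)
        eco = EcoParams(adsorption_constant_ml_h=0.0, exposure_threshold_per_ml=1e6)
        below = run_experiment(
            mini_layout, flat_field(mini_layout, 1e5), eco, mut,
            duration_h=6.0, seed=3, dt_h=0.01, initial_cells=2000,
        )
        above = run_experiment(
            mini_layout, flat_field(mini_layout, 1e7), eco, mut,
            duration_h=6.0, seed=3, dt_h=0.01, initial_cells=2000,
        )
        assert below.R[-1].sum() == 0
        assert above.R[-1].sum() > 0

    def test_oversized_step_rejected(self, mini_layout):
        with pytest.raises(StepSizeError):
            run_experiment(
                mini_layout, flat_field(mini_layout, 2e9), EcoParams(), MutationParams(),
                duration_h=1.0, seed=0, dt_h=0.05,
            )

    def test_monotone_colonization_phage_free(self):
        layout = build_hex_array(6, 10, target_area_mm2=5.3)
        eco = EcoParams()
        rec = run_experiment(
            layout, flat_field(layout, 0.0), eco, MutationParams(),
            duration_h=24.0, seed=21, dt_h=0.01, record_every=100, initial_cells=10_000,
        )
        occupied = ((rec.S + rec.I + rec.R) >= 1).sum(axis=1)
        assert np.all(np.diff(occupied) >= 0)
        assert occupied[-1] > occupied[0]


class TestMoiCurves:
    def test_no_phage_monotone_to_plateau(self):
        df = ph.well_mixed_moi_curve(EcoParams(), MutationParams(), 100_000, 0.0, 24.0, seed=3)
        assert df.biomass.is_monotonic_increasing
        assert df.biomass.iloc[-1] > 0.9e8

    def test_ancestor_excluded_at_moi_1000(self):
        base = ph.well_mixed_moi_curve(EcoParams(), MutationParams(), 100_000, 0.0, 24.0, seed=3)
        challenged = ph.well_mixed_moi_curve(EcoParams(), MutationParams(), 100_000, 1000.0, 24.0, seed=3)
        assert challenged.biomass.iloc[-1] < 0.01 * base.biomass.iloc[-1]

    def test_resistant_strain_ignores_phage(self):
        eco_r = EcoParams(adsorption_constant_ml_h=0.0)
        moi0 = ph.well_mixed_moi_curve(eco_r, MutationParams(), 100_000, 0.0, 24.0, seed=3)
        moi1000 = ph.well_mixed_moi_curve(eco_r, MutationParams(), 100_000, 1000.0, 24.0, seed=3)
        np.testing.assert_array_equal(moi0.biomass.values, moi1000.biomass.values)

    def test_midlog_challenge_halts_ancestor_growth(self):
        df = ph.well_mixed_moi_curve(
            EcoParams(), MutationParams(), 10_000_000, 10.0, 12.0, seed=5,
            phage_time_h=2.0, nutrient_capacity=1e9,
        )
        at_challenge = df[df.time_h <= 2.0].biomass.iloc[-1]
        assert df.biomass.iloc[-1] < at_challenge


class TestDetectors:
    def test_hotspots_empty_without_resistance(self, mini_layout):
        rec = run_experiment(
            mini_layout, flat_field(mini_layout, 0.0), EcoParams(), MutationParams(theta_D=0.0),
            duration_h=2.0, seed=1, dt_h=0.01, initial_cells=100,
        )
        assert detect_hotspots(rec, threshold=1) == []

    def test_hand_built_crossing_is_recovered(self, mini_layout):
        rec = run_experiment(
            mini_layout, flat_field(mini_layout, 0.0), EcoParams(), MutationParams(theta_D=0.0),
            duration_h=1.0, seed=1, dt_h=0.01, record_every=10, initial_cells=100,
        )
        j = 4
        rec.R[7:, j] = 150  # plant a crossing at frame 7
        hits = detect_hotspots(rec, threshold=100)
        assert hits == [(rec.chamber_ids[j], pytest.approx(rec.times_h[7]))]

    def test_occupancy_map_conserves_snapshot(self, mini_layout):
        rec = run_experiment(
            mini_layout, flat_field(mini_layout, 0.0), EcoParams(), MutationParams(),
            duration_h=3.0, seed=6, dt_h=0.01, record_every=50, initial_cells=1000,
        )
        grid0 = occupancy_map(rec, 0.0)
        inlet_mask = grid0.chamber_id == mini_layout.inlet.chamber
        assert grid0.loc[inlet_mask, "total_cells"].iloc[0] == 1000
        assert grid0.loc[~inlet_mask, "total_cells"].sum() == 0
        grid = occupancy_map(rec, 2.0)
        frame = int(np.argmin(np.abs(rec.times_h - 2.0)))
        assert grid.total_cells.sum() == rec.totals(frame).sum()
        with pytest.raises(ValueError):
            occupancy_map(rec, 99.0)


class TestReferencePresetRun:
    def test_hotspot_emerges_in_low_intermediate_band(self, preset_experiment):
        record, field = preset_experiment
        hits = detect_hotspots(record, threshold=100)
        assert hits, "no resistant hot spot emerged"
        cid, t_cross = hits[0]
        assert t_cross <= 30.0
        c0 = field.at(0.0)
        j = record.chamber_ids.index(cid)
        assert c0[j] < np.median(c0)

    def test_gradient_refuge_for_sensitive_cells(self, preset_experiment):
        record, _ = preset_experiment
        rows = record.chamber_rows
        n_rows = rows.max() + 1
        S_by_row = np.array(
            [record.S[:, rows == r].sum(axis=1).mean() for r in range(n_rows)]
        )
        assert S_by_row[-3:].sum() > S_by_row[:3].sum()
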