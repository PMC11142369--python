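import numpy as np
import pytest

from phagehab.geometry import CorridorSpec, NanoslitSpec, build_hex_array
from phagehab.transport import (
    TransportError,
    TransportParams,
    conductance_matrix,
    row_profile,
    simulate_gradient,
    steady_state_field,
)

D = 8e-8  # cm^2/s, phage diffusivity


def chain_layout(n, equal_slits=False):
    """1-D chain of n chambers; with equal_slits the end nanoslits have the
    same conductance as the corridors (slit: 625 um x 100 nm / 100 um =
    corridor: 5 um x 10 um / 80 um cross-section over length)."""
    slit = NanoslitSpec(width_um=625.0, length_um=100.0) if equal_slits else NanoslitSpec()
    return build_hex_array(n, 1, target_area_mm2=0.1 * n, nanoslit=slit)


class TestConductanceMatrix:
    def test_two_chambers_symmetric_zero_row_sums(self):
        layout = build_hex_array(1, 2, target_area_mm2=0.2)
        sys = conductance_matrix(layout, TransportParams(), include_slits=False)
        L = sys.laplacian.toarray()[:2, :2]
        assert L[0, 1] == pytest.approx(L[1, 0])
        assert L[0, 1] > 0
        np.testing.assert_allclose(L.sum(axis=1), 0.0, atol=1e-20)

    def test_corridor_conductance_value_and_length_scaling(self):
        spec = CorridorSpec(width_um=5.0, length_um=80.0, depth_um=10.0)
        expected = D * (5e-4 * 10e-4) / 80e-4  # D*A/L in ml/s
        layout = build_hex_array(1, 2, corridor=spec, target_area_mm2=0.2)
        g = conductance_matrix(layout, TransportParams()).laplacian[0, 1]
        assert g == pytest.approx(expected)
        double = CorridorSpec(width_um=5.0, length_um=160.0, depth_um=10.0)
        layout2 = build_hex_array(1, 2, corridor=double, target_area_mm2=0.2)
        g2 = conductance_matrix(layout2, TransportParams()).laplacian[0, 1]
        assert g2 == pytest.approx(g / 2)

    def test_nanoslit_100x_less_conductive_per_unit_width(self):
        # same lateral footprint, 100 nm vs 10 um depth
        layout = build_hex_array(
            2,
            1,
            corridor=CorridorSpec(width_um=50.0, length_um=20.0, depth_um=10.0),
            nanoslit=NanoslitSpec(width_um=50.0, length_um=20.0, depth_nm=100.0),
            target_area_mm2=0.2,
        )
        sys = conductance_matrix(layout, TransportParams())
        g_corr = sys.laplacian[0, 1]
        g_slit = sys.laplacian[0, sys.channel_index["bottom"]]
        assert g_corr / g_slit == pytest.approx(100.0)

    def test_chain_matches_direct_laplacian_construction(self):
        # chain of N equal compartments: operator == g * (1-D discrete Laplacian)
        n = 6
        layout = chain_layout(n)
        sys = conductance_matrix(layout, TransportParams(), include_slits=False)
        L = sys.laplacian.toarray()[:n, :n]
        cor = layout.corridors[0]
        g = D * (cor.width_um * 1e-4 * cor.depth_um * 1e-4) / (cor.length_um * 1e-4)
        ref = np.zeros((n, n))
        for i in range(n - 1):
            ref[i, i + 1] = ref[i + 1, i] = g
            ref[i, i] -= g
            ref[i + 1, i + 1] -= g
        np.testing.assert_allclose(L, ref, rtol=1e-12)


class TestSimulateGradient:
    def test_both_boundaries_zero_gives_zero_field(self):
        layout = build_hex_array(3, 3, target_area_mm2=0.9)
        field = simulate_gradient(
            layout, TransportParams(time_step_s=60.0), duration_h=1.0,
            boundary_values={"bottom": 0.0, "top": 0.0},
        )
        assert np.all(field.values == 0.0)

    def test_uniform_boundary_monotone_convergence_to_c0(self):
        layout = build_hex_array(3, 3, target_area_mm2=0.9)
        c0 = 2e9
        field = simulate_gradient(
            layout, TransportParams(time_step_s=300.0), duration_h=800.0,
            boundary_values={"bottom": c0, "top": c0}, store_every=50,
        )
        assert np.all(np.diff(field.values, axis=0) >= -1e-6 * c0)
        np.testing.assert_allclose(field.final, c0, rtol=1e-2)

    def test_maximum_principle_and_monotone_relaxation(self):
        layout = build_hex_array(4, 4, target_area_mm2=1.6)
        c0 = 2e9
        field = simulate_gradient(layout, TransportParams(time_step_s=30.0), duration_h=5.0)
        assert field.values.min() >= 0.0
        assert field.values.max() <= c0 * (1 + 1e-12)
        assert np.all(np.diff(field.values, axis=0) >= -1e-9 * c0)

    def test_closed_system_conserves_virions(self):
        layout = build_hex_array(3, 3, target_area_mm2=0.9)
        sys = conductance_matrix(layout, TransportParams(), include_slits=False)
        rng = np.random.default_rng(0)
        init = rng.uniform(0, 1e9, layout.n_chambers)
        field = simulate_gradient(
            layout, TransportParams(time_step_s=60.0), duration_h=10.0,
            initial=init, closed=True, store_every=1,
        )
        totals = field.values @ sys.volumes_ml
        rel_step = np.abs(np.diff(totals)) / totals[0]
        assert rel_step.max() < 1e-9

    def test_bad_time_step_rejected(self):
        layout = build_hex_array(2, 2, target_area_mm2=0.4)
        with pytest.raises(TransportError):
            simulate_gradient(layout, TransportParams(time_step_s=-1.0), duration_h=1.0)


class TestSteadyState:
    def test_single_chamber_tracks_its_channel(self):
        layout = build_hex_array(1, 1, target_area_mm2=0.1)
        c0 = 2e9
        c = steady_state_field(layout, TransportParams(), boundary_values={"bottom": c0, "top": c0})
        assert c[0] == pytest.approx(c0)

    def test_symmetric_layout_midpoint_at_half(self):
        # even chain with equal end couplings: profile is antisymmetric, so the
        # two middle chambers straddle c0/2
        layout = chain_layout(4, equal_slits=True)
        c0 = 2e9
        c = steady_state_field(layout, TransportParams(), boundary_values={"bottom": c0, "top": 0.0})
        assert (c[1] + c[2]) / 2 == pytest.approx(c0 / 2, rel=1e-9)

    def test_agrees_with_dense_brute_force(self):
        layout = build_hex_array(3, 4, target_area_mm2=1.2)
        params = TransportParams()
        sys = conductance_matrix(layout, params)
        n = sys.n_chambers
        L = sys.laplacian.toarray()
        bvals = {"bottom": params.feed_concentration_per_ml, "top": 0.0}
        b = np.zeros(2)
        for cid, idx in sys.channel_index.items():
            b[idx - n] = bvals[cid]
        dense = np.linalg.solve(-L[:n, :n], L[:n, n:] @ b)
        np.testing.assert_allclose(steady_state_field(layout, params), dense, rtol=1e-10)

    def test_detached_layout_is_singular(self):
        layout = build_hex_array(2, 2, target_area_mm2=0.4)
        layout.nanoslits = []
        with pytest.raises(TransportError):
            steady_state_field(layout, TransportParams())

    def test_chain_steady_profile_linear(self):
        # equal conductances end to end: discrete Laplace solution is linear
        layout = chain_layout(8, equal_slits=True)
        c0 = 2e9
        c = steady_state_field(layout, TransportParams(), boundary_values={"bottom": c0, "top": 0.0})
        expected = np.linspace(c0, 0.0, 10)[1:-1]  # 8 interior nodes of a 10-node chain
        np.testing.assert_allclose(c, expected, rtol=0.01)

    def test_long_simulation_converges_to_steady_state(self):
        layout = chain_layout(4, equal_slits=True)
        params = TransportParams(time_step_s=600.0)
        target = steady_state_field(layout, params)
        field = simulate_gradient(layout, params, duration_h=3000.0, store_every=100)
        np.testing.assert_allclose(field.final, target, rtol=0.01)


class TestReferencePresetGradient:
    def test_20h_profile_strictly_decreasing_from_phage_channel(self, device_preset, preset_gradient):
        prof = row_profile(device_preset, preset_gradient.at(20 * 3600.0))
        assert np.all(np.diff(prof) < 0)

    def test_field_spans_orders_of_magnitude(self, device_preset, preset_gradient):
        prof = row_profile(device_preset, preset_gradient.at(20 * 3600.0))
        assert prof[0] / prof[-1] > 1e3
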