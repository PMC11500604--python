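"""Voltage classification, ERP fields (regional / harmonic), substrate rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atrialerp import scenarios as sc
from atrialerp.courtemanche import INFLAMMATION
from atrialerp.synthetic import (ERPMeasurementSet, SyntheticPatientSpec,
                                 make_fixture_cable, make_patient, make_sheet)


class TestClassifyVoltage:
    def test_thresholds(self):
        cls = sc.classify_voltage(np.array([0.05, 0.3, 1.2, 0.1, 0.5]))
        assert list(cls) == [sc.ABLATION, sc.FIBROSIS, sc.HEALTHY,
                             sc.FIBROSIS, sc.HEALTHY]

    def test_uniform_healthy_map(self):
        assert sc.lva_fraction(np.full(100, 1.0)) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            sc.classify_voltage(np.array([-0.1]))

    def test_size_mismatch_rejected(self, small_patient):
        with pytest.raises(ValueError, match="covers"):
            sc.classify_voltage(np.ones(3), small_patient.mesh)


class TestRegionalAssign:
    def test_single_measurement_constant_field(self, small_patient):
        mesh = small_patient.mesh
        m = ERPMeasurementSet(positions=mesh.nodes[10], erp_ms=[240.0])
        field = sc.regional_assign(mesh, m)
        assert np.all(field == 240.0)

    def test_same_region_measurements_averaged(self):
        mesh = make_sheet(20.0, 20.0, dx=2.0)
        mesh.region[:] = 0
        m = ERPMeasurementSet(
            positions=[mesh.nodes[3], mesh.nodes[50]], erp_ms=[230.0, 250.0])
        field = sc.regional_assign(mesh, m)
        assert np.all(field == 240.0)

    def test_values_subset_of_region_means(self, small_patient):
        p = small_patient
        field = sc.regional_assign(p.mesh, p.measurements)
        meas = p.measurements
        allowed = set(np.round(meas.erp_ms, 9))
        for r in np.unique(p.mesh.region):
            inside = meas.erp_ms[p.mesh.region[meas.node_ids] == r]
            if inside.size:
                allowed.add(round(float(inside.mean()), 9))
        assert set(np.round(np.unique(field), 9)) <= allowed


class TestLaplaceInterpolate:
    def test_single_value_harmonic_is_constant(self, small_patient):
        mesh = small_patient.mesh
        m = ERPMeasurementSet(positions=mesh.nodes[7], erp_ms=[254.0])
        field = sc.laplace_interpolate(mesh, m)
        np.testing.assert_allclose(field, 254.0)

    def test_exact_at_measurement_nodes(self, small_patient):
        p = small_patient
        field = sc.laplace_interpolate(p.mesh, p.measurements)
        snapped = p.measurements.snapped(p.mesh)
        np.testing.assert_allclose(field[snapped.node_ids], snapped.erp_ms)

    def test_cable_gives_linear_ramp(self):
        """Two boundary values on a 1D cable interpolate to the straight
        line (closed-form harmonic solution)."""
        cable = make_fixture_cable()
        m = ERPMeasurementSet(
            positions=[cable.nodes[0], cable.nodes[-1]],
            erp_ms=[200.0, 300.0])
        field = sc.laplace_interpolate(cable, m)
        mid = field[cable.n_nodes // 2]
        assert mid == pytest.approx(250.0, abs=1.0)
        expect = 200.0 + 100.0 * cable.nodes[:, 0] / 40.0
        np.testing.assert_allclose(field, expect, atol=1.0)

    def test_conflicting_duplicates_rejected(self, small_patient):
        mesh = small_patient.mesh
        m = ERPMeasurementSet(positions=[mesh.nodes[5], mesh.nodes[5]],
                              erp_ms=[200.0, 300.0])
        with pytest.raises(ValueError, match="conflicting"):
            sc.laplace_interpolate(mesh, m)

    def test_unmeasured_component_rejected(self):
        cable = make_fixture_cable()
        mid = (cable.nodes[cable.elements].mean(axis=1)[:, 0] > 18) & \
              (cable.nodes[cable.elements].mean(axis=1)[:, 0] < 22)
        cable.conductive[mid] = False
        m = ERPMeasurementSet(positions=cable.nodes[0], erp_ms=[250.0])
        with pytest.raises(ValueError, match="component"):
            sc.laplace_interpolate(cable, m)

    @settings(deadline=None, max_examples=15)
    @given(seed=st.integers(0, 10_000))
    def test_maximum_principle(self, seed):
        """Interpolated fields never leave the measured range and hit the
        measurements exactly (non-negative-weight Laplacian)."""
        p = make_patient(SyntheticPatientSpec(width=30.0, height=30.0,
                                              dx=2.0, seed=seed))
        field = sc.laplace_interpolate(p.mesh, p.measurements)
        lo, hi = p.measurements.erp_ms.min(), p.measurements.erp_ms.max()
        assert field.min() >= lo - 1e-9
        assert field.max() <= hi + 1e-9


class TestBuildScenario:
    def test_scenario_a_homogeneous(self, small_patient, ladder10):
        m = sc.build_scenario(small_patient.mesh, sc.ScenarioSpec("A"),
                              ladder10)
        assert m.metadata["erp_field"].std() == 0.0
        assert np.unique(m.scales, axis=0).shape[0] == 1
        np.testing.assert_allclose(m.scales[0],
                                   ladder10.levels[-1].as_array())

    def test_scenario_b_uses_table(self, small_patient, ladder10):
        table = {"default": 160.0}
        m = sc.build_scenario(small_patient.mesh,
                              sc.ScenarioSpec("B", literature_table=table),
                              ladder10)
        assert np.all(m.metadata["erp_field"] == 160.0)

    def test_default_table_mean_near_159(self):
        table = sc.default_literature_table()
        vals = [v for k, v in table.items() if not k.startswith("_")]
        assert 140.0 <= min(vals) and max(vals) <= 180.0
        assert np.mean(vals) == pytest.approx(159.0, abs=4.0)

    def test_degenerate_d_equals_homogeneous(self, small_patient, ladder10):
        p = small_patient
        m = ERPMeasurementSet(
            positions=p.measurements.positions,
            erp_ms=np.full(p.measurements.erp_ms.size, 254.0))
        built = sc.build_scenario(p.mesh, sc.ScenarioSpec("D"), ladder10,
                                  measurements=m)
        np.testing.assert_allclose(built.metadata["erp_field"], 254.0)
        assert np.unique(built.scales, axis=0).shape[0] == 1

    def test_c_and_d_agree_at_measurement_nodes(self, small_patient,
                                                ladder10):
        p = small_patient
        snapped = p.measurements.snapped(p.mesh)
        mc = sc.build_scenario(p.mesh, sc.ScenarioSpec("C"), ladder10,
                               measurements=p.measurements)
        md = sc.build_scenario(p.mesh, sc.ScenarioSpec("D"), ladder10,
                               measurements=p.measurements)
        fd = md.metadata["erp_field"][snapped.node_ids]
        np.testing.assert_allclose(fd, snapped.erp_ms)
        # C holds the regional mean there, equal when alone in its region
        fc = mc.metadata["erp_field"][snapped.node_ids]
        region_of = p.mesh.region[snapped.node_ids]
        for k, r in enumerate(region_of):
            inside = snapped.erp_ms[region_of == r]
            assert fc[k] == pytest.approx(inside.mean())

    def test_d_field_discrete_harmonicity(self, small_patient, ladder10):
        """Away from the measurement nodes the interpolated field is
        discretely harmonic: every free node equals the mean of its graph
        neighbours (the smoothness guarantee of the construction)."""
        p = small_patient
        md = sc.build_scenario(p.mesh, sc.ScenarioSpec("D"), ladder10,
                               measurements=p.measurements)
        f = md.metadata["erp_field"]
        fixed = np.zeros(p.mesh.n_nodes, dtype=bool)
        fixed[p.measurements.snapped(p.mesh).node_ids] = True
        pairs, _ = p.mesh.edges(conductive_only=True)
        import scipy.sparse as sp
        n = p.mesh.n_nodes
        A = sp.coo_matrix((np.ones(len(pairs)),
                           (pairs[:, 0], pairs[:, 1])), shape=(n, n))
        A = (A + A.T).tocsr()
        deg = np.asarray(A.sum(axis=1)).ravel()
        resid = f - (A @ f) / np.maximum(deg, 1)
        assert np.abs(resid[~fixed]).max() < 1e-6

    def test_missing_inputs_rejected(self, small_patient, ladder10):
        with pytest.raises(ValueError, match="measurement"):
            sc.build_scenario(small_patient.mesh, sc.ScenarioSpec("D"),
                              ladder10)
        with pytest.raises(ValueError, match="voltage"):
            sc.build_scenario(small_patient.mesh,
                              sc.ScenarioSpec("A", substrate="fibrosis_only"),
                              ladder10)
        with pytest.raises(ValueError):
            sc.ScenarioSpec("E")


class TestSubstrate:
    def _classes(self, mesh, frac_fib=0.5, frac_abl=0.1, seed=3):
        rng = np.random.default_rng(seed)
        cls = np.full(mesh.n_nodes, sc.HEALTHY)
        n = mesh.n_nodes
        pick = rng.permutation(n)
        cls[pick[:int(frac_abl * n)]] = sc.ABLATION
        cls[pick[int(frac_abl * n):int((frac_abl + frac_fib) * n)]] = \
            sc.FIBROSIS
        return cls

    def test_thirty_percent_rule_exact(self, ladder10):
        """Of the fibrosis-class elements exactly 30% (rounded half-up)
        become non-conductive."""
        mesh = make_sheet(50.0, 50.0, dx=1.0)
        cls = np.full(mesh.n_nodes, sc.FIBROSIS)
        out = sc.apply_substrate(mesh, cls, "fibrosis_only", seed=0)
        n_fib = mesh.n_elements
        expect = int(np.floor(0.3 * n_fib + 0.5))
        assert int((~out.conductive).sum()) == expect

    def test_seeded_selection_reproducible(self, small_patient):
        mesh = small_patient.mesh
        cls = self._classes(mesh)
        a = sc.apply_substrate(mesh, cls, "lesions_and_fibrosis", seed=9)
        b = sc.apply_substrate(mesh, cls, "lesions_and_fibrosis", seed=9)
        assert np.array_equal(a.conductive, b.conductive)
        c2 = sc.apply_substrate(mesh, cls, "lesions_and_fibrosis", seed=10)
        assert not np.array_equal(a.conductive, c2.conductive)

    def test_fibrosis_only_keeps_lesions_conductive(self, small_patient):
        mesh = small_patient.mesh
        cls = self._classes(mesh)
        out = sc.apply_substrate(mesh, cls, "fibrosis_only", seed=0)
        ec = sc._element_classes(mesh, cls)
        assert out.conductive[ec == sc.ABLATION].all()
        out2 = sc.apply_substrate(mesh, cls, "lesions_and_fibrosis", seed=0)
        assert not out2.conductive[ec == sc.ABLATION].any()

    def test_inflammation_composition(self, small_patient):
        mesh = small_patient.mesh.copy()
        mesh.scales[:] = 2.0
        cls = np.full(mesh.n_nodes, sc.FIBROSIS)
        out = sc.apply_substrate(mesh, cls, "fibrosis_only", seed=1)
        inflamed = out.metadata["inflamed_nodes"]
        expect = np.tile(2.0 * INFLAMMATION.scale.as_array(),
                         (inflamed.size, 1))
        np.testing.assert_allclose(out.scales[inflamed], expect)

    def test_missing_ablation_class_warns(self, small_patient):
        mesh = small_patient.mesh
        cls = np.full(mesh.n_nodes, sc.HEALTHY)
        with pytest.warns(UserWarning, match="no ablation"):
            sc.apply_substrate(mesh, cls, "lesions_and_fibrosis", seed=0)

    def test_unknown_mode_rejected(self, small_patient):
        with pytest.raises(ValueError):
            sc.apply_substrate(small_patient.mesh,
                               np.zeros(small_patient.mesh.n_nodes), "bogus")
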