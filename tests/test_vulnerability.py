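"""Site sampling, re-entry detection, TCL computation, result bookkeeping."""

import numpy as np
import pytest

from atrialerp.synthetic import make_sheet
from atrialerp.vulnerability import (NoSustainedActivity, SiteOutcome,
                                     VulnerabilityResult, compute_tcl,
                                     detect_reentry, select_sites)


class TestSelectSites:
    def test_spacing_larger_than_mesh_gives_one_site(self):
        mesh = make_sheet(20.0, 20.0, dx=2.0)
        sites = select_sites(mesh, spacing=100.0, seed=0)
        assert len(sites) == 1

    def test_seed_determinism(self):
        mesh = make_sheet(40.0, 40.0, dx=2.0)
        a = select_sites(mesh, spacing=15.0, seed=4)
        b = select_sites(mesh, spacing=15.0, seed=4)
        assert np.array_equal(a.node_ids, b.node_ids)

    def test_pairwise_spacing_guaranteed(self):
        mesh = make_sheet(60.0, 60.0, dx=2.0)
        sites = select_sites(mesh, spacing=20.0, seed=1)
        for i, a in enumerate(sites.node_ids):
            d = mesh.geodesic_distances([a])
            for b in sites.node_ids[i + 1:]:
                assert d[b] >= 20.0 - 1e-9

    def test_site_count_on_10cm_sheet(self):
        """Farthest-point sampling at 2 cm spacing on a 10x10 cm sheet lands
        between the disc-packing bounds (20-35 sites)."""
        mesh = make_sheet(100.0, 100.0, dx=2.0)
        sites = select_sites(mesh, spacing=20.0, seed=0)
        assert 20 <= len(sites) <= 35

    def test_empty_surface_rejected(self):
        mesh = make_sheet(20.0, 20.0, dx=2.0)
        mesh.conductive[:] = False
        with pytest.raises(ValueError, match="empty"):
            select_sites(mesh, spacing=10.0, seed=0)


class TestDetectReentry:
    def test_record_too_short_rejected(self):
        with pytest.raises(ValueError, match="record"):
            detect_reentry(np.array([100.0]), t_last_stim=100.0,
                           record_end=500.0)

    def test_extinguished_wave_is_not_reentry(self):
        la = np.array([50.0, 120.0, 300.0, -np.inf])
        assert not detect_reentry(la, t_last_stim=0.0, record_end=1100.0)

    def test_late_activity_is_reentry(self):
        la = np.array([50.0, 120.0, 800.0])
        assert detect_reentry(la, t_last_stim=0.0, record_end=1100.0)

    def test_silent_mesh_is_not_reentry(self):
        la = np.full(10, -np.inf)
        assert not detect_reentry(la, t_last_stim=0.0, record_end=1100.0)


class TestComputeTcl:
    def test_five_equally_spaced_upstrokes(self):
        """Upstrokes at 0, 210, 420, 630, 840 ms give TCL 210 ms."""
        t = np.arange(0.0, 1000.0, 0.5)
        V = np.full_like(t, -80.0)
        for onset in (0.0, 210.0, 420.0, 630.0, 840.0):
            V[(t >= onset) & (t < onset + 100.0)] = 20.0
        assert compute_tcl(t, V) == pytest.approx(210.0, abs=1.0)

    def test_periodic_trace(self):
        t = np.arange(0.0, 1000.0, 0.5)
        V = -80.0 + 100.0 * (np.sin(2 * np.pi * t / 200.0) > 0.7)
        assert compute_tcl(t, V) == pytest.approx(200.0, abs=2.0)

    def test_single_peak_raises(self):
        t = np.arange(0.0, 1000.0, 0.5)
        V = np.where((t >= 100.0) & (t < 300.0), 10.0, -80.0)
        with pytest.raises(NoSustainedActivity):
            compute_tcl(t, V)

    def test_deadtime_merges_notched_upstrokes(self):
        t = np.arange(0.0, 600.0, 0.5)
        V = np.full_like(t, -80.0)
        # two rapid deflections 20 ms apart then one clean beat at 400
        for onset in (100.0, 120.0, 400.0):
            V[(t >= onset) & (t < onset + 10.0)] = 20.0
        assert compute_tcl(t, V) == pytest.approx(300.0, abs=2.0)


def test_cross_field_on_quiescent_sheet_is_not_reentry():
    """A paced wave that sweeps the sheet and extinguishes at the boundary
    is classified as no re-entry."""
    from atrialerp.vulnerability import induce_cross_field

    mesh = make_sheet(30.0, 30.0, dx=2.0, sigma_l=0.35)
    rec, flag = induce_cross_field(mesh, s2_delay=400.0, record_ms=1000.0,
                                   dt=0.05)
    assert flag is False
    assert rec.V.shape[1] == 1


class TestResultBookkeeping:
    def _mk(self, flags):
        res = VulnerabilityResult(scenario="X")
        for k, f in enumerate(flags):
            res.outcomes.append(SiteOutcome(site=k, evaluable=f is not None,
                                            induced=bool(f),
                                            tcl=200.0 + k if f else None))
        return res

    def test_ratio_definition(self):
        res = self._mk([True, False, False, True])
        assert res.ratio == 0.5
        assert res.n_induced == 2

    def test_ratio_excludes_non_evaluable(self):
        res = self._mk([True, None, False])
        assert res.n_evaluable == 2
        assert res.ratio == 0.5

    def test_all_quiet_ratio_zero(self):
        assert self._mk([False, False]).ratio == 0.0

    def test_ratio_invariant_to_ordering(self):
        flags = [True, False, True, False, False]
        a = self._mk(flags)
        b = self._mk(flags[::-1])
        assert a.ratio == b.ratio

    def test_summary_contains_tcl_stats(self):
        s = self._mk([True, True, False]).summary()
        assert s["n_sites"] == 3
        assert s["mean_tcl"] == pytest.approx(200.5)
        assert s["sd_tcl"] == pytest.approx(np.std([200.0, 201.0], ddof=1))
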