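"""Shared fixtures.

Expensive artifacts (tuned conductivities, the calibrated remodeling
endpoint, the scaled-down ladder, synthetic patients) are session-scoped so
the whole suite pays for them once.  Sheet work runs at dx = 1.25 mm and
dt = 50 us; cable calibration at the reference 0.4 mm / 20 us.
"""

import numpy as np
import pytest

from atrialerp import calibration as cal
from atrialerp import engine
from atrialerp.synthetic import (SyntheticPatientSpec, make_patient,
                                 make_fixture_cable)

DT_SHEET = engine.DT_SHEET
DX_SHEET = 1.25


@pytest.fixture(scope="session")
def sigma_cable():
    """Longitudinal conductivity for 0.3 m/s on the 0.4 mm cable."""
    return cal.tune_conductivity(0.3)


@pytest.fixture(scope="session")
def cable(sigma_cable):
    return make_fixture_cable(sigma_l=sigma_cable)


@pytest.fixture(scope="session")
def control_erp(cable):
    """Cable ERP of the unscaled (control) model, full in-silico protocol."""
    return cal.cable_erp(np.ones(9), cable=cable)


@pytest.fixture(scope="session")
def af_endpoint(cable):
    """Chronic-AF endpoint calibrated to a 157 ms cable ERP."""
    scale, alpha, erp = cal.calibrate_af_endpoint(157.0, cable=cable)
    return scale, alpha, erp


@pytest.fixture(scope="session")
def ladder10(cable, af_endpoint):
    """Scaled-down (10-level) remodeling ladder with measured cable ERPs."""
    return cal.build_ladder(n_levels=10, endpoint=af_endpoint[0], cable=cable)


@pytest.fixture(scope="session")
def sigma_sheet_03():
    return cal.tune_conductivity(0.3, dx=DX_SHEET, dt=DT_SHEET)


@pytest.fixture(scope="session")
def sigma_sheet_07():
    return cal.tune_conductivity(0.7, dx=DX_SHEET, dt=DT_SHEET)


@pytest.fixture(scope="session")
def sigma_sheet10_03():
    """0.3 m/s at the finer 1.0 mm sheet resolution (re-entry fixtures)."""
    return cal.tune_conductivity(0.3, dx=1.0, dt=DT_SHEET)


@pytest.fixture(scope="session")
def flagship_patient(sigma_sheet_03):
    """The synthetic stand-in for the highest-vulnerability mapped patient:
    dense low-voltage substrate, dispersed ERP around 250 ms."""
    spec = SyntheticPatientSpec(
        width=60.0, height=60.0, dx=DX_SHEET, erp_mean=250.0, erp_sd=21.0,
        corr_length=20.0, lva_fraction=60.0, ablation_fraction_of_lva=0.25,
        sigma_l=sigma_sheet_03, seed=11)
    return make_patient(spec)


@pytest.fixture(scope="session")
def small_patient():
    """Tiny patient for interpolation / bookkeeping tests (no simulation)."""
    spec = SyntheticPatientSpec(width=40.0, height=40.0, dx=2.0, seed=5)
    return make_patient(spec)
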