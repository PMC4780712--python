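import numpy as np
import pytest

from cbctscatter import (AnalyticScatterField, CollimatorSetting,
                         ScannerGeometry, add_scatter_and_noise,
                         build_phantom, build_spectrum, project_primary)


@pytest.fixture(scope="session")
def geom_small():
    """4x-downsampled detector, 40 views: the desk-scale test geometry."""
    return ScannerGeometry(det_rows=96, det_cols=120, det_pitch_mm=2.0,
                           n_views=40)


@pytest.fixture(scope="session")
def mono60():
    return build_spectrum(mode="monoenergetic", energy_kev=60.0)


@pytest.fixture(scope="session")
def poly120():
    return build_spectrum(120.0, 10.0)


@pytest.fixture(scope="session")
def water10():
    return build_phantom("water_10cm")


def make_two_fov_fixtures(geom, spectrum, phantom, *, amplitude=0.3, s0=5.0,
                          poisson=False, seed=0, i0=1e4, n_views=None):
    """Analytic two-FOV stacks (slits 14/42 mm) with synthetic scatter."""
    if n_views is not None:
        geom = geom.with_views(n_views)
    from cbctscatter import log_slit_response

    field = AnalyticScatterField(amplitude=amplitude,
                                 slit_response=log_slit_response(s0))
    out = {}
    for slit in (14.0, 42.0):
        coll = CollimatorSetting(slit_mm=slit, geometry=geom)
        prim = project_primary(phantom, geom, coll, spectrum, i0=i0)
        out[slit] = add_scatter_and_noise(prim, field, coll, poisson=poisson,
                                          seed=seed)
    return out[14.0], out[42.0], field
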