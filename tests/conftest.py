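import numpy as np
import pytest

from cinedense import load_builtin_config
from cinedense.phantom import Phantom
from cinedense.phase import DisplacementField
from cinedense.interp import pixel_center_coords
from cinedense.pipeline import analyze_study


@pytest.fixture(scope="session")
def lowfat_config():
    return load_builtin_config("lowfat")


@pytest.fixture(scope="session")
def lowfat_phantom(lowfat_config):
    return Phantom(lowfat_config)


@pytest.fixture(scope="session")
def lowfat_study(lowfat_phantom):
    study, truth = lowfat_phantom.render_study("lf01", "lowfat")
    return study, truth


@pytest.fixture(scope="session")
def lowfat_analysis(lowfat_study):
    return analyze_study(lowfat_study[0])


@pytest.fixture(scope="session")
def highfat_config():
    return load_builtin_config("highfat")


@pytest.fixture(scope="session")
def highfat_phantom(highfat_config):
    return Phantom(highfat_config)


@pytest.fixture(scope="session")
def highfat_study(highfat_phantom):
    study, truth = highfat_phantom.render_study("hf01", "highfat")
    return study, truth


@pytest.fixture(scope="session")
def highfat_analysis(highfat_study):
    return analyze_study(highfat_study[0])


def make_annulus_field(u_of, n_frames=3, n=64, pixel_spacing=0.25,
                       r_in=2.0, r_out=4.0):
    """Synthetic displacement field over an annulus.

    ``u_of(x, f)`` returns the Eulerian displacement (mm) of the tissue at
    current position x (N, 2) for frame f; it must be zero at frame 0.
    The per-frame mask contains the pixels whose reference position
    x - u(x, f) lies inside the annulus.
    """
    cx, cy = pixel_center_coords((n, n), pixel_spacing)
    center = n * pixel_spacing / 2.0
    x = np.column_stack([cx.ravel(), cy.ravel()])
    u_x = np.full((n_frames, n, n), np.nan)
    u_y = np.full((n_frames, n, n), np.nan)
    mask = np.zeros((n_frames, n, n), dtype=bool)
    for f in range(n_frames):
        u = u_of(x, f)
        ref_r = np.hypot(*(x - u - center).T)
        inside = (ref_r >= r_in) & (ref_r <= r_out)
        mask[f] = inside.reshape(n, n)
        u_x[f].ravel()[inside] = u[inside, 0]
        u_y[f].ravel()[inside] = u[inside, 1]
    return DisplacementField(u_x=u_x, u_y=u_y, mask=mask,
                             pixel_spacing=pixel_spacing), center


@pytest.fixture()
def annulus_field_factory():
    return make_annulus_field
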