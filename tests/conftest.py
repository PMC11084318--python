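import numpy as np
import pytest

from contrastsim import phantom as ph
from contrastsim import projector as pr
from contrastsim import radiograph as rg
from contrastsim import spectra as sp


@pytest.fixture(scope="session")
def contrast_pair():
    """(NaDITMB solution, Omnipaque solution) at 23.35 mg I/mL, unit density."""
    return ph.contrast_solutions()


@pytest.fixture(scope="session")
def sim_phantom_a(contrast_pair):
    return ph.build_simulation_phantom(contrast_pair[0])


@pytest.fixture(scope="session")
def sim_phantom_b(contrast_pair):
    return ph.build_simulation_phantom(contrast_pair[1])


@pytest.fixture(scope="session")
def desk_geometry():
    """Reduced-resolution simulation geometry covering the full detector area."""
    return pr.simulation_geometry((250, 250), 1.6)


@pytest.fixture(scope="session")
def spectrum_35():
    return sp.fixture_spectrum("rh_rh_35kvp")


@pytest.fixture(scope="session")
def spectrum_100():
    return sp.fixture_spectrum("w_al_100kvp")


@pytest.fixture(scope="session")
def wellplate():
    return ph.build_wellplate_phantom()


@pytest.fixture(scope="session")
def radiograph_geometry():
    return pr.radiograph_geometry()


@pytest.fixture(scope="session")
def wellplate_paths(wellplate, radiograph_geometry):
    return pr.PathLengthSet(wellplate, radiograph_geometry)


@pytest.fixture(scope="session")
def radiograph_study(wellplate, wellplate_paths):
    """One synthetic radiograph per survey kVp, fixed seed."""
    images = {}
    for kvp in (46.0, 80.0, 95.0, 100.0):
        protocol = rg.AcquisitionProtocol(kvp=kvp, seed=7)
        images[kvp] = rg.simulate_radiograph(wellplate, protocol,
                                             paths=wellplate_paths)
    return images


def march_line_integral(origin, direction, phantom, energy, step_mm=0.001,
                        t_span=(980.0, 1080.0)):
    """Brute-force ray-marching oracle for integral mu dl (independent of the
    analytic chord formulas): sample points along the ray at ``step_mm`` and
    accumulate the local linear attenuation."""
    from contrastsim.materials import solution_mu

    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    ts = np.arange(*t_span, step_mm)
    pts = np.asarray(origin, float)[None, :] + ts[:, None] * direction[None, :]
    mu = np.zeros(len(pts))
    for slab in phantom.slabs:
        ex, ey = slab.lateral_extent
        cx, cy = slab.center_xy
        inside = ((np.abs(pts[:, 0] - cx) <= ex / 2)
                  & (np.abs(pts[:, 1] - cy) <= ey / 2)
                  & (pts[:, 2] >= slab.z0) & (pts[:, 2] <= slab.z1))
        mu[inside] = solution_mu(slab.material, energy)
    for disk in phantom.disks:
        inside = ((np.hypot(pts[:, 0] - disk.center[0],
                            pts[:, 1] - disk.center[1]) <= disk.radius)
                  & (pts[:, 2] >= disk.z0) & (pts[:, 2] <= disk.z1))
        mu[inside] = solution_mu(disk.material, energy)
    return mu.sum() * step_mm / 10.0
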