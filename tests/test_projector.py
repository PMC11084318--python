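import numpy as np
import pytest

from contrastsim import phantom as P
from contrastsim import projector as PR
from contrastsim import spectra as S
from contrastsim.materials import solution_mu

from conftest import march_line_integral


@pytest.fixture(scope="module")
def paths_a(sim_phantom_a, desk_geometry):
    return PR.PathLengthSet(sim_phantom_a, desk_geometry)


class TestLineIntegrals:
    def test_empty_phantom_projects_to_zero(self, desk_geometry):
        empty = P.PhantomSpec((), ())
        image = PR.project_line_integrals(empty, desk_geometry, 20.0)
        assert np.all(image.values == 0.0)

    def test_air_pixels_are_zero(self, sim_phantom_a, desk_geometry, paths_a):
        image = PR.project_line_integrals(sim_phantom_a, desk_geometry, 20.0,
                                          paths=paths_a)
        # detector corners lie outside the magnified slab footprint
        assert image.values[0, 0] == 0.0 and image.values[-1, -1] == 0.0
        assert image.values.max() > 0

    def test_central_disk_pixel_closed_form(self, sim_phantom_a, desk_geometry,
                                            paths_a):
        """The pixel under a disk center reads mu_c*t/10 + mu_p*(45-t)/10 up
        to the tiny cone-beam obliquity."""
        energy = 20.0
        image = PR.project_line_integrals(sim_phantom_a, desk_geometry, energy,
                                          paths=paths_a)
        slab = sim_phantom_a.slabs[0]
        mu_p = solution_mu(slab.material, energy)
        for disk in sim_phantom_a.disks[::5]:
            from contrastsim.roi import _well_roi_center

            row, col = _well_roi_center(disk, desk_geometry)
            value = image.values[int(round(row)), int(round(col))]
            mu_c = solution_mu(disk.material, energy)
            # oblique chord factor 1/cos(theta) for the off-axis disk
            r_lat = np.hypot(disk.center[0], disk.center[1])
            sec = np.sqrt(1.0 + (r_lat / disk.center[2]) ** 2)
            expected = sec * (mu_c * disk.thickness
                              + mu_p * (45.0 - disk.thickness)) / 10
            assert value == pytest.approx(expected, rel=2e-3)

    def test_matches_ray_marching_oracle(self, sim_phantom_a, desk_geometry,
                                         paths_a):
        """Analytic projection equals 1 um ray marching within 0.1% on random
        pixels and several energies."""
        rng = np.random.default_rng(11)
        rows, cols = desk_geometry.detector_shape
        xg, yg = desk_geometry.pixel_centers()
        for energy in (18.0, 35.0, 60.0):
            image = PR.project_line_integrals(sim_phantom_a, desk_geometry,
                                              energy, paths=paths_a)
            checked = 0
            while checked < 7:
                r = rng.integers(0, rows)
                c = rng.integers(0, cols)
                if image.values[r, c] == 0:
                    continue
                direction = np.array([xg[r, c], yg[r, c],
                                      desk_geometry.source_to_detector])
                oracle = march_line_integral((0, 0, 0), direction,
                                             sim_phantom_a, energy)
                assert oracle == pytest.approx(image.values[r, c], rel=1e-3)
                checked += 1

    def test_thicker_disks_attenuate_more(self, sim_phantom_a, desk_geometry,
                                          paths_a):
        """Disk enhancement over the local slab baseline grows strictly with
        disk thickness at every energy (the raw profile additionally carries a
        position-dependent oblique-chord term, so the baseline is removed)."""
        from contrastsim.roi import line_integral_profile

        slab_only = P.PhantomSpec((sim_phantom_a.slabs[0],), ())
        slab_paths = PR.PathLengthSet(slab_only, desk_geometry)
        for energy in (18.0, 35.0, 60.0):
            image = PR.project_line_integrals(sim_phantom_a, desk_geometry,
                                              energy, paths=paths_a)
            baseline = PR.project_line_integrals(slab_only, desk_geometry,
                                                 energy, paths=slab_paths)
            profile = line_integral_profile(image, sim_phantom_a)
            base = line_integral_profile(baseline, sim_phantom_a)
            enhancement = (profile.mean_line_integral.values
                           - base.mean_line_integral.values)
            assert np.all(np.diff(enhancement) > 0)

    def test_magnification_of_mid_depth_disk(self, sim_phantom_a, desk_geometry,
                                             paths_a):
        """A 10 mm disk at mid-slab depth (z = 1022.5 mm) projects with scale
        D2/z ~ 1.27 on the D2 = 1300 mm detector."""
        image = PR.project_line_integrals(sim_phantom_a, desk_geometry, 20.0,
                                          paths=paths_a)
        disk = max(sim_phantom_a.disks, key=lambda d: d.thickness)
        slab = sim_phantom_a.slabs[0]
        mu_p = solution_mu(slab.material, 20.0)
        base = mu_p * slab.thickness / 10
        from contrastsim.roi import _well_roi_center

        row_c, col_c = _well_roi_center(disk, desk_geometry)
        row_line = image.values[int(round(row_c)), :]
        enhanced = np.flatnonzero(row_line > base * 1.02)
        width_mm = (enhanced[-1] - enhanced[0] + 1) * desk_geometry.pixel_pitch
        expected = 2 * disk.radius * 1300.0 / disk.center[2]
        assert width_mm == pytest.approx(expected, rel=0.05)


class TestPolychromatic:
    def test_monoenergetic_reduces_to_beer_law(self, sim_phantom_a,
                                               desk_geometry, paths_a):
        mono = S.Spectrum(np.array([25.0]), np.array([1.0]), kvp=25.0)
        intensity = PR.project_polychromatic(sim_phantom_a, desk_geometry, mono,
                                             paths=paths_a)
        li = PR.project_line_integrals(sim_phantom_a, desk_geometry, 25.0,
                                       paths=paths_a)
        assert np.allclose(intensity.values / intensity.i0,
                           np.exp(-li.values), rtol=1e-12)

    def test_no_phantom_reads_i0(self, desk_geometry, spectrum_35):
        empty = P.PhantomSpec((), ())
        intensity = PR.project_polychromatic(empty, desk_geometry, spectrum_35)
        assert np.allclose(intensity.values, intensity.i0)

    def test_effective_line_integral_inverts_mono(self, sim_phantom_a,
                                                  desk_geometry, paths_a):
        mono = S.Spectrum(np.array([25.0]), np.array([2.0]), kvp=25.0)
        intensity = PR.project_polychromatic(sim_phantom_a, desk_geometry, mono,
                                             paths=paths_a)
        eff = PR.effective_line_integral(intensity)
        li = PR.project_line_integrals(sim_phantom_a, desk_geometry, 25.0,
                                       paths=paths_a)
        assert np.allclose(eff.values, li.values, atol=1e-10)

    def test_beam_hardening_lowers_effective_attenuation(
            self, sim_phantom_a, desk_geometry, paths_a, spectrum_35):
        """The polychromatic effective line integral under an iodinated disk
        falls below the monochromatic value at the spectrum mean energy."""
        from contrastsim.roi import line_integral_profile

        poly = PR.effective_line_integral(PR.project_polychromatic(
            sim_phantom_a, desk_geometry, spectrum_35, paths=paths_a))
        mono = PR.project_line_integrals(
            sim_phantom_a, desk_geometry, spectrum_35.mean_energy(), paths=paths_a)
        p_poly = line_integral_profile(poly, sim_phantom_a)
        p_mono = line_integral_profile(mono, sim_phantom_a)
        thick = p_poly.thickness_mm > 2.0
        assert np.all(p_poly.mean_line_integral[thick].values
                      <= p_mono.mean_line_integral[thick].values)

    def test_contrast_decreases_with_kvp(self, sim_phantom_a, desk_geometry,
                                         paths_a, spectrum_35, spectrum_100):
        i35 = PR.project_polychromatic(sim_phantom_a, desk_geometry,
                                       spectrum_35, paths=paths_a)
        i100 = PR.project_polychromatic(sim_phantom_a, desk_geometry,
                                        spectrum_100, paths=paths_a)
        from contrastsim.roi import _well_roi_center, disk_roi, measure_roi

        bg_mask = paths_a.slab_mask & ~paths_a.disk_mask
        for disk in sim_phantom_a.disks:
            roi = disk_roi(disk.label, _well_roi_center(disk, desk_geometry), 24)
            c = []
            for image in (i35, i100):
                m = measure_roi(image.values, roi)
                c.append(1.0 - m.mean / image.values[bg_mask].mean())
            assert c[1] < c[0]

    def test_weighting_mode_changes_image(self, sim_phantom_a, desk_geometry,
                                          paths_a, spectrum_35):
        fl = PR.project_polychromatic(sim_phantom_a, desk_geometry, spectrum_35,
                                      weighting="fluence", paths=paths_a)
        en = PR.project_polychromatic(sim_phantom_a, desk_geometry, spectrum_35,
                                      weighting="energy", paths=paths_a)
        assert not np.allclose(fl.values / fl.i0, en.values / en.i0)
        with pytest.raises(ValueError):
            PR.project_polychromatic(sim_phantom_a, desk_geometry, spectrum_35,
                                     weighting="bogus")


class TestImageIO:
    def test_line_integral_tiff_round_trip(self, sim_phantom_a, desk_geometry,
                                           paths_a, tmp_path):
        image = PR.project_line_integrals(sim_phantom_a, desk_geometry, 20.0,
                                          paths=paths_a)
        out = tmp_path / "li.tif"
        PR.write_line_integral_tiff(image, out)
        back = PR.read_image(out)
        assert np.allclose(back, image.values, rtol=1e-6)

    def test_intensity_tiff_scale(self, sim_phantom_a, desk_geometry, paths_a,
                                  spectrum_35, tmp_path):
        intensity = PR.project_polychromatic(sim_phantom_a, desk_geometry,
                                             spectrum_35, paths=paths_a)
        out = tmp_path / "int.tif"
        PR.write_intensity_tiff(intensity, out)
        back = PR.read_image(out)
        assert back.max() == 65535
        assert back.dtype == float
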