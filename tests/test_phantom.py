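import numpy as np
import pytest

from contrastsim import phantom as P
from contrastsim.materials import solution_mu

from conftest import march_line_integral


class TestSimulationPhantom:
    def test_default_layout(self, sim_phantom_a):
        disks = sim_phantom_a.disks
        assert len(disks) == 14
        thicknesses = sorted(d.thickness for d in disks)
        assert thicknesses[0] == pytest.approx(0.2)
        assert thicknesses[-1] == pytest.approx(2.6)

    def test_linear_thickness_spacing(self, sim_phantom_a):
        thicknesses = np.sort([d.thickness for d in sim_phantom_a.disks])
        steps = np.diff(thicknesses)
        assert np.allclose(steps, 2.4 / 13)

    def test_single_disk_at_slab_center(self, contrast_pair):
        ph = P.build_simulation_phantom(contrast_pair[0], disk_count=1, columns=1)
        (disk,) = ph.disks
        assert disk.center[:2] == (0.0, 0.0)
        slab = ph.slabs[0]
        assert disk.center[2] == pytest.approx(slab.z0 + slab.thickness / 2)

    def test_disks_centered_in_depth(self, sim_phantom_a):
        slab = sim_phantom_a.slabs[0]
        for d in sim_phantom_a.disks:
            assert d.z0 >= slab.z0 and d.z1 <= slab.z1
            assert d.center[2] == pytest.approx(slab.z0 + slab.thickness / 2)

    def test_unfittable_layout_rejected(self, contrast_pair):
        with pytest.raises(P.LayoutError):
            P.build_simulation_phantom(contrast_pair[0], disk_radius=40.0)

    def test_overlapping_disks_rejected(self, contrast_pair):
        sol = contrast_pair[0]
        slab = P.SlabPrimitive(45.0, (200.0, 200.0), 1000.0, P.pmma_solid())
        mk = lambda x: P.DiskPrimitive((x, 0, 1022.5), 10.0, 1.0, sol, label=f"d{x}")
        with pytest.raises(P.LayoutError):
            P.PhantomSpec((slab,), (mk(0.0), mk(15.0)))


class TestWellPlate:
    def test_column_height_from_volume(self, wellplate):
        r = 3.2
        h_expected = 100.0 / (np.pi * r * r)  # 0.1 mL in mm^3
        a4 = next(d for d in wellplate.disks if d.label == "A4")
        assert a4.thickness == pytest.approx(h_expected, rel=1e-12)
        assert a4.thickness == pytest.approx(3.11, abs=0.01)

    def test_volume_linearity(self, wellplate):
        a1 = next(d for d in wellplate.disks if d.label == "A1")  # 0.2 mL
        a4 = next(d for d in wellplate.disks if d.label == "A4")  # 0.1 mL
        assert a1.thickness == pytest.approx(2 * a4.thickness)

    def test_row_materials(self, wellplate):
        a = next(d for d in wellplate.disks if d.label == "A1")
        b = next(d for d in wellplate.disks if d.label == "B1")
        assert a.material.label == "NaDITMB"
        assert b.material.label == "Omnipaque"

    def test_row_count(self, wellplate):
        assert len(wellplate.disks) == 16
        assert sum(d.label.startswith("A") for d in wellplate.disks) == 8

    def test_overfilled_well_rejected(self):
        with pytest.raises(P.LayoutError):
            P.build_wellplate_phantom(volumes_ml=[0.5])


class TestPathLength:
    def test_axial_ray_through_disk_center(self, sim_phantom_a):
        d = sim_phantom_a.disks[0]
        # ray along +z directly above the disk axis (parallel beam limit)
        length = P.path_length((d.center[0], d.center[1], 0.0), (0, 0, 1), d)
        assert length == pytest.approx(d.thickness, rel=1e-12)

    def test_miss_returns_zero(self, sim_phantom_a):
        d = sim_phantom_a.disks[0]
        length = P.path_length((d.center[0] + d.radius + 0.1, d.center[1], 0.0),
                               (0, 0, 1), d)
        assert length == 0.0

    def test_oblique_slab_chord(self, sim_phantom_a):
        slab = sim_phantom_a.slabs[0]
        theta = np.deg2rad(4.0)  # stays inside the lateral extent at depth
        direction = (np.sin(theta), 0.0, np.cos(theta))
        length = P.path_length((0.0, 0.0, 0.0), direction, slab)
        assert length == pytest.approx(slab.thickness / np.cos(theta), rel=1e-12)

    @pytest.mark.parametrize("kind", ["slab", "disk"])
    def test_chords_match_ray_marching(self, sim_phantom_a, kind):
        """Closed-form chords agree with a 1 um ray-marching oracle."""
        rng = np.random.default_rng(2024)
        slab = sim_phantom_a.slabs[0]
        prim = slab if kind == "slab" else sim_phantom_a.disks[-1]
        step = 0.001
        for _ in range(100):
            x, y = rng.uniform(-40, 40, 2)
            direction = np.array([x, y, 1150.0])
            direction /= np.linalg.norm(direction)
            analytic = P.path_length((0, 0, 0), direction, prim)
            ts = np.arange(990.0, 1060.0, step)
            pts = ts[:, None] * direction[None, :]
            if kind == "slab":
                inside = ((np.abs(pts[:, 0]) <= slab.lateral_extent[0] / 2)
                          & (np.abs(pts[:, 1]) <= slab.lateral_extent[1] / 2)
                          & (pts[:, 2] >= slab.z0) & (pts[:, 2] <= slab.z1))
            else:
                inside = ((np.hypot(pts[:, 0] - prim.center[0],
                                    pts[:, 1] - prim.center[1]) <= prim.radius)
                          & (pts[:, 2] >= prim.z0) & (pts[:, 2] <= prim.z1))
            marched = inside.sum() * step
            assert marched == pytest.approx(analytic, abs=2 * step + 0.001 * analytic)

    def test_disk_paths_bounded_by_slab_path(self, sim_phantom_a):
        rng = np.random.default_rng(5)
        slab = sim_phantom_a.slabs[0]
        for _ in range(50):
            x, y = rng.uniform(-90, 90, 2)
            direction = np.array([x, y, 1300.0])
            total_disks = sum(P.path_length((0, 0, 0), direction, d)
                              for d in sim_phantom_a.disks)
            assert total_disks <= P.path_length((0, 0, 0), direction, slab) + 1e-9

    def test_material_substitution_conserves_geometry(self, sim_phantom_a,
                                                      desk_geometry):
        """Along any ray the summed attenuating length equals the slab chord:
        disks replace slab material without changing total path."""
        from contrastsim.projector import PathLengthSet

        paths = PathLengthSet(sim_phantom_a, desk_geometry)
        total = np.zeros(desk_geometry.detector_shape)
        for _, length in paths.material_terms:
            total += length
        slab_only = PathLengthSet(
            P.PhantomSpec((sim_phantom_a.slabs[0],), ()), desk_geometry)
        assert np.allclose(total, slab_only.material_terms[0][1], atol=1e-9)


def test_march_oracle_agrees_with_phantom_line_integral(sim_phantom_a):
    """Full-phantom sanity: the independent marching oracle reproduces the
    material-substitution bookkeeping for a ray through a disk."""
    d = sim_phantom_a.disks[3]
    direction = np.array([d.center[0], d.center[1], d.center[2]])
    direction = direction / np.linalg.norm(direction)
    energy = 20.0
    slab = sim_phantom_a.slabs[0]
    mu_s = solution_mu(slab.material, energy)
    mu_c = solution_mu(d.material, energy)
    l_slab = P.path_length((0, 0, 0), direction, slab)
    l_disk = P.path_length((0, 0, 0), direction, d)
    analytic = (mu_s * (l_slab - l_disk) + mu_c * l_disk) / 10.0
    marched = march_line_integral((0, 0, 0), direction, sim_phantom_a, energy)
    assert marched == pytest.approx(analytic, rel=1e-3)
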