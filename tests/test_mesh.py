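"""Grid construction, electrode rasterization and boundary classification."""

import numpy as np
import pytest

import epsim
from epsim.mesh import ANODE, BOUNDARY_FACES, CATHODE, TISSUE


class TestBuildGrid:
    @pytest.mark.parametrize("extent_mm,h_mm,shape", [
        ((1, 1, 1), 0.5, (3, 3, 3)),
        ((10, 10, 5), 0.25, (41, 41, 21)),
        ((20, 10, 10), 0.5, (41, 21, 21)),
    ])
    def test_node_counts(self, extent_mm, h_mm, shape):
        g = epsim.build_grid(tuple(e * 1e-3 for e in extent_mm), h_mm * 1e-3)
        assert g.shape == shape
        assert np.allclose(g.extent, [e * 1e-3 for e in extent_mm])

    def test_non_divisible_extent_names_axis(self):
        with pytest.raises(epsim.ConfigurationError, match="axis y"):
            epsim.build_grid((0.9e-3, 1e-3, 0.9e-3), 0.3e-3)

    @pytest.mark.parametrize("spacing", [0.0, -1e-3])
    def test_bad_spacing(self, spacing):
        with pytest.raises(epsim.ConfigurationError):
            epsim.build_grid((1e-3, 1e-3, 1e-3), spacing)

    def test_too_few_nodes(self):
        with pytest.raises(epsim.ConfigurationError, match="at least 3"):
            epsim.build_grid((1e-3, 1e-3, 1e-3), 1e-3)


def brute_force_labels(grid, electrodes):
    """Nodewise loop oracle for rasterization."""
    material = np.full(grid.shape, TISSUE, dtype=int)
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            for k in range(grid.shape[2]):
                p = np.array([i, j, k]) * grid.spacing
                for el in electrodes:
                    if bool(el.contains(*p)):
                        material[i, j, k] = el.label
    return material


class TestRasterize:
    def test_plate_node_count(self):
        # 1 mm^3 plate in a larger box, h = 0.5 mm -> 3^3 = 27 nodes
        g = epsim.build_grid((4e-3, 4e-3, 4e-3), 0.5e-3)
        el = epsim.ElectrodeGeometry(kind="plate", center=(2e-3, 2e-3, 2e-3),
                                     dims=(1e-3, 1e-3, 1e-3),
                                     polarity="anode")
        labels = epsim.rasterize_electrodes(g, [el])
        assert int(labels.anode_mask.sum()) == 27

    def test_empty_list_all_tissue(self, small_grid):
        labels = epsim.rasterize_electrodes(small_grid, [])
        assert labels.tissue_mask.all()

    def test_thin_needle_claims_single_column(self):
        g = epsim.build_grid((4e-3, 4e-3, 4e-3), 0.5e-3)
        el = epsim.ElectrodeGeometry(kind="needle", center=(2e-3, 2e-3, 2e-3),
                                     radius=0.4 * 0.5e-3, length=2e-3,
                                     polarity="cathode")
        labels = epsim.rasterize_electrodes(g, [el])
        want = brute_force_labels(g, [el])
        np.testing.assert_array_equal(labels.material, want)
        # the column: z in [1, 3] mm at (x, y) = (2, 2) mm -> 5 nodes
        assert int(labels.cathode_mask.sum()) == 5
        assert labels.cathode_mask[4, 4, 2:7].all()

    @pytest.mark.parametrize("tilt", [(0, 0, 1), (1, 0, 1), (1, 2, 2)])
    def test_oracle_equality_needles(self, tilt):
        g = epsim.build_grid((5e-3, 5e-3, 5e-3), 0.5e-3)
        els = [
            epsim.ElectrodeGeometry(kind="needle",
                                    center=(1.5e-3, 2.5e-3, 2.5e-3),
                                    radius=0.6e-3, length=3e-3, axis=tilt,
                                    polarity="anode"),
            epsim.ElectrodeGeometry(kind="plate",
                                    center=(4e-3, 2.5e-3, 2.5e-3),
                                    dims=(0.7e-3, 2e-3, 3e-3),
                                    polarity="cathode"),
        ]
        labels = epsim.rasterize_electrodes(g, els)
        np.testing.assert_array_equal(labels.material,
                                      brute_force_labels(g, els))

    def test_polarity_swap_permutes_labels(self, small_grid):
        from dataclasses import replace
        els = [
            epsim.ElectrodeGeometry(kind="plate", center=(1e-3, 2.5e-3, 2.5e-3),
                                    dims=(1e-3, 1e-3, 1e-3), polarity="anode"),
            epsim.ElectrodeGeometry(kind="plate", center=(4e-3, 2.5e-3, 2.5e-3),
                                    dims=(1e-3, 1e-3, 1e-3),
                                    polarity="cathode"),
        ]
        a = epsim.rasterize_electrodes(small_grid, els)
        swapped = [replace(els[0], polarity="cathode"),
                   replace(els[1], polarity="anode")]
        b = epsim.rasterize_electrodes(small_grid, swapped)
        np.testing.assert_array_equal(a.anode_mask, b.cathode_mask)
        np.testing.assert_array_equal(a.cathode_mask, b.anode_mask)
        np.testing.assert_array_equal(a.tissue_mask, b.tissue_mask)

    def test_refinement_changes_volume_by_at_most_surface_layer(self):
        el = epsim.ElectrodeGeometry(kind="needle", center=(5e-3, 5e-3, 5e-3),
                                     radius=1.2e-3, length=6e-3,
                                     polarity="anode")
        vols = {}
        for h in (0.5e-3, 0.25e-3):
            g = epsim.build_grid((10e-3, 10e-3, 10e-3), h)
            labels = epsim.rasterize_electrodes(g, [el])
            vols[h] = int(labels.anode_mask.sum()) * g.node_volume
        surface = 2 * np.pi * 1.2e-3 * 6e-3 + 2 * np.pi * 1.2e-3 ** 2
        assert abs(vols[0.5e-3] - vols[0.25e-3]) <= surface * 0.5e-3

    def test_overlap_error(self, small_grid):
        els = [
            epsim.ElectrodeGeometry(kind="plate", center=(2.5e-3,) * 3,
                                    dims=(2e-3,) * 3, polarity="anode"),
            epsim.ElectrodeGeometry(kind="plate", center=(3e-3,) * 3,
                                    dims=(2e-3,) * 3, polarity="cathode"),
        ]
        with pytest.raises(epsim.GeometryError, match="overlap"):
            epsim.rasterize_electrodes(small_grid, els)

    def test_outside_domain_error(self, small_grid):
        el = epsim.ElectrodeGeometry(kind="plate", center=(20e-3,) * 3,
                                     dims=(1e-3,) * 3, polarity="anode")
        with pytest.raises(epsim.GeometryError, match="outside"):
            epsim.rasterize_electrodes(small_grid, [el])


class TestClassifyBoundaries:
    def test_interior_electrodes_all_tissue_air(self):
        # electrodes not touching the boundary: every face is tissue-air
        g = epsim.build_grid((6e-3, 6e-3, 6e-3), 0.5e-3)
        els2 = [epsim.ElectrodeGeometry(kind="needle",
                                        center=(2e-3, 3e-3, 3e-3),
                                        radius=0.3e-3, length=2e-3,
                                        polarity="anode",
                                        exposed_fraction=1.0),
                epsim.ElectrodeGeometry(kind="needle",
                                        center=(4e-3, 3e-3, 3e-3),
                                        radius=0.3e-3, length=2e-3,
                                        polarity="cathode",
                                        exposed_fraction=1.0)]
        l2 = epsim.classify_boundaries(
            g, epsim.rasterize_electrodes(g, els2), els2)
        assert l2.face_counts()["electrode_air"] == 0

    def test_flush_plate_exposed_faces_tagged(self):
        g = epsim.build_grid((4e-3, 4e-3, 4e-3), 0.5e-3)
        # plate flush with the z+ face
        el = [epsim.ElectrodeGeometry(kind="plate", center=(2e-3, 2e-3, 4e-3),
                                      dims=(2e-3, 2e-3, 0.0),
                                      polarity="anode", exposed_fraction=1.0),
              epsim.ElectrodeGeometry(kind="plate", center=(2e-3, 2e-3, 0.0),
                                      dims=(2e-3, 2e-3, 0.0),
                                      polarity="cathode",
                                      exposed_fraction=0.0)]
        labels = epsim.classify_boundaries(
            g, epsim.rasterize_electrodes(g, el), el)
        top = labels.electrode_air["z+"]
        assert int(top.sum()) == 25          # 5x5 plate nodes on the face
        assert not labels.electrode_air["z-"].any()   # exposed_fraction 0

    def test_exposed_fraction_zero_no_convective_faces(self):
        g = epsim.build_grid((4e-3, 4e-3, 4e-3), 0.5e-3)
        els = [epsim.ElectrodeGeometry(kind="plate", center=(2e-3, 2e-3, 4e-3),
                                       dims=(2e-3, 2e-3, 0.0),
                                       polarity="anode", exposed_fraction=0.0),
               epsim.ElectrodeGeometry(kind="plate", center=(2e-3, 2e-3, 0.0),
                                       dims=(2e-3, 2e-3, 0.0),
                                       polarity="cathode",
                                       exposed_fraction=0.0)]
        labels = epsim.classify_boundaries(
            g, epsim.rasterize_electrodes(g, els), els)
        assert labels.face_counts()["electrode_air"] == 0
        total = sum(labels.electrode_air[f].size for f in BOUNDARY_FACES)
        assert labels.face_counts()["tissue_air"] == total
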