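"""Synthetic multi-cell domain generator: variants, determinism, feasibility."""

import numpy as np
import pytest
import shapely

import cytoconvect as cc
from cytoconvect.domains import EPITHELIAL_VARIANTS, generate_epithelial_sheet
from cytoconvect.errors import InvalidInputError

T_BODY = 310.15


def _geometry_signature(scenario):
    return [
        (c.polygon, c.nucleus_center, c.nucleus_radii, c.nucleus_angle)
        for c in scenario.cells
    ]


def _thermal_signature(scenario):
    return [(c.nucleus_temp_C, c.patches) for c in scenario.cells]


class TestEpithelialVariants:
    def test_eight_variants_and_unknown_rejected(self):
        assert len(EPITHELIAL_VARIANTS) == 8
        with pytest.raises(InvalidInputError):
            generate_epithelial_sheet("Z", seed=0)

    def test_seed_determinism_byte_identical(self):
        for v in ("A", "E"):  # E is the only seeded variant
            a = generate_epithelial_sheet(v, seed=11).to_yaml()
            b = generate_epithelial_sheet(v, seed=11).to_yaml()
            assert a == b

    def test_variant_B_differs_only_in_nuclear_heating(self):
        a = generate_epithelial_sheet("A", seed=0)
        b = generate_epithelial_sheet("B", seed=0)
        assert _geometry_signature(a) == _geometry_signature(b)
        assert all(cb.nucleus_temp_C > ca.nucleus_temp_C
                   for ca, cb in zip(a.cells, b.cells))

    def test_variant_H_differs_only_in_heating_distribution(self):
        a = generate_epithelial_sheet("A", seed=0)
        h = generate_epithelial_sheet("H", seed=0)
        assert _geometry_signature(a) == _geometry_signature(h)
        assert all(len(c.patches) == 1 for c in h.cells)   # one-sided heating
        assert all(c.nucleus_temp_C == 37.0 for c in h.cells)

    @pytest.mark.parametrize("variant", ["C", "D", "E", "G"])
    def test_stratification_variants_move_only_nuclei(self, variant):
        a = generate_epithelial_sheet("A", seed=5)
        v = generate_epithelial_sheet(variant, seed=5)
        assert [c.polygon for c in a.cells] == [c.polygon for c in v.cells]
        assert [c.nucleus_radii for c in a.cells] == [c.nucleus_radii for c in v.cells]
        assert _thermal_signature(a) == _thermal_signature(v)
        assert [c.nucleus_center for c in a.cells] != [c.nucleus_center for c in v.cells]

    def test_variant_F_changes_shape_preserving_area(self):
        a = generate_epithelial_sheet("A", seed=0)
        f = generate_epithelial_sheet("F", seed=0)
        ra = a.cells[0].nucleus_radii
        rf = f.cells[0].nucleus_radii
        assert len(rf) == 2 and rf[0] != rf[1]
        assert np.prod(rf) == pytest.approx(ra[0] ** 2, rel=1e-9)

    def test_sheet_meshes_and_solves(self, props):
        """Baseline sheet passes mesh validation and converges at defaults."""
        scenario = generate_epithelial_sheet("A", seed=0)
        mesh = scenario.build_mesh(target_edge_length=1.4)
        mesh.validate()
        sol = cc.solve_flow(mesh, props, scenario.thermal_bc())
        assert sol.max_speed_um_s > 0
        assert max(sol.residuals.values()) <= 1e-6


class TestMulticell:
    def test_six_independent_regions(self):
        scenario = cc.generate_multicell_domain(6, seed=1)
        mesh = scenario.build_mesh(target_edge_length=2.0)
        mesh.validate()
        assert len(np.unique(mesh.element_region)) == 6

    def test_patch_fraction_one_equals_fully_heated_nucleus(self, props):
        """mito_patch_fraction = 1 is equivalent to a fully heated nucleus
        wall: every nuclear facet carries the patch tag, and the solve
        matches the same domain with a uniformly heated nucleus."""
        full = cc.generate_multicell_domain(2, seed=3, mito_patch_fraction=1.0)
        mesh = full.build_mesh(target_edge_length=2.5)
        for k in range(2):
            assert len(mesh.facets_with_tag(f"mito{k}")) > 0
            assert len(mesh.facets_with_tag(f"w2:{k}")) == 0
        sol_patch = cc.solve_flow(mesh, props, full.thermal_bc())

        import copy

        uniform = copy.deepcopy(full)
        for c in uniform.cells:
            c.patches = ()
            c.nucleus_temp_C = 38.0
        mesh_u = uniform.build_mesh(target_edge_length=2.5)
        sol_uniform = cc.solve_flow(mesh_u, props, uniform.thermal_bc())
        assert sol_patch.max_speed_um_s == pytest.approx(
            sol_uniform.max_speed_um_s, rel=1e-9
        )

    def test_partial_patch_drives_flow(self, props):
        sc = cc.generate_multicell_domain(1, seed=2, mito_patch_fraction=0.3)
        mesh = sc.build_mesh(target_edge_length=2.0)
        sol = cc.solve_flow(mesh, props, sc.thermal_bc())
        assert sol.max_speed_um_s > 0
        assert max(sol.residuals.values()) <= 1e-6

    def test_seed_variation_preserves_summary_statistics(self):
        """Different seeds give different polygons but similar mean cell area."""
        means = []
        polys = []
        for seed in range(6):
            sc = cc.generate_multicell_domain(6, seed=seed)
            areas = [shapely.Polygon(c.polygon).area for c in sc.cells]
            means.append(np.mean(areas))
            polys.append(sc.cells[0].polygon)
        assert polys[0] != polys[1]
        target = (45.0 * np.sqrt(6)) ** 2 / 6  # box area / n_cells
        for m in means:
            assert 0.6 * target < m < 1.1 * target

    def test_nuclei_interior_and_8pct_area(self):
        sc = cc.generate_multicell_domain(6, seed=0)
        for c in sc.cells:
            poly = shapely.Polygon(c.polygon)
            nucleus = shapely.Point(c.nucleus_center).buffer(c.nucleus_radii[0])
            assert poly.contains(nucleus)
            assert nucleus.area / poly.area < 0.1

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidInputError):
            cc.generate_multicell_domain(0, seed=0)
        with pytest.raises(InvalidInputError):
            cc.generate_multicell_domain(4, seed=0, mito_patch_fraction=0.0)


class TestSerialization:
    def test_yaml_roundtrip_identity(self, tmp_path):
        sc = cc.generate_multicell_domain(4, seed=9, mito_patch_fraction=0.4)
        path = tmp_path / "scenario.yaml"
        sc.to_yaml(path)
        restored = cc.DomainScenario.from_yaml(path)
        assert restored.to_yaml() == sc.to_yaml()
        assert restored.seed == 9
        assert restored.gravity_direction == (0.0, -1.0)  # in-plane gravity recorded
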