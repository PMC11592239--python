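"""FE solver: loads, spring bed, RBE3 distribution, closed-form oracles,
linearity and equilibrium."""

import numpy as np
import pytest

from spinefea.fem import (
    GRAVITY,
    LoadCase,
    SpringBed,
    VertebralFEModel,
    build_spring_bed,
    contact_stiffness_shares,
    default_load_fractions,
    failure_check,
    level_load,
    rbe3_distribute,
    solve_vertebra,
    stress_summaries,
)
from spinefea.materials import MaterialCard, build_material_card
from spinefea.meshing import (
    FEMesh,
    extract_boundary_triangles,
    structured_solid,
    tag_contact_surfaces,
    tet_volumes,
    _split_prisms,
)
from spinefea.specimens import default_donor_spine


def _fixture_card(e_spong=300.0, s_max=2.82):
    return MaterialCard("cyl", 0.0, 8000.0, e_spong, s_max, "pragmatic", "t")


def _cylinder_model(force=400.0, e_spong=300.0, nu=0.3, edge=2.5):
    mesh = structured_solid(20.0, 20.0, 25.0, 1.0, edge)
    tag_contact_surfaces(mesh)
    springs = build_spring_bed(mesh)
    sup = mesh.node_sets["superior_contact"]
    areas = mesh.tributary_areas["superior_contact"]
    centroid = (mesh.nodes[sup] * areas[:, None]).sum(0) / areas.sum()
    load = LoadCase(master_point=centroid, axis=np.array([0.0, 0.0, 1.0]), force_f=force)
    return VertebralFEModel(mesh, 200.0, _fixture_card(e_spong), springs, load, nu=nu)


class TestLevelLoad:
    def test_force_is_fraction_of_body_weight(self):
        spine = default_donor_spine()
        table = {lab: 0.5 for lab in [v.label for v in spine.vertebrae]}
        f = level_load(spine, "Th8", table)
        assert f == pytest.approx(0.5 * 104.5 * GRAVITY)
        assert f == pytest.approx(512.6, abs=0.1)

    def test_zero_fraction_gives_zero_force(self):
        spine = default_donor_spine()
        table = {lab: 0.0 for lab in [v.label for v in spine.vertebrae]}
        assert level_load(spine, "C3", table) == 0.0

    def test_default_table_monotone_craniocaudally(self):
        spine = default_donor_spine()
        assert (
            level_load(spine, "L5")
            > level_load(spine, "Th8")
            > level_load(spine, "C3")
        )
        fr = default_load_fractions()
        assert fr["C3"] == pytest.approx(0.08)
        assert fr["L5"] == pytest.approx(0.60)

    def test_non_monotone_table_rejected(self):
        spine = default_donor_spine()
        table = default_load_fractions()
        table["L1"] = 0.01
        with pytest.raises(ValueError, match="nondecreasing"):
            level_load(spine, "Th8", table)


class TestSpringBed:
    def test_total_stiffness_matches_cap_area_closed_form(self):
        mesh = structured_solid(20.0, 20.0, 25.0, 1.0, 2.0)
        tag_contact_surfaces(mesh)
        bed = build_spring_bed(mesh, e_iv=9.8, t_iv=5.0)
        assert bed.total_stiffness == pytest.approx(9.8 * np.pi * 400 / 5.0, rel=0.01)
        # exact against the meshed cap area
        a = mesh.tributary_areas["inferior_contact"].sum()
        assert bed.total_stiffness == pytest.approx(9.8 * a / 5.0, rel=1e-12)

    def test_doubling_disc_thickness_halves_stiffness(self):
        mesh = structured_solid(10.0, 10.0, 20.0, 1.0, 2.0)
        tag_contact_surfaces(mesh)
        k1 = build_spring_bed(mesh, t_iv=5.0).stiffness
        k2 = build_spring_bed(mesh, t_iv=10.0).stiffness
        np.testing.assert_allclose(k2, k1 / 2.0)

    def test_apportioning_preserves_total(self):
        mesh = structured_solid(10.0, 10.0, 20.0, 1.0, 2.0)
        tag_contact_surfaces(mesh)
        shares = contact_stiffness_shares(mesh, "inferior_contact", 300.0, 8000.0, 200.0)
        bed_a = build_spring_bed(mesh)
        bed_s = build_spring_bed(mesh, apportion=shares)
        assert bed_s.total_stiffness == pytest.approx(bed_a.total_stiffness)
        assert not np.allclose(bed_s.stiffness, bed_a.stiffness)

    def test_rigid_body_on_springs_recovers_series_deflection(self):
        """Near-rigid bone: platform displacement = F / sum(k_i)."""
        model = _cylinder_model(force=400.0, e_spong=3e6)
        model.material = MaterialCard("rigid", 0.0, 8e6, 3e6, 1.0, "pragmatic", "t")
        res = model.fit()
        expected = 400.0 / model.springs.total_stiffness
        assert res.deflection() == pytest.approx(expected, rel=0.01)


class TestRbe3:
    def _prism_mesh(self):
        # equilateral triangular prism, top face = 3 symmetric nodes
        a = 10.0
        tri = np.array(
            [[a, 0.0], [-a / 2, a * np.sqrt(3) / 2], [-a / 2, -a * np.sqrt(3) / 2]]
        )
        nodes = np.vstack(
            [np.column_stack([tri, np.zeros(3)]), np.column_stack([tri, np.ones(3) * 5])]
        )
        tets = _split_prisms(np.array([[0, 1, 2, 3, 4, 5]]))
        vols = tet_volumes(nodes, tets)
        tets[vols < 0] = tets[vols < 0][:, [0, 1, 3, 2]]
        shell = extract_boundary_triangles(nodes, tets)
        mesh = FEMesh(nodes=nodes, tetrahedra=tets, shell_triangles=shell)
        tag_contact_surfaces(mesh)
        return mesh

    def test_three_symmetric_nodes_share_force_equally(self):
        mesh = self._prism_mesh()
        load = LoadCase(
            master_point=np.array([0.0, 0.0, 5.0]),
            axis=np.array([0.0, 0.0, 1.0]),
            force_f=9.0,
        )
        f = rbe3_distribute(mesh, load).reshape(-1, 3)
        top = mesh.node_sets["superior_contact"]
        np.testing.assert_allclose(f[top, 2], -3.0, rtol=1e-9)

    def test_force_sum_exact_and_moment_balanced(self):
        mesh = structured_solid(12.0, 9.0, 18.0, 0.85, 2.0)
        tag_contact_surfaces(mesh)
        sup = mesh.node_sets["superior_contact"]
        areas = mesh.tributary_areas["superior_contact"]
        master = (mesh.nodes[sup] * areas[:, None]).sum(0) / areas.sum()
        master += np.array([0.7, -0.4, 0.0])  # deliberately off-centroid
        load = LoadCase(master_point=master, axis=np.array([0.0, 0.0, 1.0]), force_f=400.0)
        f = rbe3_distribute(mesh, load).reshape(-1, 3)
        total = f.sum(axis=0)
        np.testing.assert_allclose(total, [0.0, 0.0, -400.0], atol=1e-10 * 400)
        d = mesh.nodes - master
        moment = np.cross(d, f).sum(axis=0)
        diameter = np.ptp(mesh.nodes, axis=0).max()
        assert np.linalg.norm(moment[:2]) < 1e-6 * 400.0 * diameter

    def test_weights_are_nonnegative_area_shares_by_default(self):
        mesh = self._prism_mesh()
        load = LoadCase(
            master_point=np.array([0.0, 0.0, 5.0]),
            axis=np.array([0.0, 0.0, 1.0]),
            force_f=1.0,
        )
        rbe3_distribute(mesh, load)
        assert load.weights.sum() == pytest.approx(1.0)
        assert np.all(load.weights >= 0)


class TestSolve:
    def test_zero_force_zero_response(self):
        model = _cylinder_model(force=0.0, edge=3.0)
        res = model.fit()
        assert np.allclose(res.displacements, 0.0)
        assert np.allclose(res.shell_von_mises, 0.0)
        assert np.allclose(res.tet_von_mises, 0.0)

    def test_linearity_in_applied_force(self):
        m1 = _cylinder_model(force=400.0, edge=3.0)
        r1 = m1.fit()
        m1.load.force_f = 800.0
        r2 = m1.fit()
        np.testing.assert_allclose(r2.displacements, 2 * r1.displacements, rtol=1e-9)
        np.testing.assert_allclose(r2.tet_von_mises, 2 * r1.tet_von_mises, rtol=1e-9)
        np.testing.assert_allclose(r2.shell_von_mises, 2 * r1.shell_von_mises, rtol=1e-9)

    def test_spring_reactions_balance_applied_load(self):
        res = _cylinder_model(edge=3.0).fit()
        total = res.reaction_sum()
        assert abs(total[2] - 400.0) / 400.0 < 1e-8
        assert abs(total[0]) < 1e-8 * 400 and abs(total[1]) < 1e-8 * 400

    def test_composite_oracle_within_five_percent(self, oracle_check):
        c = oracle_check
        assert c.max_rel_error() < 0.05
        assert c.reaction_residual < 1e-8

    def test_oracle_error_decreases_under_refinement(self):
        from spinefea.validation import composite_cylinder_oracle

        coarse = composite_cylinder_oracle(edge_target=5.0, mesh_true_reference=False)
        fine = composite_cylinder_oracle(edge_target=2.5, mesh_true_reference=False)
        assert fine.max_rel_error() <= coarse.max_rel_error() + 1e-12
        # convergence of the displacement solution itself
        assert fine.deflection_fe == pytest.approx(coarse.deflection_fe, rel=0.02)

    def test_unconstrained_model_reports_singularity(self):
        model = _cylinder_model(edge=3.5)
        model.springs = SpringBed(
            node_ids=model.springs.node_ids,
            stiffness=np.zeros_like(model.springs.stiffness),
        )
        with pytest.raises(RuntimeError, match="spring bed"):
            model.fit()


class TestSummariesAndFailure:
    def test_summaries_equal_brute_force_percentiles(self):
        res = _cylinder_model(edge=3.0).fit()
        s = stress_summaries(res, percentile=95.0)
        assert s["cortical_stress"] == pytest.approx(
            float(np.percentile(res.shell_von_mises, 95.0))
        )
        assert s["cancellous_stress"] == pytest.approx(
            float(np.percentile(res.tet_von_mises, 95.0))
        )
        axial = res.displacements @ res.model.load.axis
        assert s["deflection"] == pytest.approx(float(np.abs(axial).max()))

    def test_smooth_field_insensitive_to_percentile_choice(self):
        res = _cylinder_model(edge=3.0).fit()
        s100 = stress_summaries(res, percentile=100.0)
        s95 = stress_summaries(res, percentile=95.0)
        assert s100["cortical_stress"] == pytest.approx(
            s95["cortical_stress"], rel=0.10
        )
        assert s100["cancellous_stress"] == pytest.approx(
            s95["cancellous_stress"], rel=0.10
        )

    def test_failure_margin_is_stress_ratio_and_boundary_inclusive(self):
        res = _cylinder_model(edge=3.0).fit()
        out = failure_check(res)
        assert out["margin"] == pytest.approx(
            float(res.tet_von_mises.max()) / 2.82
        )
        assert out["failure"] is (out["margin"] >= 1.0)
        # boundary: margin exactly 1 flags failure
        card_boundary = MaterialCard(
            "b", 0.0, 8000.0, 300.0, float(res.tet_von_mises.max()), "pragmatic", "t"
        )
        assert failure_check(res, card_boundary)["failure"] is True

    def test_margin_scales_linearly_with_force(self):
        m = _cylinder_model(force=400.0, edge=3.0)
        r1 = m.fit()
        m.load.force_f = 400.0 * 20
        r2 = m.fit()
        assert failure_check(r2)["margin"] == pytest.approx(
            20 * failure_check(r1)["margin"], rel=1e-9
        )

    def test_results_summary_renders(self):
        spine = default_donor_spine()
        card = build_material_card(117.0, vertebra_label="Th6")
        res = solve_vertebra(spine["Th6"], card, 300.0, edge_target=3.0)
        text = res.summary()
        assert "Th6" in text and "von Mises" in text and "failure margin" in text.lower()
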