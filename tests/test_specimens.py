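"""Synthetic specimen generator: reference spine defaults, parametric
surfaces against quadrature oracles, and rasterization semantics."""

import numpy as np
import pytest
from scipy.integrate import quad

from spinefea.specimens import (
    DISH_LEVELS,
    LEVELS,
    MICRO_CT_LEVELS,
    SECTION_CANCELLOUS_HU,
    SECTION_CORTICAL_THICKNESS_UM,
    SECTION_OF,
    SpineSpec,
    VertebraSpec,
    default_donor_spine,
    mid_sagittal_volume,
    rasterize,
    spine_from_yaml,
    spine_to_yaml,
    vertebra_surface,
)


class TestDonorSpineDefaults:
    def test_anthropometry_and_count(self):
        spine = default_donor_spine()
        assert spine.body_mass == 104.5
        assert spine.body_height_m == 1.61
        assert len(spine.vertebrae) == 22
        assert [v.label for v in spine.vertebrae] == list(LEVELS)

    def test_section_parameter_assignment(self):
        spine = default_donor_spine()
        assert spine["Th8"].cortical_thickness == 188.0
        assert spine["C5"].cortical_thickness == 156.0
        assert spine["L3"].cortical_thickness == 149.0
        assert spine["C4"].cancellous_hu_mean == 222.0
        assert spine["L2"].cancellous_hu_mean == 47.8

    def test_section_thickness_ordering_ts_cs_ls(self):
        med = SECTION_CORTICAL_THICKNESS_UM
        assert med["TS"] > med["CS"] > med["LS"]

    def test_dish_levels_elevated_above_thoracic_baseline(self):
        spine = default_donor_spine()
        baseline = SECTION_CANCELLOUS_HU["TS"]
        for label in DISH_LEVELS:
            v = spine[label]
            assert v.dish_flag
            assert v.cancellous_hu_mean > baseline
        assert not spine["Th4"].dish_flag

    def test_micro_ct_covers_15_bodies(self):
        assert len(MICRO_CT_LEVELS) == 15

    def test_ordering_and_uniqueness_enforced(self):
        spine = default_donor_spine()
        with pytest.raises(ValueError, match="ordered"):
            SpineSpec(
                vertebrae=[spine["L1"], spine["C3"]],
                body_mass=70.0,
                body_height_m=1.7,
            )


class TestVertebraSurface:
    def test_watertight_genus_zero(self):
        spec = default_donor_spine()["Th8"]
        surf = vertebra_surface(spec, edge_target=2.0)
        assert surf.is_watertight
        n_v = len(surf.vertices)
        n_f = len(surf.faces)
        n_e = len(surf.edges_unique)
        assert n_v - n_e + n_f == 2  # Euler characteristic of a sphere

    def test_no_waist_gives_right_elliptical_cylinder(self):
        spec = default_donor_spine()["L3"]
        spec.waist_factor = 1.0
        surf = vertebra_surface(spec, edge_target=1.0)
        ap, ml = spec.endplate_semi_axes
        # volume equals prism volume pi*a*b*h within the polygonal error
        expected = np.pi * ap * ml * spec.body_height
        assert surf.volume == pytest.approx(expected, rel=0.01)

    def test_waisted_volume_matches_quadrature_oracle(self):
        """Enclosed volume vs 1-D quadrature of the cross-section profile."""
        spec = VertebraSpec(
            label="L3",
            section="LS",
            body_height=25.0,
            endplate_semi_axes=(15.0, 20.0),
            waist_factor=0.85,
            cortical_thickness=150.0,
            cancellous_hu_mean=100.0,
            cancellous_hu_sd=0.0,
        )
        surf = vertebra_surface(spec, edge_target=1.0)

        def section_area(z):
            s = 1.0 - (1.0 - 0.85) * np.cos(np.pi * z / 25.0) ** 2
            return np.pi * 15.0 * 20.0 * s**2

        expected, _ = quad(section_area, -12.5, 12.5)
        assert surf.volume == pytest.approx(expected, rel=0.02)

    def test_degenerate_spec_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            VertebraSpec(
                label="C3",
                section="CS",
                body_height=14.0,
                endplate_semi_axes=(0.0, 8.0),
                waist_factor=0.9,
                cortical_thickness=150.0,
                cancellous_hu_mean=200.0,
                cancellous_hu_sd=10.0,
            )


class TestRasterize:
    def _spec(self, sd=0.0, hu=117.0):
        spine = default_donor_spine()
        v = spine["Th6"]
        v.cancellous_hu_sd = sd
        v.cancellous_hu_mean = hu
        return v

    def test_zero_noise_interior_is_exactly_the_mean(self):
        vol = rasterize(self._spec(sd=0.0), 0.625)
        interior = vol.values[vol.labels == 1]
        assert np.all(interior == np.float32(117.0))

    def test_bitwise_reproducible_under_fixed_seed(self):
        a = rasterize(self._spec(sd=10.0), 0.625, seed=7)
        b = rasterize(self._spec(sd=10.0), 0.625, seed=7)
        assert np.array_equal(a.values, b.values)
        c = rasterize(self._spec(sd=10.0), 0.625, seed=8)
        assert not np.array_equal(a.values, c.values)

    def test_interior_mean_obeys_law_of_large_numbers(self):
        vol = rasterize(self._spec(sd=10.0), 0.625, seed=3)
        interior = vol.values[vol.labels == 1]
        n = interior.size
        assert abs(float(interior.mean()) - 117.0) < 3.0 * 10.0 / np.sqrt(n)

    def test_coarse_spacing_flags_thin_shell_band(self):
        vol = rasterize(self._spec(), 1.0)
        assert any("quarter voxel" in w for w in vol.meta["warnings"])
        fine = mid_sagittal_volume(self._spec(), 0.025)
        assert fine.meta["warnings"] == []

    def test_shell_band_width_matches_thickness_within_half_voxel(self):
        """Round trip: at 25 µm the rasterized cortical band on the ventral
        midline is as wide as the specified Cr.Th to within half a voxel."""
        for t_c in (101.0, 149.0, 156.0, 188.0):
            spec = self._spec()
            spec.cortical_thickness = t_c
            vol = mid_sagittal_volume(spec, 0.025)
            sl = vol.labels[:, 0, :]
            k_mid = sl.shape[1] // 2  # z = 0 row, ventral edge along +x
            row = sl[:, k_mid]
            band = np.flatnonzero(row == 2)
            ventral_run = band[band > sl.shape[0] // 2]
            width_um = len(ventral_run) * 25.0
            assert abs(width_um - t_c) <= 12.5 + 1e-9

    def test_spine_volume_stacks_all_bodies(self):
        spine = default_donor_spine(noise_seed=2)
        small = SpineSpec(
            vertebrae=[spine["C3"], spine["C4"]],
            body_mass=spine.body_mass,
            body_height_m=spine.body_height_m,
            noise_seed=2,
        )
        vol = rasterize(small, 1.0)
        assert set(vol.meta["centres_z"]) == {"C3", "C4"}
        assert (vol.labels > 0).sum() > 0


def test_yaml_round_trip(tmp_path):
    spine = default_donor_spine(noise_seed=5)
    path = tmp_path / "spine.yaml"
    spine_to_yaml(spine, path)
    back = spine_from_yaml(str(path))
    assert back.body_mass == spine.body_mass
    assert back.noise_seed == 5
    assert [v.label for v in back.vertebrae] == [v.label for v in spine.vertebrae]
    assert back["Th8"].cortical_thickness == spine["Th8"].cortical_thickness


def test_section_of_labels():
    assert SECTION_OF("C7") == "CS"
    assert SECTION_OF("Th12") == "TS"
    assert SECTION_OF("L1") == "LS"
    with pytest.raises(ValueError):
        SECTION_OF("S1")
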