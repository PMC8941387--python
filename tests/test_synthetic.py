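"""Synthetic cohorts: determinism, calibration, fixtures."""

import numpy as np
import pytest

from facemasc.landmarks import LANDMARK_CODES
from facemasc.synthetic import (CELL_SIZES, CELLS, CohortConfig, CohortError,
                                FeatureTableConfig, fixture_mesh,
                                generate_cohort, generate_feature_table)
from facemasc.template import DIMORPHISM_FIELD, FEMALE_TEMPLATE, subject_mesh


class TestCohortGenerator:
    def test_published_cell_counts(self):
        records, lsets = generate_cohort(CohortConfig(seed=0))
        assert len(records) == 355
        assert len(lsets) == 355
        counts = {}
        for r in records:
            counts[(r.sex, r.family_group)] = counts.get(
                (r.sex, r.family_group), 0) + 1
        assert counts == CELL_SIZES

    def test_degenerate_config_reproduces_template(self):
        config = CohortConfig(
            group_sizes={c: 2 for c in CELLS},
            dimorphism_scale=0.0, group_shift=0.0, noise_sd=0.0,
            size_sd=0.0, age_slope=0.0, seed=3,
        )
        _, lsets = generate_cohort(config)
        for ls in lsets:
            np.testing.assert_array_equal(ls.to_array(), FEMALE_TEMPLATE)

    def test_bitwise_deterministic(self):
        config = CohortConfig(seed=42)
        rec1, ls1 = generate_cohort(config)
        rec2, ls2 = generate_cohort(config)
        assert [r.age for r in rec1] == [r.age for r in rec2]
        for a, b in zip(ls1, ls2):
            np.testing.assert_array_equal(a.to_array(), b.to_array())

    def test_zero_subjects_error(self):
        with pytest.raises(CohortError, match="zero"):
            generate_cohort(CohortConfig(group_sizes={c: 0 for c in CELLS}))

    def test_negative_counts_rejected(self):
        with pytest.raises(CohortError):
            CohortConfig(group_sizes={("male", "autism_parent"): -1})

    def test_group_shift_monotone_masculinization(self):
        """Larger group shifts displace autism-parent faces further along
        the male direction."""
        field = DIMORPHISM_FIELD.ravel()
        field = field / np.linalg.norm(field)
        projections = []
        for shift in (0.0, 0.15, 0.30):
            config = CohortConfig(
                group_sizes={("male", "autism_parent"): 0,
                             ("female", "autism_parent"): 40,
                             ("male", "comparison_parent"): 0,
                             ("female", "comparison_parent"): 0},
                group_shift=shift, seed=5,
            )
            _, lsets = generate_cohort(config)
            disp = np.mean(
                [(ls.to_array() - FEMALE_TEMPLATE).ravel() @ field
                 for ls in lsets])
            projections.append(disp)
        assert projections[0] < projections[1] < projections[2]

    def test_sex_differences_along_dimorphism_field(self):
        records, lsets = generate_cohort(CohortConfig(seed=1))
        field = DIMORPHISM_FIELD.ravel()
        proj = {
            sex: np.mean([
                (ls.to_array() - FEMALE_TEMPLATE).ravel() @ field
                for r, ls in zip(records, lsets) if r.sex == sex])
            for sex in ("male", "female")
        }
        assert proj["male"] > proj["female"] + 0.5 * field @ field


class TestFeatureTableGenerator:
    def test_nasal_tip_cell_mean_calibrated(self):
        """The (fathers, autism) nasal-tip-protrusion cell mean lands
        within 3 s.e. of the configured 21.1 mm at n = 58."""
        cfg = FeatureTableConfig()
        table, _ = generate_feature_table(cfg, seed=0)
        cell = table[(table.sex == "male")
                     & (table.family_group == "autism_parent")]
        assert len(cell) == 58
        # standard error from the generator's actual cell spread (the
        # shape-contrast channel perturbs the s.d. of this variable)
        se = cell["e_nasal_tip_protrusion"].std(ddof=1) / np.sqrt(58)
        assert abs(cell["e_nasal_tip_protrusion"].mean() - 21.1) < 3 * se

    def test_all_cell_means_calibrated_across_seeds(self):
        """Every configured cell mean is within 3 s.e. of its target in
        >= 95% of seeds."""
        cfg = FeatureTableConfig()
        n_seeds = 60
        ok = {(v, ci): 0 for v in cfg.cell_stats for ci in range(4)}
        for seed in range(n_seeds):
            table, _ = generate_feature_table(cfg, seed=seed)
            for v, stats in cfg.cell_stats.items():
                for ci, (sex, grp) in enumerate(CELLS):
                    cell = table[(table.sex == sex)
                                 & (table.family_group == grp)]
                    mu, _ = stats[ci]
                    se = cell[v].std(ddof=1) / np.sqrt(len(cell))
                    ok[(v, ci)] += abs(cell[v].mean() - mu) < 3 * se
        for key, hits in ok.items():
            assert hits >= 0.95 * n_seeds, key

    def test_tiny_sd_collapses_to_cell_means(self):
        cfg = FeatureTableConfig()
        stats = {v: tuple((m, 1e-9) for (m, _) in s)
                 for v, s in cfg.cell_stats.items()}
        cfg = FeatureTableConfig(cell_stats=stats)
        table, _ = generate_feature_table(cfg, seed=2)
        for v, s in stats.items():
            for ci, (sex, grp) in enumerate(CELLS):
                cell = table[(table.sex == sex)
                             & (table.family_group == grp)]
                np.testing.assert_allclose(cell[v], s[ci][0], atol=1e-5)

    def test_age_feature_correlation_matches_loading(self):
        """At n = 10 000 per cell the within-cell age correlation is the
        configured loading (closed form of the linear-Gaussian model)."""
        cfg = FeatureTableConfig()
        sizes = {c: (10000 if c == ("female", "comparison_parent") else 0)
                 for c in CELLS}
        table, _ = generate_feature_table(cfg, group_sizes=sizes, seed=3)
        r = np.corrcoef(table["age"], table["e_nose_width"])[0, 1]
        assert r == pytest.approx(cfg.r_age, abs=0.05)

    def test_invalid_covariance_request(self):
        with pytest.raises(CohortError, match="positive definite"):
            FeatureTableConfig(masc_scale=2.5)

    def test_invalid_sd_rejected(self):
        cfg = FeatureTableConfig()
        stats = dict(cfg.cell_stats)
        stats["e_nose_width"] = tuple(
            (m, 0.0) for (m, _) in stats["e_nose_width"])
        with pytest.raises(CohortError, match="sd"):
            FeatureTableConfig(cell_stats=stats)

    def test_determinism(self):
        t1, _ = generate_feature_table(seed=9)
        t2, _ = generate_feature_table(seed=9)
        assert t1.equals(t2)

    def test_null_config_removes_group_signal(self):
        cfg = FeatureTableConfig().null_group_effect()
        for v, stats in cfg.cell_stats.items():
            for sex in ("male", "female"):
                cells = [stats[ci] for ci, c in enumerate(CELLS)
                         if c[0] == sex]
                assert cells[0][0] == cells[1][0]
        assert cfg.group_area["autism_parent"] \
            == cfg.group_area["comparison_parent"]

    def test_injected_effect_shifts_only_target_variable(self):
        cfg = FeatureTableConfig().with_group_effect("e_nose_width", 0.4)
        null = FeatureTableConfig().null_group_effect()
        for v in cfg.cell_stats:
            for ci, cell in enumerate(CELLS):
                delta = (cfg.cell_stats[v][ci][0]
                         - null.cell_stats[v][ci][0])
                if v == "e_nose_width" and cell[1] == "autism_parent":
                    assert delta > 0
                else:
                    assert delta == 0


def test_cohort_mean_facial_area_matches_published_scale():
    """Mean facial area over a calibrated cohort's deformed meshes lands
    within 10% of the published 35 435 mm^2."""
    sizes = {("male", "autism_parent"): 10,
             ("female", "autism_parent"): 22,
             ("male", "comparison_parent"): 8,
             ("female", "comparison_parent"): 19}
    _, lsets = generate_cohort(CohortConfig(group_sizes=sizes, seed=2))
    areas = [subject_mesh(ls).area() for ls in lsets]
    assert np.mean(areas) == pytest.approx(35435, rel=0.10)


class TestFixtureMeshes:
    def test_plane_is_coplanar(self):
        mesh = fixture_mesh("plane", 12)
        assert np.allclose(mesh.vertices[:, 2], 0.0)
        assert mesh.n_triangles > 0

    def test_sphere_vertices_unit_radius(self):
        mesh = fixture_mesh("unit_sphere", 3)
        radii = np.linalg.norm(mesh.vertices, axis=1)
        np.testing.assert_allclose(radii, 1.0, atol=1e-9)

    def test_face_template_interpolates_landmarks(self, small_cohort):
        """Each subject's landmarks lie on their deformed surface within
        the generator's landmark jitter."""
        records, lsets = small_cohort
        ls = lsets[0]
        mesh = fixture_mesh("face_template", landmarks=ls)
        _, dist, _ = mesh.closest_point(ls.to_array())
        assert np.all(dist <= 1.0)

    def test_unknown_kind(self):
        with pytest.raises(CohortError, match="unknown"):
            fixture_mesh("torus")

    def test_plane_resolution_floor(self):
        with pytest.raises(CohortError):
            fixture_mesh("plane", 1)
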