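"""Synthetic cohort generator: template anatomy, cohort structure,
longitudinal signal, and reproducibility."""

import numpy as np
import pandas as pd
import pytest

from rnflpca.config import CohortConfig
from rnflpca.maps import extract_mean_cprnflt
from rnflpca.simulate import (damage_patterns, generate_cohort,
                              generate_template_map)

SMALL_GRID = dict(grid_h=48, grid_w=64)


class TestTemplate:
    def test_ridge_structure_and_thin_fovea(self, default_cfg, template):
        v = template.values
        fx, fy = template.fovea_xy
        fovea_val = v[int(round(fy)), int(round(fx))]
        assert fovea_val < 0.25 * v.max()
        # peripapillary ring pixels are thicker than the field background
        ox, oy = template.onh_xy
        ring_val = v[int(round(oy)) - 23, int(round(ox))]  # ~1.7 mm above ONH
        assert ring_val > np.median(v)

    def test_circle_mean_tuned_to_target(self, default_cfg, template):
        assert extract_mean_cprnflt(template) == pytest.approx(
            default_cfg.template_cprnflt_um, abs=2.0)

    def test_deterministic_for_fixed_config(self, default_cfg, template):
        again = generate_template_map(default_cfg)
        assert np.array_equal(again.values, template.values)

    def test_zero_arcuate_amplitude_is_radially_symmetric(self):
        cfg = CohortConfig()
        tm = generate_template_map(cfg, arcuate_amplitude=0.0,
                                   foveal_depth=0.0)
        h, w = tm.shape
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        ux, uy = cfg.um_per_px
        r = np.hypot((xx - tm.onh_xy[0]) * ux, (yy - tm.onh_xy[1]) * uy)
        # sample two rings; all values on a ring should agree
        for r0 in (1000.0, 1700.0):
            band = np.abs(r - r0) < 20.0
            vals = tm.values[band]
            assert vals.std() < 0.02 * vals.mean()

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(grid_h=10, grid_w=10)


class TestCohortStructure:
    def test_default_eye_totals_match_study_design(self):
        cfg = CohortConfig(n_visits=1, **SMALL_GRID, seed=0)
        cohort, truth = generate_cohort(cfg)
        eyes = truth.eyes
        assert (eyes.group == "glaucoma").sum() == 179
        assert (eyes.group == "healthy").sum() == 56
        assert cohort.table.participant_id.nunique() == 93 + 28

    def test_fixed_seed_is_bit_identical(self):
        cfg = CohortConfig(n_glaucoma_participants=3, n_healthy_participants=2,
                           n_visits=2, **SMALL_GRID, seed=9)
        a, _ = generate_cohort(cfg)
        b, _ = generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.table, b.table)
        for sid in a.maps:
            assert np.array_equal(a.maps[sid].values, b.maps[sid].values)

    def test_no_variation_case_gives_identical_visit_maps(self):
        cfg = CohortConfig(n_glaucoma_participants=2, n_healthy_participants=1,
                           n_visits=4, **SMALL_GRID, seed=3,
                           measurement_noise_sd=0.0, healthy_slope_mean=0.0,
                           healthy_slope_sd=0.0, progressing_fraction=0.0,
                           slope_severity_coupling=0.0,
                           max_translation_px=0.0, max_rotation_deg=0.0,
                           max_scale_dev=0.0)
        cohort, truth = generate_cohort(cfg)
        for eye_id, sub in cohort.table.groupby("eye_id"):
            sids = sub.scan_id.tolist()
            first = cohort.maps[sids[0]].values
            for sid in sids[1:]:
                assert np.allclose(cohort.maps[sid].values, first, atol=1e-9)

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(progressing_fraction=1.5)

    def test_misalignment_and_laterality_recorded(self, small_cohort):
        cohort, truth = small_cohort
        scans = truth.scans
        assert scans.flipped.mean() == pytest.approx(0.5, abs=0.2)
        assert (scans.scale > 0).all()
        # recorded landmark positions follow the applied transform
        for sid in scans.scan_id.head(5):
            assert cohort.maps[sid].values.shape == (60, 80)


@pytest.fixture(scope="module")
def nine_visit_cohort():
    cfg = CohortConfig(n_glaucoma_participants=10,
                       n_healthy_participants=6, n_visits=9,
                       grid_h=60, grid_w=80, seed=21,
                       measurement_noise_sd=2.0)
    return generate_cohort(cfg)


class TestLongitudinalSignal:
    def test_ols_slope_recovery_of_mean_cprnflt(self, nine_visit_cohort):
        """Per-eye OLS slopes of the generated circle-scan series recover the
        generative rates to within the closed-form OLS error budget."""
        cohort, truth = nine_visit_cohort
        errs = []
        for eye_id, sub in cohort.table.groupby("eye_id"):
            t = sub.visit_month.to_numpy() / 12.0
            y = sub.mean_cprnflt.to_numpy()
            slope = np.polyfit(t, y, 1)[0]
            true = truth.eyes.set_index("eye_id").loc[eye_id, "slope_cprnflt"]
            errs.append(abs(slope - true))
        assert np.mean(errs) < 0.5

    def test_glaucoma_thinner_than_healthy_at_baseline(self, nine_visit_cohort):
        cohort, _ = nine_visit_cohort
        base = cohort.baseline()
        g = base.loc[base.group == "glaucoma", "mean_cprnflt"].mean()
        h = base.loc[base.group == "healthy", "mean_cprnflt"].mean()
        assert g < h

    def test_progressing_fraction_within_binomial_ci(self, nine_visit_cohort):
        _, truth = nine_visit_cohort
        eyes = truth.eyes[truth.eyes.group == "glaucoma"]
        n = len(eyes)
        p = 0.15
        observed = eyes.progressing.sum()
        sd = np.sqrt(n * p * (1 - p))
        assert abs(observed - n * p) <= 3 * sd + 1

    def test_structure_function_link(self, nine_visit_cohort):
        """Generated visual-field MD tracks the structural deficit."""
        cohort, truth = nine_visit_cohort
        base = cohort.baseline().set_index("eye_id")
        eyes = truth.eyes.set_index("eye_id")
        pat = truth.patterns
        loss = []
        for eye_id, row in eyes.iterrows():
            if row.group == "healthy":
                loss.append(0.0)
            else:
                m = pat[row.pattern]
                loss.append(row.severity_um * (m * m).sum() / m.sum())
        r = np.corrcoef(-np.asarray(loss), base.loc[eyes.index, "sap_md"])[0, 1]
        assert r > 0.6

    def test_age_confound_present(self, nine_visit_cohort):
        cohort, _ = nine_visit_cohort
        base = cohort.baseline()
        g = base.loc[base.group == "glaucoma", "age"].mean()
        h = base.loc[base.group == "healthy", "age"].mean()
        assert g > h + 5.0


def test_patterns_are_normalised_and_distinct(default_cfg):
    pats = damage_patterns(default_cfg)
    assert set(pats) == {"inferior_arcuate", "superior_arcuate",
                         "diffuse_macular"}
    for v in pats.values():
        assert v.min() >= 0 and v.max() == pytest.approx(1.0)
    inf, sup = pats["inferior_arcuate"], pats["superior_arcuate"]
    cos = (inf * sup).sum() / np.sqrt((inf ** 2).sum() * (sup ** 2).sum())
    assert cos < 0.2  # near-orthogonal damage directions
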