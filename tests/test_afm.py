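"""AFM analysis chain: flattening, detection, measurement, shape factor and
log-normal fits."""

import math

import numpy as np
import pytest

from coreshell import (AFMTopograph, ParticlePopulation, detect_particles,
                       equivalent_sphere_diameter, fit_lognormal,
                       flatten_first_order, gen_afm_topograph, measure_all,
                       measure_particle, shape_correction_factor)


def _plane(shape, a, b, c):
    I, J = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return a + b * I + c * J


class TestFlatten:
    def test_exact_on_pure_plane(self):
        topo = AFMTopograph(_plane((64, 64), 3.0, 0.05, -0.02), 1.0)
        flat = flatten_first_order(topo)
        assert np.max(np.abs(flat.heights)) < 1e-9

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        topo = AFMTopograph(_plane((64, 64), 1.0, 0.1, 0.2) + rng.normal(0, 0.5, (64, 64)),
                            1.0)
        once = flatten_first_order(topo)
        twice = flatten_first_order(once)
        np.testing.assert_allclose(twice.heights, once.heights, atol=1e-9)

    def test_masked_flatten_preserves_particle_heights(self):
        pop = ParticlePopulation([50.0, 40.0])
        topo, truth = gen_afm_topograph(pop, 1.0, 300.0, tilt_nm_per_px=0.05,
                                        noise_sd_nm=0.2, seed=7)
        # mask out particle footprints using ground truth
        coords = (np.arange(300) + 0.5) * 1.0
        X, Y = np.meshgrid(coords, coords)
        mask = np.zeros((300, 300), bool)
        for _, row in truth.iterrows():
            mask |= ((X - row.center_x_nm) ** 2 + (Y - row.center_y_nm) ** 2
                     < (row.width_x_nm / 2 + 3) ** 2)
        flat = flatten_first_order(topo, mask)
        for _, row in truth.iterrows():
            j = int(row.center_x_nm)
            i = int(row.center_y_nm)
            local = flat.heights[i - 2:i + 3, j - 2:j + 3].max()
            assert local == pytest.approx(row.height_nm, abs=5 * 0.2)

    def test_all_masked_rejected(self):
        topo = AFMTopograph(np.ones((8, 8)), 1.0)
        with pytest.raises(ValueError):
            flatten_first_order(topo, np.ones((8, 8), bool))


class TestDetect:
    def test_blank_noisy_image_yields_nothing(self):
        rng = np.random.default_rng(1)
        topo = AFMTopograph(rng.normal(0, 0.5, (256, 256)), 1.0)
        assert detect_particles(topo, min_height_nm=5 * 0.5) == []

    def test_counts_match_ground_truth(self):
        pop = ParticlePopulation(np.full(12, 50.0))
        topo, _ = gen_afm_topograph(pop, 2.0, 700.0, noise_sd_nm=0.3, seed=11)
        flat = flatten_first_order(topo)
        assert len(detect_particles(flat, 20.0)) == 12

    def test_touching_pair_flagged_as_fused(self):
        # construct two overlapping 50-nm caps -> one elongated region
        coords = (np.arange(200) + 0.5) * 1.0
        X, Y = np.meshgrid(coords, coords)
        z = np.zeros((200, 200))
        for cx in (80.0, 118.0):
            r2 = ((X - cx) ** 2 + (Y - 100.0) ** 2) / 25.0 ** 2
            cap = 25.0 * (1 + np.sqrt(np.clip(1 - r2, 0, None)))
            z = np.maximum(z, np.where(r2 < 1, cap, 0.0))
        topo = AFMTopograph(z, 1.0)
        regions = detect_particles(topo, 10.0)
        assert len(regions) == 1
        m = measure_particle(topo, regions[0], max_eccentricity=0.80)
        assert m.excluded and m.reason == "fused"


class TestMeasure:
    def test_sphere_measurement(self, sphere_topograph):
        topo, _ = sphere_topograph
        region = detect_particles(topo, 10.0)[0]
        m = measure_particle(topo, region)
        assert m.height_nm == pytest.approx(50.0, abs=0.05)
        assert m.widths_nm[0] == pytest.approx(50.0, abs=1.0)   # half-max, <= 1 px
        assert m.widths_nm[1] == pytest.approx(50.0, abs=1.0)
        assert m.aspect == pytest.approx(1.0, abs=0.03)

    def test_oblate_aspect_recovered(self, oblate_topograph):
        topo, _ = oblate_topograph
        region = detect_particles(topo, 30.0)[0]
        m = measure_particle(topo, region)
        assert m.aspect == pytest.approx(1.728, rel=0.05)

    def test_border_region_excluded(self):
        coords = (np.arange(100) + 0.5) * 1.0
        X, Y = np.meshgrid(coords, coords)
        r2 = (X ** 2 + (Y - 50.0) ** 2) / 25.0 ** 2   # centered on the border
        z = np.where(r2 < 1, 25.0 * (1 + np.sqrt(np.clip(1 - r2, 0, None))), 0.0)
        topo = AFMTopograph(z, 1.0)
        region = detect_particles(topo, 10.0)[0]
        m = measure_particle(topo, region)
        assert m.excluded and m.reason == "border"

    def test_aspect_trend_toward_spherical(self):
        # cores become rounder as the blend ratio increases
        aspects = []
        for i, aspect in enumerate((1.7, 1.4, 1.1)):
            pop = ParticlePopulation(np.full(8, 60.0))
            topo, _ = gen_afm_topograph(pop, 1.0, 800.0, shape_aspect=aspect,
                                        seed=20 + i)
            meas = measure_all(topo, 25.0)
            ok = meas[~meas.excluded.astype(bool)]
            aspects.append(ok.aspect.mean())
        assert aspects[0] > aspects[1] > aspects[2]
        assert aspects[2] == pytest.approx(1.1, rel=0.05)


class TestEquivalentSphere:
    @pytest.mark.parametrize("h,w1,w2,expected", [
        (50.0, 50.0, 50.0, pytest.approx(50.0, rel=1e-12)),
        (100.0, 172.8, 172.8, pytest.approx(144.0, rel=1e-3)),
    ])
    def test_values(self, h, w1, w2, expected):
        assert equivalent_sphere_diameter(h, w1, w2) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            equivalent_sphere_diameter(0.0, 10.0, 10.0)


class TestShapeFactor:
    def test_spheres_give_unity(self):
        pop = ParticlePopulation(np.full(14, 50.0))
        topo, _ = gen_afm_topograph(pop, 1.0, 800.0, seed=30)
        meas = measure_all(topo, 20.0)
        f, mad = shape_correction_factor(meas)
        assert f == pytest.approx(1.0, abs=0.03)

    def test_oblate_factor(self):
        pop = ParticlePopulation(np.full(12, 100.0))
        topo, _ = gen_afm_topograph(pop, 1.0, 1400.0, shape_aspect=1.728, seed=31)
        meas = measure_all(topo, 40.0)
        f, _ = shape_correction_factor(meas)
        assert f == pytest.approx(1.44, rel=0.05)

    def test_scale_invariance(self):
        # scaling all dimensions leaves the factor unchanged
        import pandas as pd
        base = pd.DataFrame({"height_nm": [50.0] * 12, "width1_nm": [86.4] * 12,
                             "width2_nm": [86.4] * 12})
        for s in (1.0, 3.0):
            df = base * s
            df["d_eq_nm"] = (df.height_nm * df.width1_nm * df.width2_nm) ** (1 / 3)
            f, _ = shape_correction_factor(df)
            assert f == pytest.approx(1.44, rel=1e-3)

    def test_too_few_rejected(self):
        import pandas as pd
        df = pd.DataFrame({"height_nm": [50.0] * 5, "d_eq_nm": [50.0] * 5})
        with pytest.raises(ValueError, match="at least 10"):
            shape_correction_factor(df)


class TestLogNormalFit:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(8)
        d = 100.0 * np.exp(0.1 * rng.standard_normal(5000))
        fit = fit_lognormal(d)
        assert fit.median_nm == pytest.approx(100.0, rel=0.01)
        assert fit.sigma_log == pytest.approx(0.1, rel=0.05)

    def test_monodisperse_degenerates(self):
        fit = fit_lognormal(np.full(30, 80.0))
        assert fit.sigma_log == pytest.approx(0.0, abs=1e-12)
        assert fit.mode_nm == pytest.approx(fit.median_nm, rel=1e-12)
        assert fit.median_nm == pytest.approx(80.0, rel=1e-12)

    def test_mode_identity(self):
        rng = np.random.default_rng(9)
        fit = fit_lognormal(60.0 * np.exp(0.2 * rng.standard_normal(500)))
        assert fit.mode_nm == pytest.approx(fit.median_nm * math.exp(-fit.sigma_log ** 2),
                                            rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fit_lognormal([50.0] * 10)          # too few
        with pytest.raises(ValueError):
            fit_lognormal([-1.0] * 30)          # nonpositive


def test_end_to_end_modal_diameter_recovery():
    """Full chain: render -> flatten -> detect -> measure -> correct -> fit.

    The recovered modal corrected diameter must land within max(2%, 1 px) of
    the generative median for a 300+ particle sample.
    """
    from coreshell.config import RunConfig
    from coreshell.pipeline import analyze_member_topograph

    cfg = RunConfig(seed=0)
    pixel = 2.0
    diams = []
    for i in range(4):
        pop_i = ParticlePopulation(
            50.0 * np.exp(0.1 * np.random.default_rng(100 + i).standard_normal(80)))
        topo, _ = gen_afm_topograph(pop_i, pixel, 1700.0, tilt_nm_per_px=0.02,
                                    noise_sd_nm=0.5, seed=200 + i)
        meas, fit, f = analyze_member_topograph(topo, 20.0, cfg, noise_sd_guess=0.5)
        ok = meas[~meas.excluded.astype(bool)]
        diams.append(f * ok.height_nm.to_numpy())
    all_d = np.concatenate(diams)
    assert all_d.size >= 300
    fit = fit_lognormal(all_d)
    tol = max(0.02 * 50.0, pixel)
    assert abs(fit.mode_nm - 50.0) <= tol
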