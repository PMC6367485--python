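"""Series pairing, screening, the trendline-shift shell estimator, the
polydispersity gap and the uncertainty budget."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coreshell import (SeriesPair, ShellThicknessModel, build_series_pair,
                       combine_uncertainty, estimate_shell_thickness,
                       gen_core_population, polydispersity_gap, predicted_gap,
                       screen_rows)

GOLD_NOMINALS = [5, 10, 30, 40, 50, 60, 80, 100, 150, 200, 250]


def _pair_df(nominals, L=17.0, sigma=0.0):
    return pd.DataFrame({
        "label": [f"{m}nm" for m in nominals],
        "d_afm_nm": [float(m) for m in nominals],
        "d_dls_nm": [float(m) + 2 * L for m in nominals],
        "sigma_log_afm": sigma,
    })


class TestBuildPair:
    def test_full_join(self):
        afm = pd.DataFrame({"label": [f"{m}nm" for m in GOLD_NOMINALS],
                            "d_afm_nm": GOLD_NOMINALS})
        dlsr = pd.DataFrame({"label": [f"{m}nm" for m in GOLD_NOMINALS],
                             "d_dls_nm": [m + 34 for m in GOLD_NOMINALS]})
        pair = build_series_pair(afm, dlsr)
        assert len(pair.data) == 11
        assert pair.unmatched == []

    def test_missing_label_reported(self):
        afm = pd.DataFrame({"label": [f"{m}nm" for m in GOLD_NOMINALS],
                            "d_afm_nm": GOLD_NOMINALS})
        dlsr = pd.DataFrame({"label": [f"{m}nm" for m in GOLD_NOMINALS[:-1]],
                             "d_dls_nm": [m + 34 for m in GOLD_NOMINALS[:-1]]})
        pair = build_series_pair(afm, dlsr)
        assert len(pair.data) == 10
        assert pair.unmatched == ["250nm"]

    def test_duplicate_label_rejected(self):
        afm = pd.DataFrame({"label": ["a", "a"], "d_afm_nm": [50.0, 60.0]})
        dlsr = pd.DataFrame({"label": ["a"], "d_dls_nm": [80.0]})
        with pytest.raises(ValueError, match="duplicate"):
            build_series_pair(afm, dlsr)

    def test_empty_intersection_rejected(self):
        afm = pd.DataFrame({"label": ["a"], "d_afm_nm": [50.0]})
        dlsr = pd.DataFrame({"label": ["b"], "d_dls_nm": [80.0]})
        with pytest.raises(ValueError, match="common"):
            build_series_pair(afm, dlsr)


class TestScreening:
    def test_curvature_cutoff_flags_small_members(self):
        pair = screen_rows(SeriesPair(_pair_df(GOLD_NOMINALS)))
        flagged = pair.data.loc[pair.data.excluded.astype(bool), "label"].tolist()
        assert flagged == ["5nm", "10nm", "30nm", "40nm"]
        assert set(pair.data.loc[pair.data.excluded.astype(bool), "reason"]) == {"curvature"}

    def test_wide_distribution_flagged(self):
        df = _pair_df([60, 80, 100])
        df.loc[1, "sigma_log_afm"] = 0.3
        pair = screen_rows(SeriesPair(df))
        row = pair.data.iloc[1]
        assert row.excluded and row.reason == "polydispersity"

    def test_clean_series_untouched(self):
        pair = screen_rows(SeriesPair(_pair_df([60, 80, 100, 150])))
        assert not pair.data.excluded.any()

    def test_too_few_survivors_rejected(self):
        with pytest.raises(ValueError, match="survive"):
            screen_rows(SeriesPair(_pair_df([5, 10, 60])))


class TestShellEstimator:
    def test_exact_offset_recovery(self):
        pair = screen_rows(SeriesPair(_pair_df(GOLD_NOMINALS, L=17.0)))
        est = estimate_shell_thickness(pair)
        assert est.thickness_nm == pytest.approx(17.0, rel=1e-12)
        assert est.se_nm == 0.0
        assert est.n_used == 7

    def test_results_object(self):
        pair = screen_rows(SeriesPair(_pair_df(GOLD_NOMINALS, L=8.0)))
        res = ShellThicknessModel(pair).fit()
        assert res.free_slope == pytest.approx(1.0, rel=1e-9)
        assert res.conf_int() == (pytest.approx(8.0), pytest.approx(8.0))
        assert "slope fixed at 1" in res.summary()
        assert [l for l, _ in res.excluded] == ["5nm", "10nm", "30nm", "40nm"]

    def test_negative_offset_warns_not_clamps(self):
        df = _pair_df([60, 80, 100], L=-2.0)
        res = ShellThicknessModel(SeriesPair(df)).fit()
        assert res.thickness_nm == pytest.approx(-2.0)
        assert res.negative_warning

    def test_gap_correction_applied(self):
        df = _pair_df([60, 80, 100], L=10.0)
        df["gap_nm"] = 4.0   # inflate DLS by a known polydispersity gap
        df["d_dls_nm"] += 4.0
        res = ShellThicknessModel(SeriesPair(df)).fit()
        assert res.thickness_nm == pytest.approx(10.0, rel=1e-12)

    def test_noisy_recovery_single_seed(self):
        rng = np.random.default_rng(99)
        m = np.array([50, 60, 80, 100, 150, 200, 250], float)
        df = pd.DataFrame({
            "label": [f"{v:g}" for v in m],
            "d_afm_nm": m * (1 + 0.028 * rng.standard_normal(m.size)),
            "d_dls_nm": (m + 34) * (1 + 0.016 * rng.standard_normal(m.size)),
            "u_afm_nm": 0.028 * m, "u_dls_nm": 0.016 * (m + 34),
        })
        res = ShellThicknessModel(SeriesPair(df)).fit()
        assert res.thickness_nm == pytest.approx(17.0, abs=3 * res.se_nm)
        assert res.se_nm > 0

    def test_wide_member_inflates_error(self):
        # including a broad-distribution member (whose DLS reads high by the
        # polydispersity gap) should on average worsen the estimate
        errs_with, errs_without = [], []
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            m = np.array([60, 80, 100, 150, 200], float)
            df = _pair_df([60, 80, 100, 150, 200], L=17.0)
            df["d_afm_nm"] = m * (1 + 0.028 * rng.standard_normal(m.size))
            df["d_dls_nm"] = (m + 34) * (1 + 0.016 * rng.standard_normal(m.size))
            wide = pd.DataFrame({
                "label": ["wide"], "d_afm_nm": [100.0],
                "d_dls_nm": [(100 + 34) + predicted_gap(100.0, 0.3)],
                "sigma_log_afm": [0.3]})
            both = pd.concat([df, wide], ignore_index=True)
            e_with = ShellThicknessModel(SeriesPair(both)).fit().thickness_nm
            e_wo = ShellThicknessModel(SeriesPair(df)).fit().thickness_nm
            errs_with.append(abs(e_with - 17.0))
            errs_without.append(abs(e_wo - 17.0))
        assert np.mean(errs_with) > np.mean(errs_without)


class TestPolydispersityGap:
    def test_monodisperse_gap_is_zero(self):
        pop = gen_core_population(100.0, 0.0, 50, seed=0)
        assert polydispersity_gap(pop) == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_value(self):
        # sigma = 0.2, median 100: 100*(exp(5.5*0.04) - exp(-0.04)) ~ 28.5 nm
        assert predicted_gap(100.0, 0.2) == pytest.approx(28.5287, rel=1e-4)
        rel_sd = math.sqrt(math.expm1(0.04))
        pop = gen_core_population(100.0, rel_sd, 50000, seed=21)
        assert polydispersity_gap(pop) == pytest.approx(28.53, rel=0.10)

    def test_strictly_increasing_in_width(self):
        gaps = []
        for sigma in (0.0, 0.05, 0.1, 0.15, 0.2):
            rel_sd = math.sqrt(math.expm1(sigma ** 2))
            pop = gen_core_population(100.0, rel_sd, 30000, seed=22)
            gaps.append(polydispersity_gap(pop))
        assert all(np.diff(gaps) > 0)


class TestUncertaintyBudget:
    def test_pythagorean_combination(self):
        b = combine_uncertainty([("a", 3.0), ("b", 4.0)])
        assert b.combined_pct == pytest.approx(5.0, rel=1e-12)
        assert b.expanded_pct == pytest.approx(10.0, rel=1e-12)
        assert b.confidence_label == "95% confidence interval"

    def test_single_component(self):
        b = combine_uncertainty([("only", 2.8)])
        assert b.combined_pct == pytest.approx(2.8)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            combine_uncertainty([])

    @settings(max_examples=30, deadline=None)
    @given(us=st.lists(st.floats(0, 50), min_size=1, max_size=6),
           scale=st.floats(0.1, 10))
    def test_permutation_invariant_and_homogeneous(self, us, scale):
        comps = [(f"c{i}", u) for i, u in enumerate(us)]
        b1 = combine_uncertainty(comps)
        b2 = combine_uncertainty(list(reversed(comps)))
        assert b1.combined_pct == pytest.approx(b2.combined_pct, rel=1e-9, abs=1e-12)
        b3 = combine_uncertainty([(n, scale * u) for n, u in comps])
        assert b3.combined_pct == pytest.approx(scale * b1.combined_pct,
                                                rel=1e-9, abs=1e-9)
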