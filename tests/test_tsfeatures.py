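"""Feature bank: closed-form oracles, validity filter, normalization."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.tsa.ar_model import AutoReg

from angerppg.dataset_io import LabeledWindow
from angerppg.tsfeatures import (
    FeatureBankConfig,
    build_matrix,
    extract,
    gaussian_ami,
    maxmin_normalize,
    tertiary_family,
)


def _ar1(n: int, rho: float, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = rng.standard_normal() / np.sqrt(1 - rho**2)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + rng.standard_normal()
    return x


def _window(samples, wid="w000", anger=0):
    return LabeledWindow(
        window_id=wid, participant_id="P01", day="A", group="nonTBI",
        samples=np.asarray(samples, dtype=float), anger=anger,
        section_method="video", t_start=0.0,
    )


class TestGaussianAMI:
    @pytest.mark.parametrize("rho", [0.3, 0.5, 0.7])
    def test_matches_closed_form_on_ar1(self, rho):
        # for a Gaussian AR(1), AMI at lag 1 is -0.5 * ln(1 - rho^2)
        errs = [
            gaussian_ami(_ar1(4480, rho, seed), 1) + 0.5 * np.log1p(-(rho**2))
            for seed in range(8)
        ]
        # mean absolute error over replicate series (single-series sampling
        # noise at n = 4480 is ~0.01 for rho = 0.7)
        assert np.mean(np.abs(errs)) < 0.02

    def test_agrees_with_direct_covariance_oracle(self, rng):
        # independent oracle: explicit covariance arithmetic, no corrcoef
        for _ in range(50):
            x = rng.standard_normal(600)
            lag = int(rng.integers(1, 20))
            a, b = x[:-lag] - x[:-lag].mean(), x[lag:] - x[lag:].mean()
            rho = (a @ b) / np.sqrt((a @ a) * (b @ b))
            expected = -0.5 * np.log(1 - rho**2)
            assert gaussian_ami(x, lag) == pytest.approx(expected, abs=1e-8)


class TestModelFits:
    def test_ar2_recovery_with_sbc_selection(self):
        rng = np.random.default_rng(3)
        a1, a2 = 0.5, -0.3
        x = np.empty(4480)
        x[:2] = rng.standard_normal(2)
        for i in range(2, len(x)):
            x[i] = a1 * x[i - 1] + a2 * x[i - 2] + rng.standard_normal()
        feats = extract(x, FeatureBankConfig(families=("MF_arfit_1_8_sbc",)))
        assert feats["MF_arfit_1_8_sbc.order"] == 2
        assert feats["MF_arfit_1_8_sbc.a1"] == pytest.approx(a1, abs=0.05)
        assert feats["MF_arfit_1_8_sbc.a2"] == pytest.approx(a2, abs=0.05)

    def test_ar_fit_agrees_with_statsmodels(self):
        x = _ar1(4480, 0.6, seed=4)
        z = (x - x.mean()) / x.std()
        feats = extract(z, FeatureBankConfig(families=("MF_arfit_1_8_sbc",)))
        order = int(feats["MF_arfit_1_8_sbc.order"])
        ref = AutoReg(z, lags=order, trend="c").fit()
        for k in range(order):
            assert feats[f"MF_arfit_1_8_sbc.a{k + 1}"] == pytest.approx(
                ref.params[k + 1], abs=1e-2
            )

    def test_garch_detects_conditional_heteroskedasticity(self):
        # simulate a GARCH(1,1)-style series: persistence should be high,
        # versus near-zero ARCH terms on white noise
        rng = np.random.default_rng(5)
        n = 4480
        e = np.empty(n)
        s2 = 1.0
        for i in range(n):
            s2 = 0.05 + 0.15 * (e[i - 1] ** 2 if i else 1.0) + 0.8 * s2
            e[i] = np.sqrt(s2) * rng.standard_normal()
        cfg = FeatureBankConfig(families=("MF_GARCH_ar_P1_Q2",))
        f_garch = extract(e, cfg)
        f_white = extract(rng.standard_normal(n), cfg)
        assert f_garch["MF_GARCH_ar_P1_Q2.persistence"] > 0.7
        assert (
            f_garch["MF_GARCH_ar_P1_Q2.alpha1"] + f_garch["MF_GARCH_ar_P1_Q2.alpha2"]
            > f_white["MF_GARCH_ar_P1_Q2.alpha1"] + f_white["MF_GARCH_ar_P1_Q2.alpha2"]
        )


class TestMotifs:
    def test_proportions_sum_to_one_per_word_length(self, rng):
        x = rng.standard_normal(2000)
        feats = extract(x, FeatureBankConfig(families=("SB_MotifThree_diffquant",)))
        for L in (1, 2, 3, 4):
            total = sum(
                v for k, v in feats.items()
                if k.startswith(f"SB_MotifThree_diffquant.p{L}_")
            )
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_alphabet_is_equiprobable_at_length_one(self, rng):
        x = rng.standard_normal(5000)
        feats = extract(x, FeatureBankConfig(families=("SB_MotifThree_diffquant",)))
        for w in ("a", "b", "c"):
            assert feats[f"SB_MotifThree_diffquant.p1_{w}"] == pytest.approx(1 / 3, abs=0.01)


class TestMatrix:
    def test_validity_filter_drops_column_cohort_wide(self, rng):
        good = _window(rng.standard_normal(500), "w0")
        flat = _window(np.zeros(500), "w1")  # constant: model features missing
        cfg = FeatureBankConfig(families=("DN_Summaries", "SP_Summaries_fft"))
        m = build_matrix([good, flat], cfg)
        assert all(c.startswith("DN_Summaries") for c in m.values.columns)
        assert not m.values.isna().any().any()

    def test_duplicate_window_ids_rejected(self, rng):
        w = _window(rng.standard_normal(500))
        with pytest.raises(ValueError, match="duplicate"):
            build_matrix([w, w])

    def test_extraction_is_deterministic(self, rng):
        x = rng.standard_normal(1000)
        assert extract(x) == extract(x)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="256"):
            extract(np.zeros(100))

    def test_feature_ids_have_tertiary_prefix(self, small_pipeline):
        for fid in small_pipeline.matrix.feature_ids:
            fam = tertiary_family(fid)
            assert "." not in fam and fam  # family is the pre-dot token
            assert fid.startswith(fam + ".")


class TestNormalization:
    def test_hand_arithmetic_example(self):
        values = pd.DataFrame(
            {"F.x": [2.0, 4.0, 6.0]},
            index=pd.Index(["a", "b", "c"], name="window_id"),
        )
        from angerppg.tsfeatures import FeatureMatrix

        meta = pd.DataFrame(index=values.index)
        m = maxmin_normalize(FeatureMatrix(values, meta))
        assert list(m.values["F.x"]) == [0.0, 0.5, 1.0]

    def test_idempotent_on_attained_unit_range(self, rng):
        from angerppg.tsfeatures import FeatureMatrix

        col = np.r_[0.0, rng.random(10), 1.0]
        values = pd.DataFrame({"F.x": col}, index=pd.Index([f"w{i}" for i in range(12)], name="window_id"))
        m = maxmin_normalize(FeatureMatrix(values, pd.DataFrame(index=values.index)))
        assert np.allclose(m.values["F.x"], col)

    def test_constant_column_dropped_with_warning(self, rng):
        from angerppg.tsfeatures import FeatureMatrix

        values = pd.DataFrame(
            {"F.x": rng.random(5), "F.const": np.ones(5)},
            index=pd.Index([f"w{i}" for i in range(5)], name="window_id"),
        )
        with pytest.warns(UserWarning, match="zero-range"):
            m = maxmin_normalize(FeatureMatrix(values, pd.DataFrame(index=values.index)))
        assert list(m.values.columns) == ["F.x"]

    def test_rank_order_preserved_and_bounds_attained(self, small_pipeline):
        raw, normed = small_pipeline.matrix_raw, small_pipeline.matrix
        assert float(normed.values.min().min()) == 0.0
        assert float(normed.values.max().max()) == 1.0
        for col in list(normed.values.columns)[::50]:
            a = raw.values[col].rank().to_numpy()
            b = normed.values[col].rank().to_numpy()
            assert np.array_equal(a, b)


class TestSensitivity:
    def test_spectral_feature_tracks_anger_heart_rate_shift(self, small_pipeline):
        # anger raises HR, so the dominant spectral peak of anger windows sits
        # higher than that of neutral-state windows within each session
        m = small_pipeline.matrix_raw
        meta = m.metadata
        col = "SP_Summaries_fft.peak_freq"
        sess = m.session_ids()
        diffs = []
        for sid in sess.unique():
            sel = sess == sid
            anger = m.values.loc[sel.to_numpy() & (meta["anger"] == 1), col]
            other = m.values.loc[sel.to_numpy() & (meta["anger"] == 0), col]
            diffs.append(anger.mean() - other.mean())
        assert np.mean(diffs) > 0
        assert np.mean(np.array(diffs) > 0) >= 0.75
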