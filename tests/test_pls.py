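"""NIPALS PLS-1: closed forms, oracle equivalence, cross-validation, attribution."""

import numpy as np
import pytest

from evftir.pls import (
    ClassCoding,
    beta_peak_attribution,
    cross_validate,
    encode_classes,
    fit_pls,
    predict,
)
from evftir.preprocess import preprocess_pipeline
from evftir.simulate import default_scenario, simulate_dataset
from evftir.spectra import SampleMeta


def _meta(conditions):
    return tuple(
        SampleMeta(f"s{i}", "cells", c, 1 + i // 3, 1 + i % 3)
        for i, c in enumerate(conditions)
    )


class TestEncode:
    def test_default_coding(self):
        y = encode_classes(_meta(["control", "abeta", "control"]))
        np.testing.assert_array_equal(y, [0.0, 1.0, 0.0])

    def test_signed_coding(self):
        coding = ClassCoding({"control": -1.0, "abeta": 1.0})
        y = encode_classes(_meta(["control", "abeta"]), coding)
        np.testing.assert_array_equal(y, [-1.0, 1.0])
        assert coding.positive_class() == "abeta"

    def test_unknown_condition_rejected(self):
        coding = ClassCoding({"control": 0.0, "other": 1.0})
        with pytest.raises(ValueError, match="abeta"):
            encode_classes(_meta(["control", "abeta"]), coding)

    def test_single_code_rejected(self):
        with pytest.raises(ValueError):
            ClassCoding({"control": 1.0, "abeta": 1.0})


class TestFit:
    def test_orthonormal_columns_closed_form(self):
        rng = np.random.default_rng(0)
        Q, _ = np.linalg.qr(rng.normal(size=(8, 4)))
        Q -= Q.mean(axis=0)  # recenter; keep first column as response
        Q, _ = np.linalg.qr(Q)  # re-orthonormalize the centered columns
        y = Q[:, 0].copy()
        m = fit_pls(Q, y, n_factors=1)
        beta = m.beta
        np.testing.assert_allclose(beta[0], 1.0, atol=1e-8)
        np.testing.assert_allclose(beta[1:], 0.0, atol=1e-8)
        np.testing.assert_allclose(predict(m, Q), y, atol=1e-8)

    def test_one_factor_is_projection_on_t(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        m = fit_pls(X, y, n_factors=1)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        t = Xc @ (Xc.T @ yc / np.linalg.norm(Xc.T @ yc))
        oracle = y.mean() + t * (t @ yc) / (t @ t)
        np.testing.assert_allclose(predict(m, X), oracle, atol=1e-10)

    def test_saturated_fit_reproduces_y(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 8))
        y = rng.normal(size=6)
        m = fit_pls(X, y, n_factors=5)
        np.testing.assert_allclose(predict(m, X), y, atol=1e-8)

    def test_ols_oracle_and_rmsec_monotone(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            p = int(rng.integers(2, 7))
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            Xc = X - X.mean(axis=0)
            k = min(n - 1, np.linalg.matrix_rank(Xc))
            m = fit_pls(X, y, n_factors=k)
            ols = y.mean() + Xc @ np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
            np.testing.assert_allclose(predict(m, X), ols, atol=1e-8)
            rmse = [
                np.sqrt(np.mean((y - predict(m, X, n_factors=j)) ** 2))
                for j in range(1, m.n_factors + 1)
            ]
            assert all(b <= a + 1e-10 for a, b in zip(rmse, rmse[1:]))

    def test_matches_sklearn_pls_fit(self):
        # independent implementation cross-check on fitted values and beta
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(21)
        X = rng.normal(size=(14, 10))
        y = rng.normal(size=14)
        for k in (1, 2, 4):
            mine = fit_pls(X, y, n_factors=k)
            ref = PLSRegression(n_components=k, scale=False).fit(X, y[:, None])
            np.testing.assert_allclose(
                mine.beta, ref.coef_.ravel(), atol=1e-8
            )
            np.testing.assert_allclose(
                predict(mine, X), ref.predict(X).ravel(), atol=1e-8
            )

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 20))
        y = rng.normal(size=12)
        m = fit_pls(X, y, n_factors=5)
        G = m.T.T @ m.T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.diag(G).max()

    def test_sign_convention(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(9, 5))
        y = rng.normal(size=9)
        m = fit_pls(X, y, n_factors=3)
        for a in range(m.n_factors):
            w = m.W[:, a]
            assert w[int(np.argmax(np.abs(w)))] > 0

    def test_constant_y_rejected(self):
        X = np.random.default_rng(6).normal(size=(5, 3))
        with pytest.raises(ValueError, match="constant"):
            fit_pls(X, np.ones(5), n_factors=1)


class TestPredict:
    def test_beta_identity_on_training_data(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        m = fit_pls(X, y, n_factors=3)
        # NIPALS reconstruction: y_mean + sum_a t_a q_a
        nipals_fit = m.y_mean + m.T @ m.q
        np.testing.assert_allclose(predict(m, X), nipals_fit, atol=1e-10)

    def test_mean_row_predicts_mean(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        m = fit_pls(X, y, n_factors=2)
        np.testing.assert_allclose(
            predict(m, m.x_mean[None, :]), [m.y_mean], atol=1e-12
        )

    def test_constant_shift_linearity(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        m = fit_pls(X, y, n_factors=2)
        c = 1.37
        delta = predict(m, X + c) - predict(m, X)
        np.testing.assert_allclose(delta, c * m.beta.sum(), atol=1e-10)


class TestCrossValidate:
    def test_rmsec_definition_and_explicit_loop(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(12, 8))
        y = rng.normal(size=12)
        y_cv, metrics = cross_validate(X, y, n_factors=2)
        full = fit_pls(X, y, n_factors=2)
        resid = y - predict(full, X)
        np.testing.assert_allclose(
            metrics.rmsec, np.sqrt(np.mean(resid**2)), atol=1e-12
        )
        # independent refit loop
        loop = np.empty_like(y)
        for i in range(12):
            keep = [j for j in range(12) if j != i]
            m = fit_pls(X[keep], y[keep], n_factors=2)
            loop[i] = predict(m, X[i : i + 1])[0]
        np.testing.assert_allclose(y_cv, loop, atol=1e-12)
        np.testing.assert_allclose(
            metrics.rmsecv, np.sqrt(np.mean((y - loop) ** 2)), atol=1e-12
        )

    def test_separable_classes_validate_strongly(self, ev_dataset):
        _, deriv, _ = preprocess_pipeline(ev_dataset)
        y = encode_classes(deriv.meta)
        _, metrics = cross_validate(deriv, y, n_factors=1)
        assert metrics.r_val > 0.9
        assert metrics.rmsecv < 0.25

    def test_permuted_labels_fail_validation(self, ev_dataset):
        _, deriv, _ = preprocess_pipeline(ev_dataset)
        y = encode_classes(deriv.meta)
        _, real = cross_validate(deriv, y, n_factors=1)
        rng = np.random.default_rng(11)
        null_r = []
        for _ in range(199):
            perm = rng.permutation(y)
            if np.ptp(perm) == 0:
                continue
            try:
                _, m = cross_validate(deriv.absorbance, perm, n_factors=1)
            except ValueError:
                continue
            null_r.append(m.r_val)
        assert real.r_val > np.quantile(null_r, 0.95)

    def test_bio_rep_scheme_holds_out_whole_replicates(self, ev_dataset):
        _, deriv, _ = preprocess_pipeline(ev_dataset)
        y = encode_classes(deriv.meta)
        y_cv, metrics = cross_validate(deriv, y, n_factors=1, scheme="loo_bio_rep")
        # manual 6-segment loop over (condition, bio_rep)
        groups = {}
        for i, m in enumerate(deriv.meta):
            groups.setdefault((m.condition, m.bio_rep), []).append(i)
        loop = np.empty_like(y)
        for key in sorted(groups):
            seg = groups[key]
            keep = [j for j in range(18) if j not in seg]
            mm = fit_pls(deriv.absorbance[keep], y[keep], n_factors=1)
            loop[seg] = predict(mm, deriv.absorbance[seg])
        np.testing.assert_allclose(y_cv, loop, atol=1e-12)
        assert metrics.rmsecv >= metrics.rmsec - 1e-12

    def test_too_few_segments_rejected(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(2, 4))
        with pytest.raises(ValueError):
            cross_validate(X, np.array([0.0, 1.0]), n_factors=1)


class TestBetaAttribution:
    def test_single_effect_band_sign(self):
        # only the 1240 band amplitude differs between classes
        from dataclasses import replace

        from evftir.simulate import BandSpec, SimConfig, simulate_dataset

        bands = (
            BandSpec(center=1240.0, base_amplitude=0.5, effect_multiplier=0.7),
            BandSpec(center=1085.0, base_amplitude=0.6),
            BandSpec(center=969.0, base_amplitude=0.35),
        )
        cfg = SimConfig(sample_type="cells", bands=bands, seed=3)
        data = simulate_dataset(cfg)
        _, deriv, _ = preprocess_pipeline(data)
        y = encode_classes(deriv.meta)
        m = fit_pls(deriv, y, n_factors=1)
        table = beta_peak_attribution(m, [1240.0], tolerance=6.0)
        row = table.iloc[0]
        assert row["matched"]
        # decreased band in the treated class: at the band center the second
        # derivative is *less negative* for abeta, so beta there is positive
        # under control=0 / abeta=1 coding
        assert row["sign"] == 1
        assert row["associated_class"] == "abeta"

    def test_missing_axis_rejected(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(10, 7))
        y = rng.normal(size=10)
        m = fit_pls(X, y, n_factors=1)
        with pytest.raises(ValueError):
            beta_peak_attribution(m, [3.0])

    def test_tolerance_zero_matches_on_grid_extremum(self, ev_run):
        beta = ev_run.beta
        # pick the global beta extremum (a guaranteed local extremum)
        k = int(np.argmax(np.abs(beta["beta"].to_numpy())))
        wn = float(beta["wavenumber"].iloc[k])
        m = fit_pls(
            ev_run.second_deriv, encode_classes(ev_run.second_deriv.meta), 1
        )
        out = beta_peak_attribution(m, [wn], tolerance=0.0)
        assert out.iloc[0]["matched"] and out.iloc[0]["found_cm1"] == wn

    def test_unmatched_targets_reported(self, ev_run):
        from evftir.pls import fit_pls as _fit

        table = ev_run.beta_peaks
        assert set(table.columns) >= {"target_cm1", "matched", "sign"}
        # far-off target is unmatched, not an error
        m = _fit(
            ev_run.second_deriv, encode_classes(ev_run.second_deriv.meta), 1
        )
        out = beta_peak_attribution(m, [5000.0], tolerance=6.0)
        assert not out.iloc[0]["matched"]
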