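import numpy as np
import pytest
from scipy.stats import ortho_group

from swirauth import DDSimca, dof_estimate, select_factors
from swirauth.preprocess import SpectralPreprocessor

# chi-square quantiles frozen from an independent oracle (R qchisq)
R_CHI2_Q99 = {
    2: 9.2103403720,
    3: 11.3448667301,
    4: 13.2767041360,
    5: 15.0862724694,
    10: 23.2092511590,
    50: 76.1538912490,
    100: 135.8067231710,
    150: 193.2076863855,
    180: 227.0561246479,
    200: 249.4451229814,
    250: 304.9395557340,
    300: 359.9064259503,
    400: 468.7244983740,
}


@pytest.fixture(scope="module")
def gaussian_model():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(200, 20))
    return DDSimca(n_components=3).fit(X), X


class TestDofEstimate:
    def test_recovers_chi_square_dof(self):
        rng = np.random.default_rng(5)
        assert dof_estimate(3.7 * rng.chisquare(4, 10_000)) == 4

    def test_exponential_is_two_dof(self):
        rng = np.random.default_rng(6)
        assert dof_estimate(rng.exponential(2.5, 10_000)) == 2

    def test_constant_distances_capped_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            assert dof_estimate(np.full(10, 3.0)) == 250
        assert "capped" in caplog.text

    def test_short_or_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            dof_estimate(np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            dof_estimate(np.zeros(5))


class TestFit:
    def test_training_score_distance_identity(self, gaussian_model):
        """With eigenvalues s^2/(n-1), training score distances average to
        A*(n-1)/n exactly."""
        model, X = gaussian_model
        n = X.shape[0]
        h = model.training_distances_["h"].to_numpy()
        assert h.mean() == pytest.approx(3 * (n - 1) / n, rel=1e-10)

    def test_cutoffs_match_independent_quantile_oracle(self, gaussian_model):
        from scipy.stats import chi2

        model, X = gaussian_model
        ndof = model.dof_score_ + model.dof_orth_
        # the quantile function itself agrees with the external oracle
        for dof, q in R_CHI2_Q99.items():
            assert chi2.ppf(0.99, dof) == pytest.approx(q, rel=1e-9)
        # and the fitted cutoffs are those quantiles at the estimated dof
        assert model.c_crit_ == pytest.approx(chi2.ppf(0.99, ndof))
        assert model.c_out_ == pytest.approx(chi2.ppf((1 - 0.01) ** (1 / 200), ndof))
        assert model.c_out_ > model.c_crit_

    def test_alpha_quantile_oracle_at_five_dof(self):
        from scipy.stats import chi2

        assert chi2.ppf(1 - 0.01, 5) == pytest.approx(R_CHI2_Q99[5], rel=1e-9)
        assert round(float(chi2.ppf(0.99, 5)), 2) == 15.09

    def test_overfitted_basis_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError):
            DDSimca(n_components=4).fit(X)  # A >= rank of centered matrix

    def test_invalid_levels_rejected(self, rng):
        X = rng.normal(size=(20, 5))
        with pytest.raises(ValueError):
            DDSimca(n_components=2, alpha=0.01, gamma=0.05).fit(X)  # gamma > alpha


class TestDistances:
    def test_center_row_is_distance_free(self, gaussian_model):
        model, _ = gaussian_model
        rec = model.distances(model.center_[None, :])
        assert rec["h"][0] == pytest.approx(0, abs=1e-18)
        assert rec["v"][0] == pytest.approx(0, abs=1e-18)
        assert rec["c"][0] == pytest.approx(0, abs=1e-15)

    def test_in_plane_displacement(self, gaussian_model):
        model, _ = gaussian_model
        delta = 0.7
        row = model.center_ + model.loadings_[:, 0] * delta
        rec = model.distances(row[None, :])
        assert rec["v"][0] == pytest.approx(0, abs=1e-12)
        assert rec["h"][0] == pytest.approx(delta**2 / model.eigenvalues_[0])

    def test_orthogonal_displacement(self, gaussian_model, rng):
        model, _ = gaussian_model
        w = rng.normal(size=model.center_.size)
        w -= model.loadings_ @ (model.loadings_.T @ w)
        w /= np.linalg.norm(w)
        delta = 1.3
        rec = model.distances((model.center_ + w * delta)[None, :])
        assert rec["h"][0] == pytest.approx(0, abs=1e-12)
        assert rec["v"][0] == pytest.approx(delta**2)

    def test_band_mismatch_rejected(self, gaussian_model, rng):
        model, _ = gaussian_model
        with pytest.raises(ValueError, match="band count"):
            model.distances(rng.normal(size=(1, 7)))


class TestClassify:
    def test_boundary_is_inclusive(self, gaussian_model, rng):
        model, _ = gaussian_model
        x = rng.normal(size=(1, 20))
        c = model.distances(x)["c"][0]
        # force the cutoff onto this sample's total distance: still accepted
        model.c_crit_ = float(c)
        assert model.classify(x)["decision"][0] == "accepted"

    def test_fresh_target_samples_mostly_accepted(self):
        rng = np.random.default_rng(3)
        model = DDSimca(n_components=5).fit(rng.normal(size=(500, 30)))
        fresh = rng.normal(size=(200, 30))
        assert (model.predict(fresh) == 1).mean() >= 0.95

    def test_distant_class_fully_rejected(self, grid, endmembers):
        """Strong adulteration is always flagged: 50% apricot mixtures are
        far outside the pure-almond class."""
        from swirauth import mix_spectra, render_endmember
        from swirauth.simulate import NoiseModel, _corrupt_matrix

        almond = render_endmember(endmembers["almond"], grid)
        apricot = render_endmember(endmembers["apricot"], grid)
        noise = NoiseModel()
        rng = np.random.default_rng(8)

        def well_spectra(spectrum, n, n_px=100):
            # each specimen is the average of n_px independently corrupted
            # pixels, as the extraction stage produces
            pix = _corrupt_matrix(np.tile(spectrum, (n * n_px, 1)), noise, rng)
            return pix.reshape(n, n_px, -1).mean(axis=1)

        pure = well_spectra(almond, 100)
        adulterated = well_spectra(mix_spectra(almond, apricot, 0.5), 50)
        model = DDSimca(n_components=3, preprocessor=SpectralPreprocessor("snv")).fit(pure)
        assert (model.predict(adulterated) == -1).all()

    def test_monotone_in_orthogonal_residual(self, gaussian_model, rng):
        """Scaling a sample's out-of-plane residual up never turns a
        rejection into an acceptance."""
        model, _ = gaussian_model
        w = rng.normal(size=20)
        w -= model.loadings_ @ (model.loadings_.T @ w)
        w /= np.linalg.norm(w)
        cs = [
            model.distances((model.center_ + w * d)[None, :])["c"][0]
            for d in (0.5, 1.0, 2.0, 4.0)
        ]
        assert np.all(np.diff(cs) > 0)

    def test_rotation_invariance(self, rng):
        """Acceptance decisions are unchanged by a common orthogonal rotation
        of training and test spectra."""
        X = rng.normal(size=(80, 12))
        T = rng.normal(size=(40, 12)) * 1.5
        Q = ortho_group.rvs(12, random_state=4)
        a = DDSimca(n_components=3).fit(X).predict(T)
        b = DDSimca(n_components=3).fit(X @ Q).predict(T @ Q)
        assert np.array_equal(a, b)

    def test_training_outlier_rate_bounded(self):
        gamma, n = 0.01, 150
        bound = gamma * n + 3 * np.sqrt(gamma * n)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            model = DDSimca(n_components=3, gamma=gamma).fit(rng.normal(size=(n, 15)))
            n_out = int((model.training_distances_["decision"] == "outlier").sum())
            assert n_out <= bound


class TestExtremePlot:
    def test_expected_count_arithmetic(self, gaussian_model):
        model, X = gaussian_model
        table = model.extreme_plot_data(X, levels=[0.05])
        assert table["expected_extremes"][0] == pytest.approx(0.05 * 200)
        assert table["envelope"][0] == pytest.approx(2 * np.sqrt(0.05 * 200 * 0.95))

    def test_consistent_with_training_decisions(self, gaussian_model):
        model, _ = gaussian_model
        table = model.extreme_plot_data(levels=[model.alpha])
        flagged = (model.training_distances_["decision"] != "regular").sum()
        assert table["observed_extremes"][0] == flagged

    def test_well_specified_data_within_envelope(self):
        rng = np.random.default_rng(10)
        model = DDSimca(n_components=4).fit(rng.normal(size=(400, 25)))
        table = model.extreme_plot_data()
        inside = (
            np.abs(table["observed_extremes"] - table["expected_extremes"])
            <= table["envelope"]
        )
        assert inside.mean() >= 0.9


class TestSelectFactors:
    def test_recovers_planted_component_count(self):
        """Recovery works when leaving structure unmodelled visibly breaks
        the chi-square calibration of the training distances; clustered
        (bimodal) component scores provide that."""
        rng = np.random.default_rng(1)
        signs = rng.choice([-1.0, 1.0], size=(150, 3))
        scores = signs * (4.0 + 0.3 * rng.normal(size=(150, 3)))
        basis = np.linalg.qr(rng.normal(size=(40, 3)))[0]
        X = scores @ basis.T + 0.05 * rng.normal(size=(150, 40))
        assert select_factors(X, A_max=8) == 3

    def test_single_candidate(self, rng):
        X = rng.normal(size=(30, 6))
        assert select_factors(X, A_max=1) == 1

    def test_too_many_candidates_rejected(self, rng):
        with pytest.raises(ValueError):
            select_factors(rng.normal(size=(10, 6)), A_max=10)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, rng):
        X = rng.uniform(0.2, 0.8, size=(60, 30))
        model = DDSimca(n_components=2, preprocessor=SpectralPreprocessor("snv")).fit(X)
        model.save(tmp_path / "model.yaml")
        back = DDSimca.load(tmp_path / "model.yaml")
        T = rng.uniform(0.2, 0.8, size=(10, 30))
        a, b = model.distances(T), back.distances(T)
        for col in ("h", "v", "c"):
            assert np.allclose(a[col], b[col])
        assert back.c_crit_ == model.c_crit_
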