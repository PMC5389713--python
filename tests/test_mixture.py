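"""Gene-wise mixture model: inversion, oracle equivalence and contrast algebra."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from mixbench import (
    MixtureModel,
    fit_mixture,
    leave_out_fit,
    rmse_logfc,
)
from mixbench.datatypes import ParameterError
from mixbench.mixture import DesignError
from mixbench.preprocess import NormalizedExpression

from conftest import noise_free_logcpm, random_reference


def simplex_sse(z_row, p, a0, b0):
    """Derivative-free oracle: Nelder-Mead minimum of the per-gene SSE."""

    def sse(theta):
        a, b = theta
        mu = np.log2(p * 2.0**a + (1 - p) * 2.0**b)
        return float(np.sum((z_row - mu) ** 2))

    best = np.inf
    for start in ((a0, b0), (a0 + 0.5, b0 - 0.5)):
        res = minimize(sse, start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000})
        best = min(best, res.fun)
    return best


def make_expr(logcpm: pd.DataFrame) -> NormalizedExpression:
    libs = pd.Series(1e6, index=logcpm.columns)
    f = pd.Series(1.0, index=logcpm.columns)
    return NormalizedExpression(logcpm, f, libs)


class TestFitInversion:
    def test_recovers_known_concentrations_noise_free(self):
        """Forward-generated logCPM from X=64, Y=16 is inverted exactly."""
        lc, p = noise_free_logcpm(np.array([64.0]), np.array([16.0]))
        expected_mu = [6.0, 5.70044, 5.32193, 4.80735, 4.0]
        assert np.allclose(sorted(set(np.round(lc.iloc[0], 5)))[::-1], expected_mu)
        res = MixtureModel(lc, p).fit()
        assert res.Xhat[0] == pytest.approx(64.0, abs=1e-6)
        assert res.Yhat[0] == pytest.approx(16.0, abs=1e-6)
        assert res.M[0] == pytest.approx(2.0, abs=1e-6)
        assert res.phi_hat[0] < 1e-6

    def test_pure_samples_only_give_group_means(self):
        """With only p in {0,1} the SSE decouples: estimates are the
        back-transformed mean logCPM of each pure group."""
        rng = np.random.default_rng(21)
        G = 40
        z_a = rng.normal(7.0, 0.3, size=(G, 3))
        z_b = rng.normal(4.0, 0.3, size=(G, 3))
        lc = pd.DataFrame(np.hstack([z_a, z_b]))
        p = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        res = MixtureModel(lc, p).fit()
        assert np.allclose(res.log2X, z_a.mean(axis=1), atol=1e-7)
        assert np.allclose(res.log2Y, z_b.mean(axis=1), atol=1e-7)

    def test_sse_matches_simplex_oracle_under_noise(self):
        rng = np.random.default_rng(22)
        X, Y = random_reference(rng, 20)
        lc, p = noise_free_logcpm(X, Y)
        lc = lc + rng.normal(0.0, 0.1, size=lc.shape)
        res = MixtureModel(lc, p).fit()
        hi = p == 1.0
        lo = p == 0.0
        for g in range(20):
            a0 = lc.to_numpy()[g, hi].mean()
            b0 = lc.to_numpy()[g, lo].mean()
            oracle = simplex_sse(lc.to_numpy()[g], p, a0, b0)
            assert res.sse[g] <= oracle + 1e-6

    def test_phi_hat_is_rss_over_residual_df(self):
        rng = np.random.default_rng(23)
        X, Y = random_reference(rng, 10)
        lc, p = noise_free_logcpm(X, Y)
        lc = lc + rng.normal(0.0, 0.2, size=lc.shape)
        res = MixtureModel(lc, p).fit()
        assert np.allclose(res.phi_hat**2 * (len(p) - 2), res.sse, rtol=1e-12)

    def test_matches_limma_fitmixture(self, tmp_path):
        """Cross-check against the canonical vectorized implementation."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(24)
        X, Y = random_reference(rng, 25)
        lc, p = noise_free_logcpm(X, Y)
        lc = lc + rng.normal(0.0, 0.15, size=lc.shape)
        lc.to_csv(tmp_path / "lc.tsv", sep="\t", index=False)
        np.savetxt(tmp_path / "p.txt", p)
        script = (
            "suppressMessages(library(limma));"
            f'z <- as.matrix(read.delim("{tmp_path / "lc.tsv"}"));'
            f'p <- scan("{tmp_path / "p.txt"}", quiet=TRUE);'
            "fit <- fitmixture(z, p);"
            'write.table(data.frame(M=fit$M, sd=fit$stdev),'
            f'"{tmp_path / "out.tsv"}", sep="\\t", row.names=FALSE, quote=FALSE)'
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        res = MixtureModel(lc, p).fit()
        assert np.abs(res.M - ref["M"].to_numpy()).max() < 1e-4
        assert np.abs(res.phi_hat - ref["sd"].to_numpy()).max() < 1e-6

    def test_parameter_recovery_under_noise(self):
        """RMS error of the estimated log-ratio stays well under 0.15 at phi=0.1."""
        rng = np.random.default_rng(25)
        X, Y = random_reference(rng, 2000)
        lc, p = noise_free_logcpm(X, Y)
        lc = lc + 0.1 * rng.standard_normal(lc.shape)
        res = MixtureModel(lc, p).fit()
        rms = np.sqrt(np.mean((res.M - np.log2(X / Y)) ** 2))
        assert rms < 0.15

    def test_unidentifiable_designs_rejected(self):
        lc = pd.DataFrame(np.ones((3, 4)))
        with pytest.raises(DesignError):
            MixtureModel(lc, np.array([0.5, 0.5, 0.5, 0.5]))
        with pytest.raises(DesignError):
            MixtureModel(pd.DataFrame(np.ones((3, 2))), np.array([1.0, 0.0]))


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(26)
    X, Y = random_reference(rng, 50)
    lc, p = noise_free_logcpm(X, Y)
    lc = lc + rng.normal(0.0, 0.05, size=lc.shape)
    return MixtureModel(lc, p).fit()


class TestContrastPrediction:

    def test_equal_proportions_give_zero(self, fitted):
        delta = fitted.predicted_logfc(0.5, 0.5).delta
        assert np.allclose(delta.to_numpy(), 0.0, atol=1e-12)

    def test_pure_contrast_equals_M(self, fitted):
        delta = fitted.predicted_logfc(1.0, 0.0).delta
        assert np.allclose(delta.to_numpy(), fitted.M, atol=1e-12)

    def test_hand_computed_value(self):
        lc, p = noise_free_logcpm(np.array([64.0]), np.array([16.0]))
        res = MixtureModel(lc, p).fit()
        delta = res.predicted_logfc(0.75, 0.25).delta
        assert delta.iloc[0] == pytest.approx(np.log2(52 / 28), abs=1e-9)
        assert delta.iloc[0] == pytest.approx(0.8930848, abs=1e-6)

    def test_antisymmetry(self, fitted):
        for p, q in [(1.0, 0.0), (0.75, 0.25), (0.6, 0.3), (0.9, 0.05)]:
            d1 = fitted.predicted_logfc(p, q).delta.to_numpy()
            d2 = fitted.predicted_logfc(q, p).delta.to_numpy()
            assert np.allclose(d1, -d2, atol=1e-12)

    def test_monotone_in_ratio(self):
        """For fixed q < p the predicted log-FC increases with Xhat/Yhat."""
        R = np.linspace(0.05, 20.0, 60)
        X = 100.0 * R
        Y = np.full_like(X, 100.0)
        lc, p = noise_free_logcpm(X, Y)
        res = MixtureModel(lc, p).fit()
        order = np.argsort(res.Xhat / res.Yhat)
        for pp, qq in [(1.0, 0.0), (0.75, 0.25), (0.75, 0.5)]:
            delta = res.predicted_logfc(pp, qq).delta.to_numpy()[order]
            assert np.all(np.diff(delta) > 0)

    def test_out_of_range_proportions_rejected(self, fitted):
        with pytest.raises(ParameterError):
            fitted.predicted_logfc(1.2, 0.0)
        with pytest.raises(ParameterError):
            fitted.predicted_logfc(0.5, -0.1)


class TestRmseLogfc:
    def test_zero_when_identical(self):
        lc, p = noise_free_logcpm(np.array([64.0, 32.0]), np.array([16.0, 32.0]))
        res = MixtureModel(lc, p).fit()
        pred = res.predicted_logfc(0.75, 0.25)
        rmse, excluded = rmse_logfc(pred.delta, pred)
        assert rmse == 0.0 and excluded == 0

    def test_direct_arithmetic(self):
        lc, p = noise_free_logcpm(np.array([64.0, 32.0]), np.array([16.0, 32.0]))
        pred = MixtureModel(lc, p).fit().predicted_logfc(1.0, 0.0)
        est = pd.Series([pred.delta.iloc[0] + 1.0, pred.delta.iloc[1] + 1.0], index=pred.delta.index)
        assert rmse_logfc(est, pred)[0] == pytest.approx(1.0, abs=1e-12)
        est = pd.Series([pred.delta.iloc[0] + 3.0, pred.delta.iloc[1]], index=pred.delta.index)
        assert rmse_logfc(est, pred)[0] == pytest.approx(np.sqrt(4.5), abs=1e-12)

    def test_empty_intersection_rejected(self):
        lc, p = noise_free_logcpm(np.array([64.0]), np.array([16.0]))
        pred = MixtureModel(lc, p).fit().predicted_logfc(1.0, 0.0)
        with pytest.raises(ParameterError):
            rmse_logfc(pd.Series([1.0], index=["other"]), pred)


class TestLeaveOutFit:
    def test_exclusion_count(self, default_design):
        rng = np.random.default_rng(27)
        good = default_design.good_only()
        X, Y = random_reference(rng, 30)
        lc, p = noise_free_logcpm(X, Y)
        lc.columns = good.sample_ids
        expr = make_expr(lc + rng.normal(0, 0.05, lc.shape))
        comparison = (good.group(0.75), good.group(0.5))
        res = leave_out_fit(expr, good, comparison)
        assert len(res.samples_used) == 9
        assert not (set(comparison[0]) | set(comparison[1])) & set(res.samples_used)

    def test_empty_exclusion_equals_full_fit(self, default_design):
        rng = np.random.default_rng(28)
        good = default_design.good_only()
        X, Y = random_reference(rng, 30)
        lc, _ = noise_free_logcpm(X, Y)
        lc.columns = good.sample_ids
        expr = make_expr(lc + rng.normal(0, 0.05, lc.shape))
        full = fit_mixture(expr, good)
        lo = leave_out_fit(expr, good, ((), ()))
        assert np.array_equal(full.M, lo.M)
        assert np.array_equal(full.phi_hat, lo.phi_hat)

    def test_leave_out_predictions_track_full_fit(self, default_design):
        rng = np.random.default_rng(29)
        good = default_design.good_only()
        X, Y = random_reference(rng, 2000)
        lc, _ = noise_free_logcpm(X, Y)
        lc.columns = good.sample_ids
        expr = make_expr(lc + rng.normal(0, 0.05, lc.shape))
        full = fit_mixture(expr, good)
        lo = leave_out_fit(expr, good, (good.group(0.75), good.group(0.25)))
        d_full = full.predicted_logfc(0.75, 0.25).delta
        d_lo = lo.predicted_logfc(0.75, 0.25).delta
        assert d_full.corr(d_lo) > 0.99

    def test_collapsing_exclusion_rejected(self, default_design):
        rng = np.random.default_rng(30)
        good = default_design.good_only()
        X, Y = random_reference(rng, 5)
        lc, _ = noise_free_logcpm(X, Y)
        lc.columns = good.sample_ids
        expr = make_expr(lc)
        groups = [good.group(p) for p in (1.0, 0.75, 0.5, 0.25)]
        with pytest.raises(DesignError):
            leave_out_fit(expr, good, (groups[0] + groups[1], groups[2] + groups[3]))


def test_degraded_substitution_raises_phi(default_design):
    """Replacing replicate-2 columns with degraded twins inflates phi_hat^2."""
    from scipy import stats
    from mixbench import simulate_mixture_counts, simulate_reference_profiles
    from mixbench.preprocess import normalize

    ref = simulate_reference_profiles(2000, 0.2, seed=31, dispersion_mean=0.05)
    counts = simulate_mixture_counts(
        ref, default_design, lib_size_mean=1e6, degradation_dispersion_multiplier=4.0, seed=31
    )
    good = default_design.good_only()
    subst = default_design.substituted(replicate=2)
    fits = {}
    for name, design in (("good", good), ("subst", subst)):
        expr = normalize(counts.subset_samples(design.sample_ids))
        fits[name] = fit_mixture(expr, design)
    shared = sorted(set(fits["good"].gene_ids) & set(fits["subst"].gene_ids))
    pg = pd.Series(fits["good"].phi_hat**2, index=fits["good"].gene_ids).loc[shared]
    ps = pd.Series(fits["subst"].phi_hat**2, index=fits["subst"].gene_ids).loc[shared]
    assert ps.median() > pg.median()
    wins = int((ps > pg).sum())
    n = int((ps != pg).sum())
    assert stats.binomtest(wins, n, alternative="greater").pvalue < 0.01
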