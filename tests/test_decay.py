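import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from mistseq import decay as dec
from mistseq import simulate as sim
from mistseq import sites as st
from mistseq.model import ValidationError


def flat_alpha(value=0.0):
    return lambda t, mu: np.full(len(t), value)


class TestWlsOracle:
    def test_matches_lstsq_on_random_fixtures(self):
        """Slope and covariance agree with an independent QR-based solve."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            n, p = rng.integers(4, 12), rng.integers(2, 4)
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            w = rng.uniform(0.1, 5.0, size=n)
            beta, cov = dec.wls_fit(X, y, w)
            sw = np.sqrt(w)
            ref, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
            assert np.allclose(beta, ref, atol=1e-10)
            ref_cov = np.linalg.inv((X * w[:, None]).T @ X)
            assert np.allclose(cov, ref_cov, atol=1e-10)

    def test_equal_weights_reduce_to_ols(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(8), np.arange(8.0)])
        y = rng.normal(size=8)
        beta_w, _ = dec.wls_fit(X, y, np.full(8, 3.7))
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(beta_w, beta_ols, atol=1e-12)


class TestFitDecay:
    def test_exact_halving_gives_ten_minute_half_life(self):
        fit = dec.fit_decay(
            np.array([0.0, 10.0, 20.0]),
            np.array([[100.0], [50.0], [25.0]]),
            np.ones((3, 1)),
            weighted=False,
        )
        assert fit.k == pytest.approx(np.log(2) / 10, abs=1e-12)
        assert fit.half_life == pytest.approx(10.0, abs=1e-9)
        assert fit.qc == dec.QC_OK

    def test_constant_counts_flagged_nondecaying(self):
        fit = dec.fit_decay(
            np.array([0.0, 5.0, 10.0, 20.0, 40.0]),
            np.full((5, 1), 80.0),
            np.ones((5, 1)),
            weighted=False,
        )
        assert fit.k == pytest.approx(0.0, abs=1e-12)
        assert fit.qc == dec.QC_NONDECAYING
        assert np.isinf(fit.half_life)

    def test_too_few_points_refused(self):
        fit = dec.fit_decay(
            np.array([0.0, 10.0, 20.0]),
            np.array([[100.0], [0.0], [0.0]]),
            np.ones((3, 1)),
            weighted=False,
        )
        assert fit.qc == dec.QC_INSUFFICIENT and np.isnan(fit.k)

    def test_heteroscedastic_fit_matches_manual_normal_equations(self):
        """The weighted fit equals the closed-form WLS solution built by hand."""
        t = np.array([0.0, 5.0, 10.0, 15.0, 40.0])
        raw = np.array([[1000.0], [500.0], [250.0], [125.0], [8.0]])
        s = np.ones((5, 1))
        alpha = 0.05
        fit = dec.fit_decay(
            t, raw, s, alpha_fn=flat_alpha(alpha), weighted=True,
            n_iter=1, bias_correction=False,
        )
        K = raw[:, 0]
        X = np.column_stack([np.ones(5), t])
        y = np.log(K)
        beta0, *_ = np.linalg.lstsq(X, y, rcond=None)  # OLS pilot
        mu = np.exp(X @ beta0)
        w = 1.0 / (1.0 / mu + alpha)
        Xw = X * w[:, None]
        beta = np.linalg.solve(Xw.T @ X, Xw.T @ y)
        se = np.sqrt(np.linalg.inv(Xw.T @ X)[1, 1])
        assert fit.k == pytest.approx(-beta[1], abs=1e-12)
        assert fit.se_k == pytest.approx(se, abs=1e-12)

    def test_zero_dispersion_infinite_depth_recovers_truth(self):
        """Noiseless limit: Poisson at huge depth converges to k_true."""
        rng = np.random.default_rng(2)
        t = np.array([0.0, 5.0, 10.0, 20.0, 40.0])
        for k_true in (0.01, 0.05, 0.15):
            mu = 1e6 * np.exp(-k_true * t)
            raw = rng.poisson(np.repeat(mu[:, None], 2, axis=1)).astype(float)
            fit = dec.fit_decay(t, raw, np.ones((5, 2)), alpha_fn=flat_alpha(0.0))
            assert fit.k == pytest.approx(k_true, rel=0.01)

    def test_delta_method_variance_matches_monte_carlo(self):
        """Var(ln K) ~ 1/mu + alpha validated against NB draws."""
        rng = np.random.default_rng(3)
        mu, alpha = 100.0, 0.05
        draws = sim.nb_draw(rng, np.full(200_000, mu), alpha)
        draws = draws[draws > 0]
        assert np.var(np.log(draws)) == pytest.approx(1 / mu + alpha, rel=0.10)


class TestPairTests:
    def fits_frame(self, rows):
        df = pd.DataFrame(
            rows, columns=["site", "gene_id", "pos", "k", "se_k", "half_life"]
        )
        df["qc"] = dec.QC_OK
        df["coding"] = True
        return df

    def test_equal_rates_give_z_zero_p_one(self):
        fits = self.fits_frame(
            [("s1", "g", 10, 0.05, 0.01, 13.9), ("s2", "g", 20, 0.05, 0.01, 13.9)]
        )
        pairs, _ = dec.test_pairs(fits)
        assert pairs.iloc[0]["z"] == 0.0 and pairs.iloc[0]["p"] == 1.0

    def test_hand_computed_z_and_fourfold_ratio(self):
        # t1/2 of 5 vs 20 min, both SE 0.01
        kA, kB = np.log(2) / 5, np.log(2) / 20
        fits = self.fits_frame(
            [("s1", "g", 10, kA, 0.01, 5.0), ("s2", "g", 11, kB, 0.01, 20.0)]
        )
        pairs, genes = dec.test_pairs(fits)
        z_expected = (kA - kB) / np.sqrt(2 * 0.01**2)
        assert pairs.iloc[0]["z"] == pytest.approx(z_expected)
        assert z_expected == pytest.approx(7.35, abs=0.01)
        assert pairs.iloc[0]["p"] == pytest.approx(2 * norm.sf(z_expected))
        assert pairs.iloc[0]["p"] < 1e-12
        assert genes.iloc[0]["max_fold_ratio"] == pytest.approx(4.0)
        assert pairs.iloc[0]["distance_nt"] == 1

    def test_bh_step_up_hand_example(self):
        """Pairs engineered to p = (.01, .02, .03, .04) all get q = .04."""
        target_p = [0.01, 0.02, 0.03, 0.04]
        rows = []
        for i, p in enumerate(target_p):
            dk = norm.isf(p / 2)  # se_A = se_B = 1/sqrt(2) -> z = delta k
            se = 1 / np.sqrt(2)
            rows += [
                (f"a{i}", f"g{i}", 10, 0.5 + dk, se, 1.0),
                (f"b{i}", f"g{i}", 20, 0.5, se, 1.0),
            ]
        pairs, _ = dec.test_pairs(self.fits_frame(rows))
        assert np.allclose(sorted(pairs["p"]), target_p)
        assert np.allclose(pairs["q"], 0.04)

    def test_degenerate_se_raises(self):
        fits = self.fits_frame(
            [("s1", "g", 10, 0.05, 0.0, 13.9), ("s2", "g", 20, 0.06, 0.01, 11.5)]
        )
        with pytest.raises(ValidationError, match="se_k"):
            dec.test_pairs(fits)


class TestAggregation:
    def fits(self, rows):
        df = pd.DataFrame(rows, columns=["site", "gene_id", "k", "n0"])
        df["qc"] = dec.QC_OK
        return df

    def test_single_isoform_gene_keeps_isoform_rate(self):
        out = dec.aggregate_gene_decay(self.fits([("s1", "g", 0.02, 10.0)]))
        assert out.iloc[0]["k"] == pytest.approx(0.02)

    def test_equal_abundance_mean(self):
        out = dec.aggregate_gene_decay(
            self.fits([("s1", "g", 0.02, 5.0), ("s2", "g", 0.04, 5.0)])
        )
        assert out.iloc[0]["k"] == pytest.approx(0.03)

    def test_weighted_mean_hand_example(self):
        out = dec.aggregate_gene_decay(
            self.fits([("s1", "g", 0.02, 3.0), ("s2", "g", 0.06, 1.0)])
        )
        assert out.iloc[0]["k"] == pytest.approx(0.03)


class TestRelativeRatio:
    def fits(self, ks, qc=dec.QC_OK):
        df = pd.DataFrame(
            {"site": [f"s{i}" for i in range(len(ks))], "k": ks}
        )
        df["qc"] = qc
        return df

    def test_hand_ratio(self):
        out = dec.relative_decay_ratio(self.fits([0.05]), self.fits([0.10]))
        assert out.iloc[0]["ratio"] == pytest.approx(0.5)

    def test_identical_conditions_give_unit_ratios(self):
        f = self.fits([0.05, 0.1, 0.2])
        out = dec.relative_decay_ratio(f, f)
        assert np.allclose(out["ratio"], 1.0)

    def test_nonpositive_wt_rate_flagged_and_excluded(self):
        out = dec.relative_decay_ratio(
            self.fits([0.05]), self.fits([-0.01], qc=dec.QC_NONDECAYING)
        )
        assert not out.iloc[0]["usable"] and np.isnan(out.iloc[0]["ratio"])


class TestReplicateConcordance:
    def fits(self, ks):
        df = pd.DataFrame({"site": [f"s{i}" for i in range(len(ks))], "k": ks})
        df["qc"] = dec.QC_OK
        return df

    def test_identical_fits_give_perfect_correlation(self):
        ks = list(np.linspace(0.01, 0.2, 12))
        out = dec.replicate_concordance(self.fits(ks), self.fits(ks))
        assert out["spearman"] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        ks = list(np.linspace(0.01, 0.2, 12))
        out = dec.replicate_concordance(self.fits(ks), self.fits(ks[::-1]))
        assert out["spearman"] == pytest.approx(-1.0)

    def test_too_few_shared_sites_refused(self):
        with pytest.raises(ValidationError, match="at least 10"):
            dec.replicate_concordance(self.fits([0.1] * 3), self.fits([0.1] * 3))

    def test_synthetic_run_concordance_above_point_eight(self, world, decay_run, config):
        table = decay_run[0]
        clean, factors, disp, _ = st.clean_and_normalize(table, world.genome, config)
        f1 = dec.fit_all(clean, factors, disp, config, "WT", replicate="R1")
        f2 = dec.fit_all(clean, factors, disp, config, "WT", replicate="R2")
        out = dec.replicate_concordance(f1, f2)
        assert out["spearman"] >= 0.8
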