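import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from thmix import analysis as A
from thmix import generate as G
from thmix import two_stage as T


class TestTransforms:
    def test_asinh_zero(self):
        assert A.transform_channel([0.0])[0] == 0.0

    def test_asinh_log_asymptote(self):
        # oracle: asinh(z) -> ln(2z) for z >> 1
        c = 5.0
        x = np.array([1e3, 1e4, 1e5])
        got = A.transform_channel(x, cofactor=c)
        want = np.log(2 * x / c)
        assert np.allclose(got, want, rtol=0.01)

    def test_monotone(self):
        x = np.sort(np.random.default_rng(0).uniform(-50, 5000, 300))
        for method in ("asinh", "logicle"):
            y = A.transform_channel(x, method=method)
            assert (np.diff(y) > 0).all()

    def test_logicle_linear_near_zero_log_far(self):
        y = A.transform_channel(np.array([-10.0, 0.0, 10.0]), method="logicle")
        # zero sits at the linearization width; response is locally linear,
        # i.e. symmetric for small +-v around that point
        zero = y[1]
        assert y[2] - zero == pytest.approx(zero - y[0], rel=1e-3)
        # logarithmic far out: equal display spacing per decade
        big = A.transform_channel(np.array([1e3, 1e4, 1e5]), method="logicle")
        d = np.diff(big)
        assert d[0] == pytest.approx(d[1], rel=0.05)

    def test_bad_cofactor(self):
        with pytest.raises(ValueError):
            A.transform_channel([1.0], cofactor=0.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            A.transform_channel([np.nan])


class TestNormalization:
    def test_identity_with_isotype_gives_median_one(self):
        rng = np.random.default_rng(1)
        iso = rng.lognormal(4.6, 0.4, 10000)
        nc = A.normalize_to_isotype(iso, iso)
        assert np.median(nc.values) == pytest.approx(1.0, abs=1e-9)

    def test_p95_is_ten(self):
        rng = np.random.default_rng(2)
        v = rng.lognormal(5.5, 0.5, 5000)
        iso = rng.lognormal(4.6, 0.4, 5000)
        nc = A.normalize_to_isotype(v, iso)
        assert np.quantile(nc.values, 0.95) == pytest.approx(10.0, abs=1e-9)

    def test_global_rescale_invariance(self):
        rng = np.random.default_rng(3)
        v = rng.lognormal(5.5, 0.5, 2000)
        iso = rng.lognormal(4.6, 0.4, 2000)
        a = A.normalize_to_isotype(v, iso).values
        b = A.normalize_to_isotype(17.3 * v, 17.3 * iso).values
        assert np.allclose(a, b, rtol=1e-12)

    def test_order_preserved(self):
        rng = np.random.default_rng(4)
        v = rng.lognormal(5.0, 0.5, 1000)
        nc = A.normalize_to_isotype(v, v)
        assert (np.argsort(nc.values) == np.argsort(v)).all()

    def test_degenerate_isotype(self):
        with pytest.raises(ValueError):
            A.normalize_to_isotype(np.zeros(10), np.zeros(10))

    def test_empty_isotype(self):
        with pytest.raises(ValueError):
            A.normalize_to_isotype(np.ones(10), np.array([]))


class TestAlpha:
    def test_diagonal_is_45(self):
        v = np.array([2.0, 5.0, 9.0])
        for variant in ("log", "linear"):
            res = A.alpha_angle(v, v, variant=variant)
            assert np.allclose(res.values, 45.0)

    def test_th1_mode_near_90(self, th1_sample, iso_sample):
        xn = A.normalize_to_isotype(th1_sample.cells["tbet"], iso_sample.cells["tbet"])
        yn = A.normalize_to_isotype(th1_sample.cells["gata3"], iso_sample.cells["gata3"])
        assert A.alpha_mode(A.alpha_angle(xn, yn).values) == pytest.approx(90.0, abs=3)

    def test_th2_mode_near_0(self, th2_sample, iso_sample):
        xn = A.normalize_to_isotype(th2_sample.cells["tbet"], iso_sample.cells["tbet"])
        yn = A.normalize_to_isotype(th2_sample.cells["gata3"], iso_sample.cells["gata3"])
        assert A.alpha_mode(A.alpha_angle(xn, yn).values) == pytest.approx(0.0, abs=3)

    def test_mixed_intermediate(self, mixed_sample, iso_sample):
        xn = A.normalize_to_isotype(mixed_sample.cells["tbet"], iso_sample.cells["tbet"])
        yn = A.normalize_to_isotype(mixed_sample.cells["gata3"], iso_sample.cells["gata3"])
        med = np.median(A.alpha_angle(xn, yn).values)
        assert 30 < med < 60

    def test_linear_variant_per_cell_factor_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.lognormal(1.0, 0.5, 500)
        y = rng.lognormal(0.5, 0.5, 500)
        c = rng.lognormal(0.0, 0.7, 500)
        a = A.alpha_angle(x, y, variant="linear").values
        b = A.alpha_angle(c * x, c * y, variant="linear").values
        assert np.allclose(a, b, rtol=1e-12)

    def test_range_and_exclusions(self):
        res = A.alpha_angle(np.array([0.5, 2.0]), np.array([0.5, 3.0]))
        assert res.n_excluded == 1  # both at floor -> excluded
        assert ((res.values >= 0) & (res.values <= 90)).all()


class TestMfiMatrix:
    def test_constant_sample(self, config):
        ds = G.generate_matrix_dataset(config, [0.0], [0.0], 10, 1)
        for s in ds.samples.values():
            s.cells["tbet"] = 123.0
        m = A.mfi_matrix(ds, "tbet")
        assert float(m.iloc[0, 0]) == 123.0

    def test_median_outlier_robustness(self, th1_sample):
        # oracle: replacing the top fraction eps moves the median to the
        # 0.5/(1-eps) quantile of the clean distribution
        v = th1_sample.cells["tbet"].to_numpy().copy()
        eps = 0.10
        rng = np.random.default_rng(0)
        idx = rng.choice(v.size, int(eps * v.size), replace=False)
        base = np.median(v)
        vq = v.copy()
        vq[idx] = 1e9
        shifted = np.median(vq)
        oracle_bound = np.quantile(v, 0.5 / (1 - eps)) / base - 1
        assert shifted / base - 1 <= oracle_bound + 0.01
        # and the mean is far less robust
        assert abs(np.mean(vq) / np.mean(v) - 1) > 10 * (shifted / base - 1)
        # on a tight channel the median shift is < 1%
        tight = 100.0 * np.exp(0.02 * rng.standard_normal(20000))
        tq = tight.copy()
        tq[idx] = 1e9
        assert abs(np.median(tq) / np.median(tight) - 1) < 0.01

    def test_monotone_in_il12(self, small_dataset):
        m = A.mfi_matrix(small_dataset, "tbet")
        for col in m.columns:
            assert (np.diff(m[col].to_numpy()) > -1e-9).all()

    def test_empty_sample_flagged(self, config):
        ds = G.generate_matrix_dataset(config, [0.0], [0.0], 0, 2)
        with pytest.warns(UserWarning, match="empty"):
            m = A.mfi_matrix(ds, "tbet")
        assert np.isnan(m.iloc[0, 0])


class TestDecomposeSeparable:
    def test_exact_separable(self):
        f1 = np.array([3.0, 7.0, 1.5, 0.8])
        f2 = np.array([1.0, 0.4, 9.0])
        M = np.outer(f1, f2) + 50.0
        g1, g2, resid = A.decompose_separable(pd.DataFrame(M), 50.0)
        assert resid < 1e-12
        assert np.allclose(g2, f2 / f2[0], rtol=1e-9)
        assert np.allclose(g1, f1 * f2[0], rtol=1e-9)

    def test_constant_matrix(self):
        M = pd.DataFrame(np.full((3, 4), 5.0))
        f1, f2, resid = A.decompose_separable(M, 0.0)
        assert resid == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(f2, 1.0)
        assert np.allclose(f1, 5.0)

    def test_rank_two_large_residual(self):
        # two equal-weight separable terms with opposed gradients
        a = np.array([1.0, 3.0, 10.0])
        b = np.array([1.0, 4.0, 10.0, 20.0])
        M = np.outer(a, b) + np.outer(a[::-1], b[::-1])
        _, _, resid = A.decompose_separable(pd.DataFrame(M), 0.0)
        assert resid > 0.05

    def test_nonpositive_entry_named(self):
        M = pd.DataFrame([[10.0, 20.0], [30.0, 4.0]])
        with pytest.raises(ValueError, match="row 1, column 1"):
            A.decompose_separable(M, 5.0)

    def test_recovery_from_generator_output(self, config):
        # log-factor correlation > 0.999 against the configured responses
        grid12 = np.array([10.0, 30.0, 90.0, 270.0, 540.0])
        grid4 = np.array([0.0, 4.0, 40.0, 540.0])
        ds = G.generate_matrix_dataset(config, grid12, grid4, 20000, 42)
        m = A.mfi_matrix(ds, "tbet")
        f1, f2, resid = A.decompose_separable(m, config.backgrounds["tbet"])
        want1 = config.responses["tbet"].f1(grid12)
        want2 = config.responses["tbet"].f2(grid4)
        assert resid < 0.01
        assert np.corrcoef(np.log(f1), np.log(want1))[0, 1] > 0.999
        assert np.corrcoef(np.log(f2), np.log(want2))[0, 1] > 0.999


class TestNoiseProfile:
    def test_zero_variance(self, config):
        ds = G.generate_matrix_dataset(config, [0.0], [0.0], 10, 1)
        for s in ds.samples.values():
            s.cells["tbet"] = 42.0
        prof = A.noise_profile(ds, "tbet")
        assert prof["cv"].iloc[0] == 0.0

    def test_lognormal_closed_form(self, config):
        # oracle: CV of lognormal(sigma) = sqrt(exp(sigma^2) - 1)
        sigma = config.sigma_total
        ds = G.generate_matrix_dataset(config, [540.0], [0.0], 20000, 3)
        prof = A.noise_profile(ds, "tbet")
        want = np.sqrt(np.exp(sigma ** 2) - 1)
        se = want / np.sqrt(2 * 20000) * 3  # crude 3-SE band
        assert abs(prof["cv"].iloc[0] - want) < max(3 * se, 0.02)


class TestBiasCurve:
    def test_bin_size_exceeds_sample(self, th1_sample):
        with pytest.raises(ValueError):
            A.bin_bias_curve(th1_sample.cells.head(100), "tbet", "ifng",
                             bin_size=500, threshold=100.0)

    def test_flat_when_probability_constant(self):
        rng = np.random.default_rng(0)
        n = 20000
        cells = pd.DataFrame({"tbet": rng.lognormal(5, 0.4, n)})
        pos = rng.random(n) < 0.3
        c = A.bin_bias_curve(cells, "tbet", "ifng", positive=pos)
        se = np.sqrt(0.3 * 0.7 / 500)
        assert (np.abs(c.positive_fraction - 0.3) < 4 * se).all()

    def test_th1_curve_reproduces_printed_fractions(self, th1_sample, thresholds):
        c = A.bin_bias_curve(th1_sample, "tbet", "ifng",
                             threshold=thresholds["ifng"])
        assert c.population_fraction == pytest.approx(0.60, abs=0.03)
        assert c.positive_fraction[-1] == pytest.approx(0.85, abs=0.05)
        assert c.bin_size == 500
        assert len(c.bin_mean_tf) == 40

    def test_monotone_after_smoothing(self, th2_sample):
        c = A.bin_bias_curve(th2_sample, "gata3", "il4",
                             positive=th2_sample.states["il4_on"].astype(bool).to_numpy())
        # isotonic comparison: cumulative means must increase
        from sklearn.isotonic import IsotonicRegression
        iso = IsotonicRegression().fit_transform(c.bin_mean_tf, c.positive_fraction)
        assert np.corrcoef(iso, c.positive_fraction)[0, 1] > 0.9
        assert iso[-1] > iso[0]

    def test_short_bin_flagged(self):
        cells = pd.DataFrame({"tbet": np.arange(1, 1202, dtype=float)})
        pos = np.zeros(1201, dtype=bool)
        c = A.bin_bias_curve(cells, "tbet", "ifng", positive=pos)
        assert c.short_bin_dropped
        assert len(c.positive_fraction) == 2

    def test_logistic_recovery_from_pooled_conditions(self, config):
        # configured midpoint recovered within 10%; floors/ceilings within
        # 10% or 0.01 absolute (finite floor observability; see ledger)
        samples = [G.generate_sample(c, config, 17000, 200 + i)
                   for i, c in enumerate((G.TH1, G.MIXED, G.TH2))]
        cells = pd.concat([s.cells for s in samples], ignore_index=True)
        states = pd.concat([s.states for s in samples], ignore_index=True)
        for cyt, tf in (("ifng", "tbet"), ("il4", "gata3")):
            curve = A.bin_bias_curve(cells, tf, cyt,
                                     positive=states[f"{cyt}_on"].astype(bool).to_numpy())
            pmin, pmax, mid, slope = A.fit_bias_curve(curve)
            true = config.biases[cyt]
            assert mid == pytest.approx(true.midpoint, rel=0.10)
            assert abs(pmin - true.p_min) < max(0.1 * true.p_min, 0.01)
            assert abs(pmax - true.p_max) < max(0.1 * true.p_max, 0.01)


class TestMutualInformation:
    def test_identical_fair_coins_one_bit(self):
        a = np.array([0, 1] * 50, dtype=bool)
        assert A.mutual_information_binary(a, a) == pytest.approx(1.0)

    def test_exact_independence_zero(self):
        a = np.repeat([0, 0, 1, 1], 25).astype(bool)
        b = np.tile([0, 1], 50).astype(bool)
        assert A.mutual_information_binary(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_independent_coins_below_5mbits(self):
        rng = np.random.default_rng(8)
        a = rng.random(100_000) < 0.4
        b = rng.random(100_000) < 0.25
        assert A.mutual_information_binary(a, b) < 0.005

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            A.mutual_information_binary([0, 1], [0])

    @given(st.integers(1, 200), st.integers(0, 200), st.integers(0, 200),
           st.integers(1, 200))
    @settings(max_examples=50, deadline=None)
    def test_nonnegative_and_symmetric(self, n00, n01, n10, n11):
        a = np.repeat([0, 0, 1, 1], [n00, n01, n10, n11]).astype(bool)
        b = np.repeat([0, 1, 0, 1], [n00, n01, n10, n11]).astype(bool)
        mi_ab = A.mutual_information_binary(a, b)
        mi_ba = A.mutual_information_binary(b, a)
        assert mi_ab >= 0.0
        assert mi_ab == pytest.approx(mi_ba, abs=1e-12)


class TestBicModality:
    def test_single_gaussian(self):
        rng = np.random.default_rng(1)
        counts = sum(A.bic_modality(np.exp(0.3 * rng.standard_normal(5000)) * 100,
                                    seed=s) == 1 for s in range(20))
        assert counts >= 19

    def test_two_well_separated_gaussians(self):
        rng = np.random.default_rng(2)
        v = np.concatenate([rng.normal(0, 1, 2500), rng.normal(6, 1, 2500)])
        assert A.bic_modality(v, transform=False, seed=0) == 2

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            A.bic_modality(np.ones(10))


class TestQuadrants:
    def test_all_below_thresholds(self):
        cells = pd.DataFrame({"ifng": np.full(100, 1.0),
                              "il4": np.full(100, 1.0)})
        with pytest.warns(UserWarning):
            qt = A.quadrant_fractions(cells, {"ifng": 50.0, "il4": 50.0})
        assert qt.counts["-/-"] == 100
        assert sum(qt.counts.values()) == qt.n == 100

    def test_counts_sum(self, mixed_sample, thresholds):
        qt = A.quadrant_fractions(mixed_sample, thresholds)
        assert sum(qt.counts.values()) == len(mixed_sample)

    def test_independence_product_rule_true_states(self, mixed_sample):
        # the coins themselves are exactly independent: 3-SE binomial band
        states = mixed_sample.states.rename(
            columns={"ifng_on": "ifng", "il4_on": "il4"}).astype(float)
        qt = A.quadrant_fractions(states, {"ifng": 0.5, "il4": 0.5})
        f = qt.fractions
        want = (f["+/-"] + f["+/+"]) * (f["-/+"] + f["+/+"])
        se = np.sqrt(max(want * (1 - want), 1e-9) / qt.n)
        assert abs(f["+/+"] - want) < 3 * se

    def test_independence_product_rule_measured(self, mixed_sample, thresholds):
        # thresholded readout shares the extrinsic size factor across
        # channels, so allow a small absolute excess on top of 3 SE
        qt = A.quadrant_fractions(mixed_sample, thresholds)
        f = qt.fractions
        want = (f["+/-"] + f["+/+"]) * (f["-/+"] + f["+/+"])
        se = np.sqrt(max(want * (1 - want), 1e-9) / qt.n)
        assert abs(f["+/+"] - want) < 3 * se + 0.01

    def test_th1_dominant_quadrant(self, th1_sample, thresholds):
        qt = A.quadrant_fractions(th1_sample, thresholds)
        pos = {k: v for k, v in qt.counts.items() if k != "-/-"}
        assert max(pos, key=pos.get) == "+/-"


class TestRatioStatistic:
    def test_identical_channels_give_one(self, iso_sample):
        cells = pd.DataFrame({"tbet": iso_sample.cells["tbet"],
                              "gata3": iso_sample.cells["tbet"]})
        iso = pd.DataFrame({"tbet": iso_sample.cells["gata3"],
                            "gata3": iso_sample.cells["gata3"]})
        assert A.ratio_statistic(cells, iso) == pytest.approx(1.0, abs=1e-9)

    def test_per_cell_shared_factor_invariance(self, mixed_sample, iso_sample):
        base = A.ratio_statistic(mixed_sample, iso_sample)
        rng = np.random.default_rng(0)
        c = rng.lognormal(0, 0.8, len(mixed_sample))
        jig = mixed_sample.cells.copy()
        jig["tbet"] *= c
        jig["gata3"] *= c
        assert A.ratio_statistic(jig, iso_sample.cells) == pytest.approx(base, rel=1e-12)

    def test_printed_values(self, th1_sample, mixed_sample, th2_sample, iso_sample):
        assert A.ratio_statistic(th1_sample, iso_sample) == pytest.approx(0.4, abs=0.05)
        assert A.ratio_statistic(mixed_sample, iso_sample) == pytest.approx(1.0, abs=0.1)
        assert A.ratio_statistic(th2_sample, iso_sample) == pytest.approx(20.0, rel=0.1)
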