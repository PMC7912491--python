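"""F_ST track, LOWESS smoothing, outlier calling, logistic ROH scan."""

import numpy as np
import pandas as pd
import pytest

from buffroh import GenotypeError, call_outliers, fst_per_snp, logistic_by_type, lowess_smooth
from buffroh.differentiation import _lowess_1d
from conftest import make_matrix, oracle_lowess


def _panel_from_freqs(p_river, p_swamp, n_per_type=50, seed=0):
    """Deterministic panel whose group allele frequencies are exact."""
    m = len(p_river)
    calls = np.zeros((2 * n_per_type, m), dtype=np.int8)
    for j, (pr, ps) in enumerate(zip(p_river, p_swamp)):
        # allele counts exactly 2*n*p per group, arranged as dosages
        for base, p in ((0, pr), (n_per_type, ps)):
            n_alt = round(2 * n_per_type * p)
            calls[base : base + n_alt // 2, j] = 2
            if n_alt % 2:
                calls[base + n_alt // 2, j] = 1
    return make_matrix(
        calls,
        positions=list(range(100_000, 100_000 * (m + 1), 100_000)),
        types=["river"] * n_per_type + ["swamp"] * n_per_type,
    )


class TestFst:
    def test_stated_estimator_values(self):
        gm = _panel_from_freqs([0.3, 0.0, 0.2], [0.3, 1.0, 0.8])
        fst = fst_per_snp(gm)["fst"].to_numpy()
        assert fst[0] == pytest.approx(0.0, abs=1e-12)   # equal frequencies
        assert fst[1] == pytest.approx(1.0, abs=1e-12)   # fixed difference
        assert fst[2] == pytest.approx(0.36, abs=1e-12)  # (0.5-0.32)/0.5

    def test_label_swap_invariance(self):
        gm = _panel_from_freqs([0.1, 0.4], [0.7, 0.2])
        swapped = make_matrix(
            gm.calls,
            positions=gm.snps["position_bp"].tolist(),
            types=["swamp"] * 50 + ["river"] * 50,
        )
        np.testing.assert_allclose(
            fst_per_snp(gm)["fst"], fst_per_snp(swapped)["fst"], atol=1e-12
        )

    def test_three_groups_rejected(self):
        gm = _panel_from_freqs([0.2], [0.5])
        gm.samples.loc[0, "buffalo_type"] = "river"
        gm.samples["buffalo_type"] = ["river"] * 30 + ["swamp"] * 40 + ["river"] * 30
        gm.samples["population"] = ["a"] * 30 + ["b"] * 40 + ["c"] * 30
        with pytest.raises(GenotypeError):
            fst_per_snp(gm, group_col="population")

    def test_weir_cockerham_alternative_runs(self):
        gm = _panel_from_freqs([0.1, 0.4], [0.7, 0.2])
        wc = fst_per_snp(gm, estimator="weir_cockerham")["fst"].to_numpy()
        assert ((wc >= -0.1) & (wc <= 1.0)).all()


def _track(y, positions=None, chrom=1):
    positions = positions or list(range(1, len(y) + 1))
    return pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(len(y))],
            "chromosome": chrom,
            "position_bp": positions,
            "fst": y,
        }
    )


class TestLowess:
    def test_constant_track_unchanged(self):
        out = lowess_smooth(_track([0.25] * 40), span=0.3)
        np.testing.assert_allclose(out["fst_smoothed"], 0.25, atol=1e-12)

    def test_exact_on_linear_track_with_full_span(self):
        x = np.arange(30) * 100_000
        y = 0.1 + 3e-7 * x
        out = lowess_smooth(_track(list(y), positions=list(x)), span=1.0)
        np.testing.assert_allclose(out["fst_smoothed"], y, atol=1e-8)

    def test_noisy_track_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(6)
        x = np.sort(rng.choice(np.arange(1, 10_000_000), 150, replace=False)).astype(float)
        y = 0.2 + 0.1 * np.sin(x / 5e5) + rng.normal(0, 0.03, 150)
        mine = _lowess_1d(x, y, 0.1, 3)
        orc = oracle_lowess(x, y, 0.1, 3)
        np.testing.assert_allclose(mine, orc, atol=1e-8)

    def test_close_to_statsmodels_reference(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        x = np.sort(rng.uniform(0, 1e6, 300))
        y = 0.2 + 0.15 * np.sin(x / 2e5) + rng.normal(0, 0.02, 300)
        mine = _lowess_1d(x, y, 0.2, 3)
        ref = sm.nonparametric.lowess(y, x, frac=0.2, it=3, return_sorted=False)
        assert np.abs(mine - ref).mean() < 0.01

    def test_tiny_chromosome_passthrough(self):
        out = lowess_smooth(_track([0.1, 0.9]), span=0.5)
        np.testing.assert_allclose(out["fst_smoothed"], [0.1, 0.9])


class TestOutliers:
    def test_flat_track_has_no_outliers(self):
        out = call_outliers(_track([0.2] * 20).rename(columns={"fst": "fst_smoothed"}))
        assert not out["fst_outlier"].any()

    def test_single_spike_flagged(self):
        y = [0.1] * 50 + [0.9]
        track = _track(y).rename(columns={"fst": "fst_smoothed"})
        out = call_outliers(track)
        assert out["fst_outlier"].sum() == 1
        assert out.loc[out["fst_outlier"], "snp_id"].iloc[0] == "s50"

    def test_threshold_matches_direct_arithmetic(self):
        rng = np.random.default_rng(30)
        y = rng.uniform(0, 0.6, 200)
        out = call_outliers(_track(list(y)).rename(columns={"fst": "fst_smoothed"}))
        thr = y.mean() + 3 * y.std(ddof=1)
        assert out["fst_threshold"].iloc[0] == pytest.approx(thr)
        np.testing.assert_array_equal(out["fst_outlier"].to_numpy(), y > thr)


class TestLogistic:
    @staticmethod
    def _inputs(member_river, member_swamp, n_river=100, n_swamp=100):
        member = np.zeros((n_river + n_swamp, 1), dtype=bool)
        member[:member_river, 0] = True
        member[n_river : n_river + member_swamp, 0] = True
        samples = pd.DataFrame(
            {
                "sample_id": [f"i{k}" for k in range(n_river + n_swamp)],
                "buffalo_type": ["river"] * n_river + ["swamp"] * n_swamp,
                "population": ["R"] * n_river + ["S"] * n_swamp,
            }
        )
        snps = pd.DataFrame({"snp_id": ["s0"], "chromosome": [1], "position_bp": [1]})
        return member, samples, snps

    def test_contingency_oracle_case(self):
        member, samples, snps = self._inputs(10, 25)
        res = logistic_by_type(member, samples, snps)
        assert res.loc[0, "odds_ratio"] == pytest.approx(3.0, abs=1e-9)
        assert not res.loc[0, "separated"]

    def test_equal_proportions_give_unit_odds(self):
        member, samples, snps = self._inputs(20, 20)
        res = logistic_by_type(member, samples, snps)
        assert res.loc[0, "beta_type"] == pytest.approx(0.0, abs=1e-9)
        assert res.loc[0, "odds_ratio"] == pytest.approx(1.0, abs=1e-9)

    def test_complete_separation_flagged(self):
        member, samples, snps = self._inputs(10, 100)
        res = logistic_by_type(member, samples, snps)
        assert bool(res.loc[0, "separated"])
        assert np.isinf(res.loc[0, "odds_ratio"])
        assert np.isnan(res.loc[0, "p_value"])

    def test_one_type_absent_rejected(self):
        member, samples, snps = self._inputs(10, 25)
        samples["buffalo_type"] = "river"
        with pytest.raises(GenotypeError):
            logistic_by_type(member, samples, snps)

    def test_cross_product_identity_on_random_tables(self):
        rng = np.random.default_rng(14)
        n = 120
        member = rng.random((2 * n, 60)) < rng.uniform(0.05, 0.9, 60)
        samples = pd.DataFrame(
            {
                "sample_id": [f"i{k}" for k in range(2 * n)],
                "buffalo_type": ["river"] * n + ["swamp"] * n,
                "population": ["R"] * n + ["S"] * n,
            }
        )
        snps = pd.DataFrame(
            {"snp_id": [f"s{j}" for j in range(60)], "chromosome": 1,
             "position_bp": np.arange(60) + 1}
        )
        res = logistic_by_type(member, samples, snps)
        r1 = member[:n].sum(0)
        s1 = member[n:].sum(0)
        cpr = (s1 * (n - r1)) / ((n - s1) * r1)
        ok = ~res["separated"].to_numpy()
        np.testing.assert_allclose(res["odds_ratio"].to_numpy()[ok], cpr[ok], rtol=1e-6)

    def test_wald_p_matches_statsmodels(self):
        import statsmodels.api as sm

        member, samples, snps = self._inputs(18, 33)
        res = logistic_by_type(member, samples, snps)
        X = sm.add_constant((samples["buffalo_type"] == "swamp").astype(float))
        fit = sm.Logit(member[:, 0].astype(float), X).fit(disp=0)
        assert res.loc[0, "beta_type"] == pytest.approx(fit.params.iloc[1], abs=1e-6)
        assert res.loc[0, "p_value"] == pytest.approx(fit.pvalues.iloc[1], abs=1e-6)
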