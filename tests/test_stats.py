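"""Contingency tables, class summaries, t-tests and scatter exports.

The t-test oracle integrates the Student t density numerically (mpmath-free
quadrature via scipy.integrate.quad on the explicit gamma-function form).
"""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.special import gammaln

from cristamorph.stats import (class_summary, contingency, scatter_export,
                               unpaired_t)

# published dataset distribution: 68 cardiomyocyte mitochondria by crista
# morphology (rows) and cell location (Interfib, Subsarc, Other), plus the
# per-morphology counts of locally swollen profiles
TABLE1 = {
    "Lam": (21, 1, 5, 0),
    "Mix": (7, 4, 8, 1),
    "Trans": (1, 0, 8, 3),
    "Tub": (1, 4, 8, 2),
}


def records_from_table1() -> pd.DataFrame:
    rows = []
    for morph, (ifib, ss, other, swollen) in TABLE1.items():
        counts = {"Interfib": ifib, "Subsarc": ss, "Other": other}
        k = 0
        for loc, n in counts.items():
            for _ in range(n):
                rows.append({"id": f"{morph}-{loc}-{k}", "morphology": morph,
                             "location": loc, "swollen": k < 0})
                k += 1
        # mark the first `swollen` records of the morphology
        for i in range(swollen):
            rows[-(k - i)]["swollen"] = True
    df = pd.DataFrame(rows)
    return df


def t_pvalue_oracle(t: float, df: float) -> float:
    """Two-tailed p by direct numerical integration of the t density."""
    lognorm = gammaln((df + 1) / 2) - gammaln(df / 2) \
        - 0.5 * np.log(df * np.pi)

    def pdf(x):
        return np.exp(lognorm - (df + 1) / 2 * np.log1p(x * x / df))

    tail, _err = quad(pdf, abs(t), np.inf)
    return 2 * tail


class TestContingency:
    def test_published_distribution_reconstructs(self):
        table = contingency(records_from_table1())
        assert table.grand_total == 68
        assert table.counts.loc["Lam", "Interfib"] == 21
        assert table.counts.loc["Tub", "Subsarc"] == 4
        assert list(table.row_totals[["Lam", "Mix", "Trans", "Tub"]]) \
            == [27, 19, 9, 13]
        assert list(table.col_totals[["Interfib", "Subsarc", "Other"]]) \
            == [30, 9, 29]
        assert int(table.swollen.sum()) == 6

    def test_cell_sums_conserve_record_count_under_shuffle(self, rng):
        df = records_from_table1()
        shuffled = df.sample(frac=1.0, random_state=7)
        a = contingency(df)
        b = contingency(shuffled)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        assert a.grand_total == len(df)

    def test_empty_and_unclassified(self):
        empty = pd.DataFrame({"morphology": [], "location": []})
        assert contingency(empty).grand_total == 0
        bad = pd.DataFrame({"id": ["x"], "morphology": ["Lam"],
                            "location": ["nowhere"]})
        with pytest.raises(ValueError, match="unclassified"):
            contingency(bad)


class TestClassSummary:
    def test_mean_sd_n(self):
        df = pd.DataFrame({"morphology": ["Lam"] * 3 + ["Tub"],
                           "A_MIT_um2": [1.0, 2.0, 3.0, 5.0]})
        out = class_summary(df, "A_MIT_um2")
        lam = out[out["morphology"] == "Lam"].iloc[0]
        assert lam["mean"] == pytest.approx(2.0)
        assert lam["sd"] == pytest.approx(1.0)
        assert lam["n"] == 3
        tub = out[out["morphology"] == "Tub"].iloc[0]
        assert np.isnan(tub["sd"])       # single observation: SD undefined

    def test_unknown_metric_lists_valid(self):
        df = pd.DataFrame({"morphology": ["Lam"], "AR": [1.0]})
        with pytest.raises(ValueError, match="available"):
            class_summary(df, "bogus")

    def test_recovers_simulated_class_means(self, rng):
        # seeded normal draws around the published class means of the
        # cross-section area (0.70 and 1.08 um^2), n=30, sd=0.1: the sample
        # means must land within 2 standard errors
        n, sd = 30, 0.1
        df = pd.DataFrame({
            "morphology": ["Lam"] * n + ["Tub"] * n,
            "A_MIT_um2": np.concatenate([rng.normal(0.70, sd, n),
                                         rng.normal(1.08, sd, n)]),
        })
        out = class_summary(df, "A_MIT_um2").set_index("morphology")
        se = sd / np.sqrt(n)
        assert abs(out.loc["Lam", "mean"] - 0.70) < 2 * se
        assert abs(out.loc["Tub", "mean"] - 1.08) < 2 * se


class TestUnpairedT:
    def test_identical_groups_t0_p1(self):
        res = unpaired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_pooled_matches_numerical_integration_oracle(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [2.0, 3.0, 4.0, 5.0, 6.0]
        res = unpaired_t(a, b, "pooled")
        # closed form: pooled variance 2.5, t = -1, df = 8
        assert res.t == pytest.approx(-1.0)
        assert res.df == 8
        assert res.p == pytest.approx(t_pvalue_oracle(res.t, res.df),
                                      abs=1e-6)

    def test_symmetry_under_group_swap(self, rng):
        a = rng.normal(0.0, 1.0, 12)
        b = rng.normal(0.4, 1.3, 9)
        r1 = unpaired_t(a, b, "welch")
        r2 = unpaired_t(b, a, "welch")
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_degenerate_conventions(self):
        res = unpaired_t([2.0, 2.0], [2.0, 2.0])
        assert (res.t, res.p) == (0.0, 1.0)
        res = unpaired_t([2.0, 2.0], [3.0, 3.0])
        assert res.p == 0.0 and np.isinf(res.t)
        with pytest.raises(ValueError, match="at least 2"):
            unpaired_t([1.0], [1.0, 2.0])

    def test_null_type_one_error_calibrated(self):
        # 2,000 null pairs (n=10 each): fraction with p < 0.05 should sit
        # in [0.035, 0.065]
        rng = np.random.default_rng(2024)
        reps, n = 2000, 10
        a = rng.standard_normal((reps, n))
        b = rng.standard_normal((reps, n))
        va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
        sp = np.sqrt(((n - 1) * va + (n - 1) * vb) / (2 * n - 2))
        t = (a.mean(axis=1) - b.mean(axis=1)) / (sp * np.sqrt(2 / n))
        from scipy import stats as sps
        p = 2 * sps.t.sf(np.abs(t), 2 * n - 2)
        frac = float(np.mean(p < 0.05))
        assert 0.035 <= frac <= 0.065
        # spot-check the vectorised nulls against unpaired_t
        res = unpaired_t(a[0], b[0])
        assert res.t == pytest.approx(t[0])
        assert res.p == pytest.approx(p[0])


class TestScatterExport:
    def _records(self):
        return pd.DataFrame({
            "id": ["a", "b", "c"], "morphology": ["Lam", "Tub", "Lam"],
            "location": ["Interfib", "Other", "Other"],
            "A_MIT_um2": [0.5, 1.0, 0.8], "AR": [2.0, 1.2, 1.5]})

    def test_long_format_no_aggregation(self):
        out = scatter_export(self._records(), "A_MIT_um2", "AR",
                             grouping="morphology")
        assert len(out) == 3
        assert list(out["class"]) == ["Lam", "Tub", "Lam"]
        assert list(out["x"]) == [0.5, 1.0, 0.8]

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="available"):
            scatter_export(self._records(), "nope", "AR")

    def test_folding_density_correlation_on_phantom_sweep(self):
        # more membrane folding <=> higher crista density across a lamellar
        # plate-count sweep
        from scipy.stats import spearmanr
        from cristamorph.morphometry2d import profile_metrics
        from cristamorph.phantom import generate_phantom
        from conftest import small_spec
        dens, fold = [], []
        for n in range(2, 10):
            spec = small_spec("lamellar", seed=n,
                              crista_params={"n_plates": n})
            _, cset, _ = generate_phantom(spec, render_volume=False)
            m = profile_metrics(cset)
            dens.append(m.crista_density)
            fold.append(m.folding)
        rho, _p = spearmanr(fold, dens)
        assert rho > 0.9
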